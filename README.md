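# socint — nurse–larva social interactome analysis

`socint` analyses how the transcriptomes of interacting social partners
— caregiving ant nurse workers and the larvae they feed — co-vary
across larval development, and what that implies about *social* gene
regulation: genes expressed in one individual whose expression shapes
the transcriptome of another. It is aimed at researchers studying
social regulation of development in eusocial insects (and dual
host–symbiont transcriptomics more broadly) who have stage-resolved
bulk expression tables for both partners.

The pipeline has four analytic layers:

1. **Co-expression module mining.** Gene stage profiles — five log2
   fold-changes vs the first larval stage L1,
   `p_s = log2((m_s + c) / (m_L1 + c))` — are assigned by Pearson
   correlation to the closest of 81 predefined trajectories (each step
   doubles, halves or holds: 3⁴ = 81 "modules"). Permuting stage labels
   per gene yields null module occupancies; a one-sided binomial test
   with Bonferroni correction (α/81) flags enriched modules. Modules
   enriched in both larvae and nurses are *parallel* shared; modules
   whose negation is enriched in the partner are *anti-parallel*.
   Random nurses (collected feeding larvae of any stage) are the
   biological control; drop-1 jackknifing of nurse samples gives CIs on
   shared-gene fractions.
2. **Candidate selection.** Per-stratum stage-association tests
   (Gaussian linear model on asinh-transformed abundance, stage +
   replicate design) feed a filter that drops genes also
   stage-associated in random nurses, then keeps the top-k by p-value.
3. **Social GRN inference.** Larval and nurse expression vectors from
   the same colony/time point are joined into meta-samples with
   tissue-labeled features. For each target gene a random-forest
   regression on all other features yields importances w(i→j)
   (GENIE3 recipe: √p candidate features per split, variance-reduction
   importance, runs averaged). Per gene: within-tissue connectivity =
   mean w over same-tissue targets, social connectivity = mean w over
   partner-tissue targets, and the **sociality index** = social −
   within.
4. **Molecular-evolution statistics.** Spearman correlations of
   selective constraint (proportion of strongly deleterious
   nonsynonymous mutations) with the connectivity measures, Wilcoxon
   contrasts (e.g. secreted vs non-secreted orthologs), a Gaussian GLM
   of sociality index on evolutionary age class + constraint + tissue
   with drop-one LRTs and Tukey post-hoc contrasts, bootstrap CIs per
   age class, and flat KS gene-set enrichment.

A synthetic-data generator (`socint.simulate`) emulates the study
design — 5 larval stages × 6 colonies, each colony sampled once for
larva / stage-specific nurse head & abdomen / random-nurse samples —
with planted module trajectories, planted cross-tissue regulator→target
effects, and annotation tables coupled to a planted sociality score, so
every stage of the pipeline can be validated against known ground
truth.

## Worked example

```python
from socint.simulate import SimConfig, simulate_experiment
from socint.grn import (build_meta_samples, infer_regulatory_matrix,
                        connectivity_summary, ranking_auroc)

cfg = SimConfig(n_genes_per_tissue=60, n_colonies_per_stage=5,
                planted_module_fraction=0.0, seed=0)
expr, truth = simulate_experiment(cfg)
meta = build_meta_samples(expr, truth.genes, truth.genes, "nurse_head")
reg = infer_regulatory_matrix(meta, n_trees=100, n_runs=10, seed=0)
conn = connectivity_summary(reg)
labels = [truth.is_social_regulator[g] for g in conn["gene_id"]]
print(f"meta-samples: {meta.n_observations}")
print(f"AUROC for planted social regulators: "
      f"{ranking_auroc(conn['social_connectivity'], labels):.3f}")
```

prints

```
meta-samples: 25
AUROC for planted social regulators: 0.898
```

i.e. from 25 colony/stage meta-samples the forest-importance network
ranks the 10 planted social regulators among 120 genes with AUROC 0.9
— genes whose colony-level expression deviations drive partner-tissue
expression are recoverable from joint nurse+larva sampling alone.

The same analysis from the shell:

```bash
social-interactome simulate --seed 0 --out data/
social-interactome run --config pipeline.yaml
```

`run` writes every intermediate table (module assignments, enrichment
reports, DE results, regulatory matrices, connectivity, evolutionary
statistics) plus a `manifest.json` with seeds, parameters and output
checksums; re-running the same config reproduces the checksums exactly.

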