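# Methods

This note documents the models, parameter choices and numerical
conventions behind `socint`, and what the synthetic-data validation
does and does not establish.

## Study design being modeled

Five larval developmental stages L1–L5 (1st instar, 2nd instar, and
small/medium/large 3rd instar), several replicate colonies pre-assigned
to each stage, each colony sampled once at its assigned stage. Per
colony the design yields five pooled samples: whole-body worker-destined
larvae, stage-specific nurse heads and abdomens (nurses observed feeding
larvae of the assigned stage), and random-nurse heads and abdomens
(nurses feeding larvae of any stage — the biological control, expected
to show no stage-locked expression dynamics). Abundances are FPKM-like
and unitless; the pipeline performs no within-sample normalization
beyond accepting such input.

## Stage profiles and module assignment

A gene's stage profile is the vector of log2 fold-changes of its
per-stage mean abundance relative to L1, with a pseudocount:
`p_s = log2((m_s + c)/(m_L1 + c))`, `p_1 = 0` exactly.

* **Ratio of means, not mean of ratios** (default). Stage means are
  computed first, then the log ratio. This is robust to
  single-replicate zeros; a `geometric` switch (mean of per-sample
  `log2(x + c)` differenced against L1) is provided for sensitivity
  analysis. The two agree exactly when each stage has one replicate.
* **Pseudocount c = 1.0** (FPKM scale), keeping zero-expression stages
  finite. How zeros at L1 are handled is a genuinely open choice; 1
  FPKM is of the order of the detection limit, so ratios below it are
  compressed toward zero rather than exploding.
* **Expression filter default**: per-stage mean ≥ 1 FPKM in ≥ 1 stage.

The module space is the 81 five-point trajectories starting at 0 whose
steps are +1/−1/0 in log2 (double/halve/hold). Assignment is argmax
Pearson correlation over the 80 non-constant modules. Pearson against
the flat module is undefined, so profiles with variance below
`flat_epsilon = 1e-8` go to the flat module with correlation recorded
as not applicable. Correlation ties break by smaller Euclidean distance
to the module, then canonical (lexicographic) order — determinism
matters for permutation reproducibility.

**Permutation null.** Each permutation independently shuffles every
gene's five stage means, recomputes the profile anchored at the new
first position, and reassigns. We permute all five stages and re-anchor
(rather than only the four post-L1 stages); under the no-structure null
both schemes are exchangeable and the all-five scheme is the stricter
randomization. Default 1000 permutations; desk-scale analyses use 200,
which changes null means by Monte-Carlo noise of order
`sqrt(mean/200)` genes — negligible against the Bonferroni threshold.

**Enrichment.** Observed count vs Binomial(n_genes, null_mean/n_genes),
upper tail, significant iff `p < α/81` (strict) *and* observed exceeds
the null mean. A null mean of zero is floored at 0.5/n_genes
(continuity correction) so the test stays defined. Bonferroni is
applied over the 81 modules within each stratum separately.

**Shared modules.** Parallel = enriched in both strata; anti-parallel =
module enriched in one stratum whose negation is enriched in the
partner. The flat module is self-inverse and can only be parallel. A
gene counts once toward the shared fraction even if its module
participates in several pairs.

**Jackknife.** Drop-1 jackknife over nurse samples (the larval stratum
is held fixed): CI = jackknife mean ± 1.96 × SE with
`SE = sqrt((n−1)/n · Σ(x_i − x̄)²)`. The shared-fraction statistic is a
step function of module significance, so the jackknife SE honestly
inflates when a module sits at the threshold; stability therefore
improves with gene count (module occupancies grow relative to the
binomial threshold), which is why validation of the contrast uses 800
genes rather than the 150-gene desk default.

## Differential expression

Inputs are FPKM-like (not counts), so the default model is a Gaussian
linear model on asinh-transformed abundance — asinh is ≈ ln(2x) for
x ≫ 1 and linear near 0, a standard variance-stabilizer for
abundance-like data. A negative-binomial count model would require raw
counts, which the pipeline deliberately does not assume.

* **Design.** Colonies are nested in stages (each colony is sampled
  once), so a raw colony factor would absorb the stage effect. The
  replicate term is the colony's within-stage index (rank by sorted
  label): a crossed stage × replicate layout that blocks on the
  sampling slot while leaving stage testable. A design in which the
  tested term adds no rank raises an error rather than silently
  returning nonsense.
* **Inference.** The reported statistic is the likelihood-ratio
  chi-square `n·ln(RSS0/RSS1)`; the reported p-value comes from the
  exact F distribution of the same nested comparison. The two are
  monotone transforms of one another, but at n = 30 samples the χ²
  asymptotics are anticonservative by several percent, which a
  calibration check against the uniform distribution detects; the F
  p-value is exact under the Gaussian model. Applies equally to the
  binary-group test, the ordinal stage × group interaction test, and
  the sociality GLM's drop-one LRTs.
* **Candidate screen** uses nominal p < 0.05 without FDR correction:
  the step is a filter for network reconstruction, not an inferential
  endpoint. Genes stage-associated in *both* stage-specific and random
  nurses are removed (colony effects not locked to larval development),
  then the top k = 1000 by p-value are kept (ties by gene id for
  determinism; desk-scale profiles scale k with gene count).

## Social GRN inference

Meta-samples join the larval and nurse expression vectors of the same
colony (each colony is one time point) into a single observation, with
features labeled `larva::gene` / `nurse_head::gene`. Incomplete
pairings are dropped; the design yields up to 30 (6 colonies × 5
stages) observations, 25 with 5 colonies per stage.

The forest follows the GENIE3 recipe with these conventions:

* features standardized to zero mean, unit variance (population SD);
* `⌊sqrt(p−1)⌋` candidate features per split, full-depth CART trees,
  bootstrap resampling;
* importance = bootstrap-weighted total variance reduction per feature,
  divided by tree count — sklearn's convention *without* the per-model
  normalization to sum 1, so importances stay comparable across target
  columns and no per-target renormalization is applied before
  connectivity averaging;
* the full reconstruction is repeated over `n_runs` independently
  seeded runs (derived as (master seed, run index)) and matrices are
  averaged; 1000 runs at full scale, 3–10 at desk scale;
* zero-variance targets yield a zero column with a warning.

Trees are built by a numba-compiled kernel (the per-fit overhead of a
general-purpose forest implementation dominates at 25 observations;
the kernel makes repeated full reconstructions practical on one core).
The kernel reproduces the reference semantics — candidate features
drawn without replacement skipping constants, best midpoint split by
SSE reduction, leaves on pure or size-<2 nodes — and its importances
are cross-checked against sklearn's RandomForestRegressor in the test
suite (correlation > 0.95 on strong-signal fixtures; identical top
features).

Connectivity summarizes **outgoing** effects (a gene's mean importance
for predicting same-tissue vs partner-tissue targets), matching the
definition of within-individual and social connectivity as the average
regulatory effect a gene exerts; an `incoming` switch exists for
sensitivity analysis. Sociality index = social − within, exactly.

## Evolutionary statistics

* Spearman correlations of constraint vs each connectivity measure,
  per tissue; rows with missing annotations are dropped pairwise and
  the reported n is the rows used.
* Rank-based contrasts: Mann–Whitney (unpaired) / Wilcoxon signed-rank
  (paired; the within-vs-social contrast is paired per gene by
  default).
* Sociality GLM: Gaussian with identity link — the response is a
  real-valued difference of importances, for which a Gaussian error
  model is the natural default. Age class enters categorically (the
  ordinal alternative would impose an unverifiable spacing). Post-hoc
  age contrasts use Tukey's HSD on the response grouped by age class
  (the Fig-style marginal comparison); covariate-adjusted contrasts can
  be obtained by running the GLM on residualized responses.
* Bootstrap CIs: percentile method over genes within class.
* Gene-set enrichment: two-sample KS of members vs non-members on the
  connectivity score, exact p where feasible. This is *flat*
  enrichment — no ontology-graph decorrelation of nested terms — a
  deliberate simplification; nested gene sets will show correlated
  signals.

## Synthetic data generator

The generator's defaults are the package's reference conditions:
5 stages × 6 colonies; log-normal baselines (ln FPKM ~ N(3, 1), i.e.
typical detected-gene abundance ≈ 20 FPKM); colony-level log2 noise
SD 0.25 (pooled samples are modeled as one noisy draw per colony, with
pooling variance folded into this term); measurement noise SD 0.1;
60% of genes planted into module trajectories; planted trajectories
drawn from a pool of 10 distinct non-flat modules per experiment
(real stage series concentrate genes in a handful of dominant
trajectories; spreading planted genes uniformly over 80 modules would
place every module at its permutation-null occupancy and no enrichment
could exist at any sample size); 30% of module/tissue combinations
anti-parallel. The parallel/anti-parallel relation is drawn per
(module, nurse tissue), not per gene: a trajectory is tracked or
mirrored wholesale by the partner, which matches the observed
head-vs-abdomen asymmetry and keeps nurse module occupancies coherent.

Random-nurse samples evaluate each planted profile at an independently
shuffled stage per (gene, colony); a shuffle shared across genes within
a colony would act like a coherent mislabeling and let spurious
enrichment survive averaging.

Regulatory structure: 10 social + 10 within regulators, each driving
50 targets (half the non-regulator pool at network-benchmark size) at
unit coefficient. A target's log2 abundance gains
`coefficient × (regulator's own colony-level deviation)`; social edges
cross tissues, within edges do not. Hub-like out-degree is deliberate:
the genes entering network reconstruction are pre-filtered
stage-associated candidates, so a genuine social regulator (e.g. a
secreted signaling inhibitor) plausibly influences a large share of
them, and mean-importance connectivity is a hub statistic — with
near-singleton out-degrees the per-gene average over ~60 partner
targets would bury any signal at 25 observations regardless of
inference quality. Edges are injected as colony-level covariation, not
time-lagged dynamics: with 3–4-day sampling intervals the lags are too
short to observe, which is also why the inference layer uses static
forests rather than a time-series variant.

Annotations: a planted sociality score (social − within regulator
status + N(0, 0.5) jitter) is coupled to selective constraint through a
Gaussian copula with latent correlation `2·sin(π·ρ_S/6)` so the
*Spearman* correlation equals the configured ρ (default −0.2);
constraint marginals are Beta(5, 2) (skewed high, as purifying-selection
estimates are). Ancient age-class probability is logistic-decreasing in
the score (ancient genes enriched among within-regulators); non-ancient
genes split uniformly over insect/hymenoptera/ant, so the younger
classes share one sociality distribution and only ancient-vs-younger
contrasts are planted. The secreted flag and a `high_sociality` gene
set are logistic-enriched among high-score genes. 10% of constraint and
5% of age annotations are left missing to exercise pairwise deletion.

## What the validation shows — and does not

Planted-structure recovery demonstrates that each pipeline stage
detects the quantity it targets at realistic noise: ≥95% module
recovery at profile noise SD 0.25; zero enriched modules on
structure-free data in ≥95% of seeds (Bonferroni calibration);
stage-specific nurses' shared-gene fraction exceeding random nurses'
with non-overlapping jackknife CIs; social-regulator recovery AUROC
≈ 0.9 at 25 meta-samples; planted ρ and the ancient-lowest age pattern
recovered by the downstream statistics. The generator does not model
read-level sampling, transcript length effects, batch structure,
correlated gene–gene baseline covariance beyond the planted edges, or
caste-determination biology; passing tests show the estimators are
correct and calibrated under the stated noise model, not that real
nurse–larva data meet that model.

Problem sizes in tests and the acceptance script (hundreds to a
thousand genes, 25–30 meta-samples, 100-tree × 10-run forests) are
desk-scale choices; all thresholds (α = 0.05, Bonferroni family 81,
k = top-1000, 1000 permutations/runs at full scale) follow the
reference conditions.

## Known limitations

* Importance-based connectivity is directional in form but correlation
  in substance at 25 observations; planted-edge direction is not
  validated (and cannot be, without interventions).
* The binomial enrichment test treats the permutation null mean as
  known; Monte-Carlo error in the null mean is ignored (conservative
  at 1000 permutations, visible at very low permutation counts).
* The F-based p-values are exact only under Gaussian errors; for
  low-abundance genes the asinh transform leaves residual skew. The
  pooled-null calibration checks bound the practical effect.
* Tukey post-hoc contrasts are computed on the marginal response by
  age class, not adjusted for constraint/tissue covariates.
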