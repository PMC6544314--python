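"""End-to-end orchestration: simulate/load -> modules -> DE -> GRN -> evo stats.

A single declarative config drives the full analysis and every
intermediate artifact is written to the output directory together with
a manifest (parameter values, seeds, per-stage row counts, SHA-256
checksums, warnings and timings). Re-running with the same config
yields identical checksums.

Numeric defaults follow the emulated study where it states them
(permutations 1000, top-k 1000, alpha 0.05, Bonferroni family 0.05,
1000 reconstruction runs at full scale); desk-scale profiles override
them explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, evostats, grn, modules
from .datamodel import (ExpressionMatrix, expression_filter, load_annotations,
                        load_expression, write_annotations, write_expression)
from .simulate import SimConfig, simulate_annotations, simulate_experiment

logger = logging.getLogger("socint.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "desk_config"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    out_dir: str = "socint_out"
    # either simulate ...
    sim: SimConfig | None = None
    # ... or load from disk
    expression_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None

    alpha: float = 0.05
    k: int = 1000
    min_mean: float = 1.0
    min_stages: int = 1
    pseudocount: float = 1.0
    flat_epsilon: float = 1e-8
    n_perm: int = 1000
    n_trees: int = 1000
    n_runs: int = 1000
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.sim is None and (self.expression_path is None
                                 or self.metadata_path is None):
            raise ValueError("config needs either a sim section or "
                             "expression_path + metadata_path")


def desk_config(seed: int = 0, out_dir: str = "socint_out") -> PipelineConfig:
    """Desk-scale profile: small gene counts, forests and permutation counts."""
    return PipelineConfig(
        out_dir=out_dir, sim=SimConfig(n_genes_per_tissue=150, seed=seed),
        k=60, n_perm=200, n_trees=50, n_runs=3, n_boot=500, seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context manager recording stage timing and wrapping errors."""

    def __init__(self, manifest: dict, name: str):
        self.manifest = manifest
        self.name = name

    def __enter__(self):
        logger.info("stage %s", self.name)
        self.manifest["stages"].setdefault(self.name, {})
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        self.manifest["stages"][self.name]["seconds"] = round(
            time.perf_counter() - self.t0, 3)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items() if k != "sim"},
        "sim": None if config.sim is None else asdict(config.sim),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    caught: list[str] = []

    def emit(name: str, obj) -> Path:
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t")
        else:
            path.write_text(obj)
        manifest["outputs"][name] = {"sha256": _sha256(path)}
        return path

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- input ------------------------------------------------------
        with _Stage(manifest, "input"):
            if config.sim is not None:
                expr, truth = simulate_experiment(config.sim)
                ann = simulate_annotations(truth, config.sim)
                write_expression(expr, out / "expression.tsv",
                                 out / "metadata.tsv")
                write_annotations(ann, out / "annotations.tsv")
                truth.to_json(out / "ground_truth.json")
                for f in ("expression.tsv", "metadata.tsv", "annotations.tsv",
                          "ground_truth.json"):
                    manifest["outputs"][f] = {"sha256": _sha256(out / f)}
            else:
                expr = load_expression(config.expression_path,
                                       config.metadata_path)
                ann = (load_annotations(config.annotation_path)
                       if config.annotation_path else None)
            manifest["stages"]["input"].update(
                {"n_genes": expr.n_genes, "n_samples": expr.n_samples})

        # ---- expression filter -------------------------------------------
        with _Stage(manifest, "filter"):
            kept = expression_filter(expr, config.min_mean, config.min_stages)
            expr = expr.subset_genes(kept)
            manifest["stages"]["filter"]["n_genes_kept"] = len(kept)

        # ---- module mining ----------------------------------------------
        strata = {
            "larva": dict(tissue="larva", caste="worker"),
            "nurse_head_ss": dict(tissue="nurse_head", nurse_type="stage_specific"),
            "nurse_abdomen_ss": dict(tissue="nurse_abdomen", nurse_type="stage_specific"),
            "nurse_head_rand": dict(tissue="nurse_head", nurse_type="random"),
            "nurse_abdomen_rand": dict(tissue="nurse_abdomen", nurse_type="random"),
        }
        assignments, enriched = {}, {}
        with _Stage(manifest, "modules"):
            for name, sel in strata.items():
                assign, report = modules.run_module_enrichment(
                    expr, sel["tissue"], sel.get("nurse_type"),
                    sel.get("caste"), n_perm=config.n_perm, seed=config.seed,
                    pseudocount=config.pseudocount,
                    flat_epsilon=config.flat_epsilon, alpha=config.alpha)
                assignments[name] = assign
                enriched[name] = set(report.loc[report["significant"],
                                                "module_id"])
                emit(f"modules_{name}_assignment.tsv", assign)
                emit(f"modules_{name}_enrichment.tsv", report)
            shared_rows = []
            for nurse in ("nurse_head_ss", "nurse_abdomen_ss",
                          "nurse_head_rand", "nurse_abdomen_rand"):
                sh = modules.shared_modules(enriched["larva"], enriched[nurse])
                counts = modules.shared_gene_counts(
                    assignments["larva"], assignments[nurse], sh)
                shared_rows.append({
                    "pair": f"larva~{nurse}",
                    "n_shared_modules": len(sh.pairs),
                    "larva_fraction": counts["a"]["fraction"],
                    "nurse_fraction": counts["b"]["fraction"],
                })
            shared_df = pd.DataFrame(shared_rows).set_index("pair")
            emit("shared_modules.tsv", shared_df)
            manifest["stages"]["modules"]["shared"] = shared_df.to_dict("index")

        # ---- differential expression ------------------------------------
        with _Stage(manifest, "diffexp"):
            de = {}
            for name, sel in strata.items():
                de[name] = diffexp.stage_association_test(
                    expr, sel["tissue"], sel.get("nurse_type"),
                    sel.get("caste"))
                emit(f"de_{name}.tsv", de[name])
            candidates = {
                "larva": diffexp.candidate_selection(
                    de["larva"], de["larva"].assign(p_value=1.0),
                    config.alpha, config.k),
                "nurse_head": diffexp.candidate_selection(
                    de["nurse_head_ss"], de["nurse_head_rand"],
                    config.alpha, config.k),
                "nurse_abdomen": diffexp.candidate_selection(
                    de["nurse_abdomen_ss"], de["nurse_abdomen_rand"],
                    config.alpha, config.k),
            }
            for name, cand in candidates.items():
                emit(f"candidates_{name}.txt", "\n".join(cand.genes) + "\n")
            manifest["stages"]["diffexp"]["n_candidates"] = {
                k: len(v.genes) for k, v in candidates.items()}

        # ---- GRN reconstruction -----------------------------------------
        conn_tables = []
        with _Stage(manifest, "grn"):
            for net, nurse_tissue in [("head_net", "nurse_head"),
                                      ("abdomen_net", "nurse_abdomen")]:
                key = nurse_tissue
                meta = grn.build_meta_samples(
                    expr, candidates["larva"].genes, candidates[key].genes,
                    nurse_tissue)
                reg = grn.infer_regulatory_matrix(
                    meta, n_trees=config.n_trees, n_runs=config.n_runs,
                    seed=config.seed)
                conn = grn.connectivity_summary(reg)
                conn["network"] = net
                conn_tables.append(conn)
                emit(f"regulatory_matrix_{net}.tsv", reg.importances)
                emit(f"connectivity_{net}.tsv", conn)
            connectivity = pd.concat(conn_tables)
            manifest["stages"]["grn"]["n_features"] = {
                t["network"].iloc[0]: len(t) for t in conn_tables}

        # ---- evolutionary statistics ------------------------------------
        with _Stage(manifest, "evostats"):
            stats_rows = []
            if ann is not None:
                for res in evostats.connectivity_constraint_correlations(
                        connectivity, ann):
                    stats_rows.append(asdict(res))
                merged = connectivity.reset_index(drop=True).merge(
                    ann, left_on="gene_id", right_index=True, how="left")
                nurse_conn = merged[merged["tissue"] != "larva"]
                sec = nurse_conn.dropna(subset=["secreted"])
                if sec["secreted"].nunique() == 2:
                    res = evostats.group_contrast(
                        sec["social_connectivity"], sec["secreted"].astype(bool),
                        name="social_connectivity_secreted_vs_not")
                    stats_rows.append(asdict(res))
                paired = evostats.group_contrast(
                    np.concatenate([merged["within_connectivity"],
                                    merged["social_connectivity"]]),
                    np.repeat(["within", "social"], len(merged)),
                    paired=True, name="within_vs_social_connectivity")
                stats_rows.append(asdict(paired))
                glm_data = merged.rename(columns={})[
                    ["sociality_index", "age_class", "constraint", "tissue"]]
                try:
                    terms, posthoc = evostats.sociality_age_glm(glm_data)
                    emit("glm_terms.tsv", terms)
                    emit("glm_age_posthoc.tsv", posthoc.set_index(
                        posthoc.columns[0]))
                except ValueError as e:
                    caught.append(f"GLM skipped: {e}")
                boot = evostats.bootstrap_class_means(
                    merged["sociality_index"].to_numpy(),
                    merged["age_class"].fillna("missing").to_numpy(),
                    n_boot=config.n_boot, seed=config.seed)
                emit("age_class_bootstrap.tsv", boot)
                sets: dict[str, list[str]] = {}
                for g, row in ann.iterrows():
                    for s in row["gene_sets"]:
                        sets.setdefault(s, []).append(g)
                if sets:
                    scores = nurse_conn.set_index("gene_id")["social_connectivity"]
                    scores = scores.groupby(level=0).mean()
                    ks = evostats.ks_set_enrichment(scores, sets)
                    emit("ks_set_enrichment.tsv", ks)
            stats_df = pd.DataFrame(stats_rows)
            if len(stats_df):
                emit("stat_results.tsv", stats_df.set_index("name"))

        caught.extend(str(w.message) for w in wrec)

    manifest["warnings"] = caught
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest
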