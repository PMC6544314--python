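"""Synthetic nurse/larva expression experiments with planted ground truth.

The generator emulates the study design: five larval developmental
stages (L1..L5), several replicate colonies pre-assigned to each stage
and sampled once, and for every colony one worker-destined larva sample
(whole body), one stage-specific nurse head, one stage-specific nurse
abdomen, and one random-nurse head and abdomen (the biological control:
nurses collected while feeding larvae of any stage). Pooled samples (ten
individuals per pool in the emulated design) are modeled as a single
noisy draw per colony, with pooling variance folded into
``profile_noise_sd``.

Planted structure, all recoverable by the pipeline:

* A fraction of genes follows module trajectories drawn from a small
  pool of distinct profiles (real stage series concentrate genes in a
  handful of dominant trajectories). For those genes the stage-specific
  nurse profile equals the larval profile (parallel) or its negation
  (anti-parallel). Random-nurse samples evaluate the profile at an
  independently shuffled stage per gene and colony, so no stage trend
  survives averaging.
* Regulator->target effects are injected as colony-level covariation:
  a target's log2 abundance gains ``coefficient x`` the regulator's
  colony-level deviation. Social regulators act across tissues, within
  regulators inside their own tissue -- exactly the quantity that
  meta-sample network inference can see (developmental time lags are
  too short to observe at this sampling density).
* Per-gene annotations (selective constraint, evolutionary age class,
  secreted flag, gene sets) are coupled to a planted "sociality" score
  via a Gaussian copula, so the downstream evolutionary statistics have
  known targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datamodel import ExpressionMatrix, STAGES
from .modules import FLAT_MODULE_ID, enumerate_module_profiles

__all__ = ["SimConfig", "GroundTruth", "PlantedEdge", "simulate_experiment",
           "simulate_annotations"]

#: jitter added to the regulator-status difference when forming the
#: planted sociality score (log-odds style latent, unitless)
SOCIALITY_JITTER_SD = 0.5


class PlantedEdge(NamedTuple):
    source: str
    target: str
    source_tissue: str
    target_tissue: str
    coefficient: float


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults model a desk-scale version of the emulated experiment:
    5 stages x 6 colonies, log-normal baseline abundance around
    e^3 ~ 20 FPKM, colony-level log2 noise of 0.25, 60% of genes planted
    into one of 10 distinct module trajectories with 30% anti-parallel
    nurse partners, and 10 + 10 social/within hub regulators each
    driving 50 targets at unit coefficient (genes entering network
    reconstruction are pre-filtered stage-associated candidates, so a
    regulator's influence plausibly touches a large share of them).
    """

    n_genes_per_tissue: int = 400
    n_colonies_per_stage: int = 6
    baseline_log_mean: float = 3.0      # natural-log FPKM
    baseline_log_sd: float = 1.0
    profile_noise_sd: float = 0.25      # log2 units, per colony draw
    planted_module_fraction: float = 0.6
    antiparallel_fraction: float = 0.3
    n_distinct_modules: int = 10
    n_social_regulators: int = 10
    n_within_regulators: int = 10
    n_targets_per_regulator: int = 50
    regulator_effect_size: float = 1.0  # log2 gain per unit regulator deviation
    meta_noise_sd: float = 0.1          # extra measurement noise, log2 units
    rho_sociality_constraint: float = -0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_colonies_per_stage < 1:
            raise ValueError("need at least one colony per stage")
        if self.n_genes_per_tissue < 1:
            raise ValueError("need at least one gene")
        for name in ("planted_module_fraction", "antiparallel_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("baseline_log_sd", "profile_noise_sd", "meta_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 <= self.rho_sociality_constraint <= 1:
            raise ValueError("rho_sociality_constraint must be in [-1,1]")
        n_reg = self.n_social_regulators + self.n_within_regulators
        if n_reg >= self.n_genes_per_tissue:
            raise ValueError("more regulators than genes")


@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment."""

    genes: list[str]
    planted_module: dict[str, str | None]          # gene -> module id or None
    nurse_relation: dict[str, dict[str, str]]      # planted gene -> tissue -> relation
    is_social_regulator: dict[str, bool]
    is_within_regulator: dict[str, bool]
    regulator_source_tissue: dict[str, str]
    planted_edges: list[PlantedEdge]
    sociality_score: np.ndarray | None = None      # filled by simulate_annotations

    def social_regulator_labels(self) -> np.ndarray:
        return np.array([self.is_social_regulator[g] for g in self.genes])

    def to_json(self, path: str | Path) -> None:
        data = {
            "genes": self.genes,
            "planted_module": self.planted_module,
            "nurse_relation": self.nurse_relation,
            "is_social_regulator": self.is_social_regulator,
            "is_within_regulator": self.is_within_regulator,
            "regulator_source_tissue": self.regulator_source_tissue,
            "planted_edges": [list(e) for e in self.planted_edges],
            "sociality_score": None if self.sociality_score is None
            else list(map(float, self.sociality_score)),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"],
            planted_module=d["planted_module"],
            nurse_relation=d["nurse_relation"],
            is_social_regulator=d["is_social_regulator"],
            is_within_regulator=d["is_within_regulator"],
            regulator_source_tissue=d["regulator_source_tissue"],
            planted_edges=[PlantedEdge(*e) for e in d["planted_edges"]],
            sociality_score=None if d["sociality_score"] is None
            else np.array(d["sociality_score"]),
        )


def _module_pool(rng: np.random.Generator, k: int) -> list:
    nonflat = [m for m in enumerate_module_profiles() if m.id != FLAT_MODULE_ID]
    idx = rng.choice(len(nonflat), size=min(k, len(nonflat)), replace=False)
    return [nonflat[i] for i in idx]


def simulate_experiment(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one full experiment (all five strata) plus its ground truth.

    Abundance model per gene g, colony c (assigned stage s), stratum t:

    ``FPKM = exp(baseline_g) * 2 ** (profile_{g,t}[s] + eps_{g,t,c}
    + sum_r coef * d_{r,c} + meta_noise)``

    where ``d_{r,c}`` is regulator r's own colony deviation in its
    source tissue. Random-nurse strata evaluate the profile at a random
    stage per (gene, colony) and carry no planted regulatory edges.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    N = config.n_genes_per_tissue
    genes = [f"g{i:04d}" for i in range(N)]
    n_col = config.n_colonies_per_stage
    C = n_col * len(STAGES)
    colony_stage = np.repeat(np.arange(len(STAGES)), n_col)
    colonies = [f"{STAGES[s]}c{j}" for s in range(len(STAGES))
                for j in range(n_col)]

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, N)

    # ---- planted module trajectories -------------------------------------
    pool = _module_pool(rng, config.n_distinct_modules)
    n_planted = int(round(config.planted_module_fraction * N))
    planted_idx = rng.choice(N, size=n_planted, replace=False)
    planted_mask = np.zeros(N, dtype=bool)
    planted_mask[planted_idx] = True

    P_larva = np.zeros((N, 5))
    P_head = np.zeros((N, 5))
    P_abd = np.zeros((N, 5))
    # the parallel/anti-parallel relation is a property of the trajectory,
    # not of single genes: nurses track or mirror a module wholesale
    anti = {
        tissue: {m.id: bool(rng.random() < config.antiparallel_fraction)
                 for m in pool}
        for tissue in ("nurse_head", "nurse_abdomen")
    }
    planted_module: dict[str, str | None] = {g: None for g in genes}
    nurse_relation: dict[str, dict[str, str]] = {}
    for i in planted_idx:
        mod = pool[rng.integers(len(pool))]
        planted_module[genes[i]] = mod.id
        vals = np.array(mod.values, dtype=float)
        P_larva[i] = vals
        rel = {t: ("antiparallel" if anti[t][mod.id] else "parallel")
               for t in ("nurse_head", "nurse_abdomen")}
        nurse_relation[genes[i]] = rel
        P_head[i] = (-1.0 if anti["nurse_head"][mod.id] else 1.0) * vals
        P_abd[i] = (-1.0 if anti["nurse_abdomen"][mod.id] else 1.0) * vals

    # ---- regulators and planted edges ------------------------------------
    n_reg = config.n_social_regulators + config.n_within_regulators
    reg_idx = rng.choice(N, size=n_reg, replace=False)
    social_idx = reg_idx[:config.n_social_regulators]
    within_idx = reg_idx[config.n_social_regulators:]
    target_pool = np.setdiff1d(np.arange(N), reg_idx)

    is_social = {g: False for g in genes}
    is_within = {g: False for g in genes}
    src_tissue: dict[str, str] = {}
    edges: list[PlantedEdge] = []

    eps_larva = rng.normal(0, config.profile_noise_sd, (N, C))
    eps_head = rng.normal(0, config.profile_noise_sd, (N, C))
    eps_abd = rng.normal(0, config.profile_noise_sd, (N, C))
    eps_rhead = rng.normal(0, config.profile_noise_sd, (N, C))
    eps_rabd = rng.normal(0, config.profile_noise_sd, (N, C))

    coef = config.regulator_effect_size
    add_larva = np.zeros((N, C))
    add_head = np.zeros((N, C))
    add_abd = np.zeros((N, C))

    def plant(reg_positions: np.ndarray, social: bool) -> None:
        for k, i in enumerate(reg_positions):
            g = genes[i]
            (is_social if social else is_within)[g] = True
            source = "larva" if k % 2 == 0 else "nurse"
            src_tissue[g] = source
            if source == "nurse":
                # one organism-level deviation: head and abdomen share it
                eps_abd[i] = eps_head[i]
                d = eps_head[i]
            else:
                d = eps_larva[i]
            targets = rng.choice(target_pool,
                                 size=min(config.n_targets_per_regulator,
                                          len(target_pool)), replace=False)
            for j in targets:
                tg = genes[j]
                if social and source == "nurse":
                    add_larva[j] += coef * d
                    edges.append(PlantedEdge(g, tg, "nurse_head", "larva", coef))
                    edges.append(PlantedEdge(g, tg, "nurse_abdomen", "larva", coef))
                elif social:
                    add_head[j] += coef * d
                    add_abd[j] += coef * d
                    edges.append(PlantedEdge(g, tg, "larva", "nurse_head", coef))
                    edges.append(PlantedEdge(g, tg, "larva", "nurse_abdomen", coef))
                elif source == "nurse":
                    add_head[j] += coef * d
                    add_abd[j] += coef * d
                    edges.append(PlantedEdge(g, tg, "nurse_head", "nurse_head", coef))
                    edges.append(PlantedEdge(g, tg, "nurse_abdomen", "nurse_abdomen", coef))
                else:
                    add_larva[j] += coef * d
                    edges.append(PlantedEdge(g, tg, "larva", "larva", coef))

    plant(social_idx, social=True)
    plant(within_idx, social=False)

    # ---- assemble per-stratum log2 signal --------------------------------
    stage_of_col = colony_stage                                     # (C,)
    rand_stage_h = rng.integers(0, 5, size=(N, C))
    rand_stage_a = rng.integers(0, 5, size=(N, C))

    def meta_noise() -> np.ndarray:
        return rng.normal(0, config.meta_noise_sd, (N, C))

    sig = {
        ("larva", "not_applicable"):
            P_larva[:, stage_of_col] + eps_larva + add_larva + meta_noise(),
        ("nurse_head", "stage_specific"):
            P_head[:, stage_of_col] + eps_head + add_head + meta_noise(),
        ("nurse_abdomen", "stage_specific"):
            P_abd[:, stage_of_col] + eps_abd + add_abd + meta_noise(),
        ("nurse_head", "random"):
            np.take_along_axis(P_head, rand_stage_h, axis=1)
            + eps_rhead + meta_noise(),
        ("nurse_abdomen", "random"):
            np.take_along_axis(P_abd, rand_stage_a, axis=1)
            + eps_rabd + meta_noise(),
    }

    queen_present = np.tile([True, False], C)[:C]

    cols = {}
    meta_rows = []
    short = {"larva": "lv", "nurse_head": "nh", "nurse_abdomen": "na"}
    for (tissue, ntype), logsig in sig.items():
        fpkm = np.exp(baseline)[:, None] * np.exp2(logsig)
        for c in range(C):
            tag = "r" if ntype == "random" else ""
            sid = f"{colonies[c]}_{short[tissue]}{tag}"
            cols[sid] = fpkm[:, c]
            meta_rows.append({
                "sample_id": sid,
                "tissue": tissue,
                "nurse_type": ntype,
                "stage": STAGES[colony_stage[c]],
                "colony": colonies[c],
                "caste": "worker" if tissue == "larva" else "not_applicable",
                "queen_present": bool(queen_present[c]),
            })

    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    expr = ExpressionMatrix(values, meta)

    truth = GroundTruth(
        genes=genes,
        planted_module=planted_module,
        nurse_relation=nurse_relation,
        is_social_regulator=is_social,
        is_within_regulator=is_within,
        regulator_source_tissue=src_tissue,
        planted_edges=edges,
    )
    return expr, truth


def simulate_annotations(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Per-gene annotations coupled to a planted sociality score.

    The score is ``1[social regulator] - 1[within regulator]`` plus
    Gaussian jitter. Selective constraint is drawn through a Gaussian
    copula whose latent correlation is calibrated so the *Spearman*
    correlation with the score equals ``config.rho_sociality_constraint``
    (latent rho = 2 sin(pi rho_S / 6)); the marginal is Beta(5, 2),
    skewed high as purifying-selection estimates are. Ancient age-class
    probability decreases with the score (ancient genes enriched among
    within regulators); the remaining genes split uniformly over the
    insect/hymenoptera/ant classes, which therefore share one sociality
    distribution. The secreted flag is enriched among social regulators.
    A small fraction of constraint and age annotations is left missing,
    as in real annotation tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = truth.genes
    n = len(genes)
    social = truth.social_regulator_labels().astype(float)
    within = np.array([truth.is_within_regulator[g] for g in genes], dtype=float)
    score = social - within + rng.normal(0, SOCIALITY_JITTER_SD, n)
    truth.sociality_score = score

    # normal scores of the sociality ranks (copula input)
    ranks = stats.rankdata(score)
    z1 = stats.norm.ppf((ranks - 0.5) / n)
    rho_l = 2 * np.sin(np.pi * config.rho_sociality_constraint / 6)
    z = rho_l * z1 + np.sqrt(max(0.0, 1 - rho_l ** 2)) * rng.normal(size=n)
    constraint = stats.beta.ppf(stats.norm.cdf(z), 5, 2)

    p_ancient = expit(0.4 - 1.5 * z1)
    ancient = rng.random(n) < p_ancient
    young = rng.choice(["insect", "hymenoptera", "ant"], size=n)
    age = np.where(ancient, "ancient", young)

    secreted = rng.random(n) < expit(-2.8 + 0.8 * z1)

    in_social_set = rng.random(n) < expit(-2.5 + 1.0 * z1)
    sets = []
    for i in range(n):
        s = []
        if in_social_set[i]:
            s.append("high_sociality")
        if rng.random() < 0.05:
            s.append("random_set_1")
        if rng.random() < 0.05:
            s.append("random_set_2")
        sets.append(s)

    constraint = constraint.astype(object)
    miss_c = rng.random(n) < 0.10
    miss_a = rng.random(n) < 0.05
    ann = pd.DataFrame({
        "constraint": np.where(miss_c, np.nan, constraint.astype(float)),
        "age_class": np.where(miss_a, None, age),
        "secreted": secreted,
        "gene_sets": sets,
    }, index=pd.Index(genes, name="gene_id"))
    return ann
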