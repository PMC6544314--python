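"""Short time-series co-expression module mining.

Genes are sorted into predefined expression trajectories ("modules"):
starting from 0 at stage L1, each subsequent stage either doubles (+1 in
log2), halves (-1) or keeps (0) the expression level, giving 3^4 = 81
possible five-point profiles. Each gene's observed log2 fold-change
profile is assigned to the closest module by Pearson correlation, a
permutation of stage labels provides the null expectation of module
occupancy, and one-sided binomial tests with Bonferroni correction flag
significantly enriched modules. Modules enriched in two interacting
strata (e.g. larvae and stage-specific nurse heads) are "shared": either
the same module in both (parallel co-expression) or a module whose
negation is enriched in the partner (anti-parallel).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (DataValidationError, ExpressionMatrix, STAGES,
                        log2fc_profiles, stage_means)

__all__ = [
    "ModuleProfile",
    "FLAT_MODULE_ID",
    "enumerate_module_profiles",
    "negate_module_id",
    "assign_to_module",
    "assign_profiles",
    "permuted_null_counts",
    "module_enrichment",
    "SharedModuleSet",
    "shared_modules",
    "shared_gene_counts",
    "run_module_enrichment",
    "jackknife_shared_counts",
    "JackknifeEstimate",
]


@dataclass(frozen=True)
class ModuleProfile:
    """One predefined five-point log2 trajectory; id is its canonical string."""

    values: tuple[int, ...]

    @property
    def id(self) -> str:
        return ",".join(str(v) for v in self.values)

    def negation(self) -> "ModuleProfile":
        return ModuleProfile(tuple(-v for v in self.values))


FLAT_MODULE_ID = "0,0,0,0,0"


def enumerate_module_profiles() -> list[ModuleProfile]:
    """All 81 module profiles, in lexicographic order on their values."""
    profiles = []
    for steps in itertools.product((-1, 0, 1), repeat=4):
        vals = (0, *np.cumsum(steps).tolist())
        profiles.append(ModuleProfile(tuple(int(v) for v in vals)))
    profiles.sort(key=lambda m: m.values)
    return profiles


# Module cache shared by the vectorized assignment below.
_MODULES = enumerate_module_profiles()
_MODULE_IDS = [m.id for m in _MODULES]
_MODULE_INDEX = {m.id: i for i, m in enumerate(_MODULES)}
_FLAT_INDEX = _MODULE_INDEX[FLAT_MODULE_ID]
_M = np.array([m.values for m in _MODULES], dtype=float)           # 81 x 5
_NONFLAT = np.array([i for i, m in enumerate(_MODULES)
                     if m.id != FLAT_MODULE_ID])
_MC = _M[_NONFLAT] - _M[_NONFLAT].mean(axis=1, keepdims=True)
_MC_UNIT = _MC / np.linalg.norm(_MC, axis=1, keepdims=True)


def negate_module_id(module_id: str) -> str:
    vals = tuple(-int(v) for v in module_id.split(","))
    return ",".join(str(v) for v in vals)


def _assign_indices(profiles: np.ndarray, flat_epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized assignment of G x 5 profiles to module indices.

    Returns (module index per gene, Pearson r per gene; NaN for flat).
    Ties on correlation are broken by smaller Euclidean distance to the
    module, then by canonical module order.
    """
    P = np.asarray(profiles, dtype=float)
    centered = P - P.mean(axis=1, keepdims=True)
    var = (centered ** 2).mean(axis=1)
    norm = np.linalg.norm(centered, axis=1)
    flat = var < flat_epsilon

    idx = np.full(P.shape[0], _FLAT_INDEX, dtype=np.int64)
    corr_out = np.full(P.shape[0], np.nan)
    if (~flat).any():
        sub = centered[~flat] / norm[~flat, None]
        corr = sub @ _MC_UNIT.T                                    # G' x 80
        best = corr.max(axis=1)
        pick = corr.argmax(axis=1)
        # resolve near-exact correlation ties deterministically
        tied = (corr >= best[:, None] - 1e-12).sum(axis=1) > 1
        if tied.any():
            Psub = P[~flat]
            for g in np.flatnonzero(tied):
                cands = np.flatnonzero(corr[g] >= best[g] - 1e-12)
                d = np.linalg.norm(_M[_NONFLAT[cands]] - Psub[g], axis=1)
                cands = cands[d <= d.min() + 1e-12]
                pick[g] = cands.min()          # canonical (lexicographic) order
        idx[~flat] = _NONFLAT[pick]
        corr_out[~flat] = best
    return idx, corr_out


def assign_to_module(profile, modules: list[ModuleProfile] | None = None,
                     flat_epsilon: float = 1e-8) -> tuple[str, float]:
    """Assign a single stage profile to its closest module.

    A profile with variance below ``flat_epsilon`` goes to the flat
    module with correlation NaN (Pearson is undefined against a constant
    profile); otherwise the argmax-correlation module over the 80
    non-constant profiles is returned.
    """
    idx, corr = _assign_indices(np.asarray(profile, float)[None, :], flat_epsilon)
    return _MODULE_IDS[idx[0]], float(corr[0])


def assign_profiles(profiles: pd.DataFrame,
                    flat_epsilon: float = 1e-8) -> pd.DataFrame:
    """Assign every gene profile to a module.

    Parameters
    ----------
    profiles
        Gene x 5 DataFrame of log2 fold-change profiles (first column 0).

    Returns
    -------
    DataFrame indexed by gene with columns ``module_id`` and
    ``correlation`` (NaN for flat-assigned genes).
    """
    idx, corr = _assign_indices(profiles.to_numpy(float), flat_epsilon)
    return pd.DataFrame(
        {"module_id": [_MODULE_IDS[i] for i in idx], "correlation": corr},
        index=profiles.index,
    )


def module_counts(assignment: pd.DataFrame) -> np.ndarray:
    """Observed gene counts per module (length-81, canonical order)."""
    idx = assignment["module_id"].map(_MODULE_INDEX).to_numpy()
    return np.bincount(idx, minlength=len(_MODULES)).astype(float)


def permuted_null_counts(means: pd.DataFrame | np.ndarray, n_perm: int,
                         seed: int, pseudocount: float = 1.0,
                         flat_epsilon: float = 1e-8) -> np.ndarray:
    """Null mean module occupancy from stage-label permutations.

    Each permutation independently shuffles every gene's five stage
    means, recomputes the log2 fold-change profile anchored at the new
    first position, and reassigns genes to modules. Returns the mean
    count per module (canonical order) over ``n_perm`` permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    M = np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(_MODULES))
    for _ in range(n_perm):
        order = np.argsort(rng.random(M.shape), axis=1)   # independent row shuffles
        P = np.take_along_axis(M, order, axis=1)
        prof = np.log2((P + pseudocount) / (P[:, :1] + pseudocount))
        prof[:, 0] = 0.0
        idx, _ = _assign_indices(prof, flat_epsilon)
        counts += np.bincount(idx, minlength=len(_MODULES))
    return counts / n_perm


def module_enrichment(observed: np.ndarray, null_means: np.ndarray,
                      n_genes: int, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided binomial enrichment test per module, Bonferroni over 81.

    Module m is tested with observed_count ~ Binomial(n_genes,
    null_mean_m / n_genes) against the upper tail; significance requires
    p < alpha/81 (strict) and an observed excess over the null mean.
    A null mean of zero is floored at 0.5 / n_genes so the test stays
    defined (continuity correction).
    """
    observed = np.asarray(observed, dtype=float)
    null_means = np.asarray(null_means, dtype=float)
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if int(round(observed.sum())) != n_genes:
        raise ValueError(
            f"observed counts sum to {observed.sum():.0f}, expected {n_genes}"
        )
    p0 = np.where(null_means > 0, null_means / n_genes, 0.5 / n_genes)
    p0 = np.minimum(p0, 1.0)
    pvals = stats.binom.sf(observed - 1, n_genes, p0)
    signif = (pvals < alpha / len(_MODULES)) & (observed > null_means)
    return pd.DataFrame({
        "module_id": _MODULE_IDS,
        "observed": observed.astype(int),
        "null_mean": null_means,
        "p_value": pvals,
        "significant": signif,
    })


@dataclass
class SharedModuleSet:
    """Modules enriched in both members of an interacting pair.

    ``pairs`` holds (module in stratum a, partner module in stratum b,
    relation), relation being ``parallel`` (same module) or
    ``antiparallel`` (partner is the negation). The flat module is its
    own negation and can only ever be parallel.
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def modules_a(self) -> set[str]:
        return {a for a, _, _ in self.pairs}

    @property
    def modules_b(self) -> set[str]:
        return {b for _, b, _ in self.pairs}


def shared_modules(enriched_a: set[str], enriched_b: set[str]) -> SharedModuleSet:
    """Parallel and anti-parallel shared modules between two enriched sets."""
    for m in set(enriched_a) | set(enriched_b):
        if m not in _MODULE_INDEX:
            raise ValueError(f"unknown module id {m!r}")
    pairs = []
    for m in sorted(enriched_a):
        if m in enriched_b:
            pairs.append((m, m, "parallel"))
        neg = negate_module_id(m)
        if neg in enriched_b and neg != m:
            pairs.append((m, neg, "antiparallel"))
    return SharedModuleSet(pairs)


def shared_gene_counts(assignment_a: pd.DataFrame, assignment_b: pd.DataFrame,
                       shared: SharedModuleSet) -> dict[str, dict[str, float]]:
    """Per-stratum counts and fractions of genes in shared modules.

    A gene is counted once even if its module participates in both a
    parallel and an anti-parallel pair.
    """
    out = {}
    for side, assignment, mods in [
        ("a", assignment_a, shared.modules_a),
        ("b", assignment_b, shared.modules_b),
    ]:
        n = len(assignment)
        count = int(assignment["module_id"].isin(mods).sum())
        out[side] = {"count": count, "total": n,
                     "fraction": count / n if n else 0.0}
    return out


def run_module_enrichment(expr: ExpressionMatrix, tissue: str,
                          nurse_type: str | None = None,
                          caste: str | None = None, *,
                          n_perm: int = 1000, seed: int = 0,
                          pseudocount: float = 1.0,
                          flat_epsilon: float = 1e-8,
                          alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stratum workflow: stage means -> profiles -> assignment -> enrichment.

    Returns (assignment DataFrame, enrichment report DataFrame).
    """
    means = stage_means(expr, tissue, nurse_type, caste)
    prof = log2fc_profiles(means, pseudocount)
    assignment = assign_profiles(prof, flat_epsilon)
    observed = module_counts(assignment)
    null = permuted_null_counts(means, n_perm, seed, pseudocount, flat_epsilon)
    report = module_enrichment(observed, null, len(assignment), alpha)
    return assignment, report


@dataclass
class JackknifeEstimate:
    """Leave-one-out jackknife summary for one shared-gene fraction."""

    estimate: float           # jackknife mean of leave-one-out replicates
    se: float
    ci_low: float
    ci_high: float
    full_value: float         # value computed on the full sample set
    replicates: np.ndarray


def _jackknife_ci(values: np.ndarray, full_value: float) -> JackknifeEstimate:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = values.mean()
    se = float(np.sqrt((n - 1) / n * ((values - mean) ** 2).sum()))
    return JackknifeEstimate(float(mean), se, float(mean - 1.96 * se),
                             float(mean + 1.96 * se), full_value, values)


def jackknife_shared_counts(expr: ExpressionMatrix, nurse_tissue: str,
                            nurse_type: str = "stage_specific", *,
                            larva_caste: str = "worker",
                            n_perm: int = 1000, seed: int = 0,
                            pseudocount: float = 1.0,
                            flat_epsilon: float = 1e-8,
                            alpha: float = 0.05) -> dict[str, JackknifeEstimate]:
    """Drop-1 jackknife CIs for the genes-in-shared-modules fractions.

    The larval stratum is held fixed; each nurse sample of the requested
    stratum is dropped once and the nurse-side profile -> assignment ->
    enrichment -> shared-count chain is re-run. The confidence interval
    is jackknife mean +/- 1.96 x jackknife SE with the standard
    leave-one-out SE formula. Keys of the result: ``larva`` and
    ``nurse`` side fractions.
    """
    nurse_stratum = expr.select(tissue=nurse_tissue, nurse_type=nurse_type)
    nurse_ids = list(nurse_stratum.samples.index)
    if len(nurse_ids) < 3:
        raise DataValidationError(
            f"need >= 3 nurse samples for jackknifing, found {len(nurse_ids)}"
        )

    larva_assign, larva_report = run_module_enrichment(
        expr, "larva", caste=larva_caste, n_perm=n_perm, seed=seed,
        pseudocount=pseudocount, flat_epsilon=flat_epsilon, alpha=alpha)
    larva_enriched = set(larva_report.loc[larva_report["significant"], "module_id"])

    def nurse_run(sub: ExpressionMatrix) -> tuple[float, float]:
        assign, report = run_module_enrichment(
            sub, nurse_tissue, nurse_type=nurse_type, n_perm=n_perm,
            seed=seed + 1, pseudocount=pseudocount,
            flat_epsilon=flat_epsilon, alpha=alpha)
        enriched = set(report.loc[report["significant"], "module_id"])
        shared = shared_modules(larva_enriched, enriched)
        counts = shared_gene_counts(larva_assign, assign, shared)
        return counts["a"]["fraction"], counts["b"]["fraction"]

    full_larva, full_nurse = nurse_run(expr)
    reps = []
    for sid in nurse_ids:
        keep = [c for c in expr.values.columns if c != sid]
        sub = ExpressionMatrix(expr.values[keep], expr.samples.loc[keep])
        reps.append(nurse_run(sub))
    reps = np.array(reps)
    return {
        "larva": _jackknife_ci(reps[:, 0], full_larva),
        "nurse": _jackknife_ci(reps[:, 1], full_nurse),
    }
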