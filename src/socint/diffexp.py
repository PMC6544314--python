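"""Stage-associated differential expression and design-based tests.

Identifies genes whose expression tracks larval developmental stage
within one stratum (larvae by their own stage, nurses by the stage of
larvae they fed), applies the random-nurse control filter, and selects
the top candidates for network reconstruction. Also provides the
binary-group test (e.g. queen presence) and the ordinal stage x group
interaction test.

Model family: inputs are FPKM-like abundances, so the default is a
Gaussian linear model on asinh-transformed abundance with stage and
within-stage replicate terms, compared by a nested-model test. The
reported ``statistic`` is the likelihood-ratio chi-square
``n * ln(RSS0/RSS1)``; the reported p-value comes from the exact F
distribution of the same nested comparison (a monotone transform of the
likelihood ratio that is correctly calibrated at the small per-stratum
sample sizes where the chi-square asymptotics are anticonservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, STAGES

__all__ = [
    "DesignError",
    "stage_association_test",
    "group_association_test",
    "candidate_selection",
    "CandidateSet",
    "interaction_test",
    "InteractionResult",
]


class DesignError(ValueError):
    """Raised when the sample design cannot support the requested test."""


def _dummies(labels: pd.Series) -> np.ndarray:
    """Drop-first dummy coding; empty (0-column) if the factor has one level."""
    d = pd.get_dummies(labels.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def _nested_lm_scan(Y: np.ndarray, X_full: np.ndarray,
                    X_red: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized nested-linear-model comparison over all genes at once.

    Y is samples x genes. Returns (LR chi2 statistic, F-based p-value,
    df of the tested term). Constant genes (no residual variance under
    either model) get statistic 0 and p 1.
    """
    n = Y.shape[0]
    df_full = int(np.linalg.matrix_rank(X_full))
    df_red = int(np.linalg.matrix_rank(X_red))
    df_diff = df_full - df_red
    if df_diff == 0:
        raise DesignError("tested term adds no degrees of freedom "
                          "(completely confounded design)")
    if n - df_full <= 0:
        raise DesignError("no residual degrees of freedom")

    def rss(X: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        return (resid ** 2).sum(axis=0)

    rss_f = rss(X_full)
    rss_r = rss(X_red)
    scale = (Y ** 2).sum(axis=0) + 1.0
    tiny = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_r - rss_f) / df_diff) / (rss_f / (n - df_full))
        pvals = stats.f.sf(f_stat, df_diff, n - df_full)
        chi2 = n * np.log(rss_r / rss_f)
    degenerate = rss_f < tiny
    flat = degenerate & (rss_r - rss_f < tiny)
    separated = degenerate & ~flat
    pvals = np.where(flat, 1.0, pvals)
    chi2 = np.where(flat, 0.0, chi2)
    pvals = np.where(separated, np.finfo(float).tiny, pvals)
    chi2 = np.where(separated, np.inf, chi2)
    return chi2, pvals, df_diff


def _replicate_factor(meta: pd.DataFrame) -> pd.Series:
    """Within-stage replicate index derived from colony labels.

    Colonies are nested in stages (each colony is sampled once), so the
    raw colony factor would absorb the stage effect entirely. The
    replicate index (rank of the colony within its stage, by sorted
    label) gives a crossed stage x replicate layout that blocks on the
    sampling slot while leaving the stage term testable.
    """
    rep = pd.Series(index=meta.index, dtype=object)
    for s in meta["stage"].unique():
        ids = meta.index[meta["stage"] == s]
        order = {c: i for i, c in enumerate(sorted(meta.loc[ids, "colony"]))}
        rep[ids] = [f"r{order[c]}" for c in meta.loc[ids, "colony"]]
    return rep


def _prepare(expr: ExpressionMatrix, tissue: str | None, nurse_type: str | None,
             caste: str | None, transform: str) -> tuple[np.ndarray, pd.DataFrame]:
    sub = expr.select(tissue=tissue, nurse_type=nurse_type, caste=caste)
    if transform == "asinh":
        Y = np.arcsinh(sub.values.to_numpy(float)).T
    elif transform == "none":
        Y = sub.values.to_numpy(float).T
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return Y, sub


def stage_association_test(expr: ExpressionMatrix, tissue: str,
                           nurse_type: str | None = None,
                           caste: str | None = None,
                           transform: str = "asinh") -> pd.DataFrame:
    """Per-gene test of the developmental-stage factor within one stratum.

    Nested comparison of ``~ stage + replicate`` against ``~ replicate``.
    Returns a DataFrame indexed by gene id with columns ``statistic``
    (LR chi2) and ``p_value`` (uncorrected, matching the pipeline's
    nominal-p candidate screen).
    """
    Y, sub = _prepare(expr, tissue, nurse_type, caste, transform)
    meta = sub.samples
    n_stages = meta["stage"].nunique()
    if n_stages < 2:
        raise DesignError(f"need >= 2 stages with samples, found {n_stages}")
    rep = _replicate_factor(meta)
    intercept = np.ones((len(meta), 1))
    X_red = np.column_stack([intercept, _dummies(rep)])
    X_full = np.column_stack([X_red, _dummies(meta["stage"])])
    chi2, p, _ = _nested_lm_scan(Y, X_full, X_red)
    return pd.DataFrame({"statistic": chi2, "p_value": p},
                        index=sub.values.index.rename("gene_id"))


def group_association_test(expr: ExpressionMatrix, factor: str = "queen_present",
                           tissue: str | None = None,
                           nurse_type: str | None = None,
                           caste: str | None = None,
                           transform: str = "asinh") -> pd.DataFrame:
    """Per-gene test of a binary sample factor, controlling for stage.

    Same model family as the stage test with the binary factor as the
    tested term (``~ stage + factor`` vs ``~ stage``). Adds a
    Benjamini-Hochberg ``fdr`` column.
    """
    Y, sub = _prepare(expr, tissue, nurse_type, caste, transform)
    meta = sub.samples
    levels = meta[factor].nunique()
    if levels < 2:
        raise DesignError(f"factor {factor!r} has a single level")
    intercept = np.ones((len(meta), 1))
    X_red = np.column_stack([intercept, _dummies(meta["stage"])])
    X_full = np.column_stack([X_red, _dummies(meta[factor])])
    chi2, p, _ = _nested_lm_scan(Y, X_full, X_red)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"statistic": chi2, "p_value": p, "fdr": fdr},
                        index=sub.values.index.rename("gene_id"))


@dataclass
class CandidateSet:
    """Ordered candidate genes for network reconstruction."""

    genes: list[str]
    complete: bool      # False if fewer than k genes qualified


def candidate_selection(de_ss: pd.DataFrame, de_random: pd.DataFrame,
                        alpha: float = 0.05, k: int = 1000) -> CandidateSet:
    """Random-nurse-filtered top-k stage-associated genes.

    Drops genes significant (p < alpha) in *both* the stage-specific and
    the random-nurse scan (colony-specific effects not tied to larval
    development), then returns the k smallest stage-specific p-values
    among the remaining significant genes, ties broken by gene id.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    p_ss = de_ss["p_value"]
    p_rand = de_random["p_value"].reindex(p_ss.index).astype(float).fillna(1.0)
    both = (p_ss < alpha) & (p_rand < alpha)
    eligible = (p_ss < alpha) & ~both
    ranked = sorted(p_ss.index[eligible], key=lambda g: (p_ss[g], g))
    return CandidateSet(genes=ranked[:k], complete=len(ranked) >= k)


@dataclass
class InteractionResult:
    chi2: float
    df: int
    p_value: float


def _to_long(profile) -> pd.DataFrame:
    """Accept a colony x 5 array or a tidy (colony, stage, value) frame."""
    if isinstance(profile, pd.DataFrame) and {"stage", "value"} <= set(profile.columns):
        out = profile.copy()
        out["stage_ord"] = out["stage"].map({s: i for i, s in enumerate(STAGES)})
        return out[["stage_ord", "value"]]
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(STAGES):
        raise ValueError("expected a colony x 5 array or tidy frame")
    rows = [{"stage_ord": s, "value": arr[c, s]}
            for c in range(arr.shape[0]) for s in range(arr.shape[1])]
    return pd.DataFrame(rows)


def interaction_test(profile_a, profile_b) -> InteractionResult:
    """Ordinal stage x group interaction test between two sample groups.

    Fits ``value ~ stage_ord * group`` and compares against the
    additive model. Stage is treated as an ordinal (0..4) covariate.
    """
    a, b = _to_long(profile_a), _to_long(profile_b)
    for name, d in [("a", a), ("b", b)]:
        if d["stage_ord"].nunique() < 3:
            raise DesignError(f"group {name} spans fewer than 3 stages")
    long = pd.concat([a.assign(group=0.0), b.assign(group=1.0)],
                     ignore_index=True)
    y = long["value"].to_numpy(float)[:, None]
    s = long["stage_ord"].to_numpy(float)
    g = long["group"].to_numpy(float)
    ones = np.ones_like(s)
    X_red = np.column_stack([ones, s, g])
    X_full = np.column_stack([ones, s, g, s * g])
    n = len(y)
    if n - 4 <= 0:
        raise DesignError("insufficient residual degrees of freedom")
    chi2, p, df = _nested_lm_scan(y, X_full, X_red)
    return InteractionResult(float(chi2[0]), df, float(p[0]))
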