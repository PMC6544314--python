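"""Statistics relating network position to molecular evolution.

Connects the connectivity measures from network inference with per-gene
annotations: Spearman correlations of selective constraint against
within-tissue connectivity, social connectivity and the sociality
index; rank-based group contrasts (e.g. secreted vs non-secreted
orthologs); a Gaussian GLM of sociality index on evolutionary age class,
constraint and tissue with drop-one likelihood-ratio tests and
Tukey-style post-hoc age contrasts; percentile bootstrap CIs for class
means; and flat Kolmogorov-Smirnov gene-set enrichment on connectivity.

Missing annotations are dropped pairwise; the reported ``n`` always
equals the rows actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "connectivity_constraint_correlations",
    "group_contrast",
    "sociality_age_glm",
    "bootstrap_class_means",
    "ks_set_enrichment",
]


@dataclass
class StatResult:
    """One test outcome: statistic, p, size and effect direction."""

    name: str
    statistic: float
    p_value: float
    n: int
    direction: str = "none"              # positive / negative / none
    groups: tuple[str, ...] | None = None
    defined: bool = True


CONNECTIVITY_MEASURES = ("within_connectivity", "social_connectivity",
                         "sociality_index")


def connectivity_constraint_correlations(conn: pd.DataFrame,
                                         ann: pd.DataFrame) -> list[StatResult]:
    """Spearman rho of selective constraint vs each connectivity measure.

    ``conn`` is a connectivity table (per-gene rows with a ``tissue``
    column and the three measures); results are reported per tissue.
    A constant column is flagged as undefined instead of tested.
    """
    merged = conn.reset_index(drop=True).merge(
        ann[["constraint"]], left_on="gene_id", right_index=True, how="left")
    results = []
    for tissue, sub in merged.groupby("tissue", sort=True):
        for measure in CONNECTIVITY_MEASURES:
            d = sub[[measure, "constraint"]].dropna()
            n = len(d)
            name = f"constraint_vs_{measure}[{tissue}]"
            if n < 10:
                results.append(StatResult(name, np.nan, np.nan, n,
                                          defined=False))
                continue
            if d[measure].nunique() == 1 or d["constraint"].nunique() == 1:
                results.append(StatResult(name, np.nan, np.nan, n,
                                          defined=False))
                continue
            rho, p = stats.spearmanr(d[measure], d["constraint"])
            direction = "positive" if rho > 0 else ("negative" if rho < 0 else "none")
            results.append(StatResult(name, float(rho), float(p), n, direction))
    return results


def group_contrast(values, groups, paired: bool = False,
                   name: str = "group_contrast") -> StatResult:
    """Rank-based two-group contrast.

    Unpaired data get a Wilcoxon rank-sum (Mann-Whitney U) test; paired
    data a Wilcoxon signed-rank test. Direction follows the median
    difference (group 1 minus group 0 / paired difference).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired contrast requires equal group sizes")
        diff = b - a
        if np.all(diff == 0):
            warnings.warn("all paired differences are zero", stacklevel=2)
            return StatResult(name, 0.0, 1.0, len(diff), "none",
                              tuple(map(str, levels)))
        stat, p = stats.wilcoxon(b, a)
        med = float(np.median(diff))
    else:
        if np.ptp(values) == 0:
            warnings.warn("all values tied", stacklevel=2)
            return StatResult(name, np.nan, 1.0, len(values), "none",
                              tuple(map(str, levels)))
        stat, p = stats.mannwhitneyu(b, a, alternative="two-sided")
        med = float(np.median(b) - np.median(a))
    direction = "positive" if med > 0 else ("negative" if med < 0 else "none")
    return StatResult(name, float(stat), float(p), len(a) + len(b), direction,
                      tuple(map(str, levels)))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ coef) ** 2).sum())


def sociality_age_glm(data: pd.DataFrame,
                      response: str = "sociality_index"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GLM of sociality index on age class + constraint (+ tissue), with post hoc.

    Fits a Gaussian linear model and performs a drop-one
    likelihood-ratio test per term (statistic ``n ln(RSS0/RSS1)``,
    p-value from the exact F distribution of the nested comparison).
    Pairwise age-class contrasts use Tukey's HSD on the response by age
    class. ``data`` needs columns ``age_class``, ``constraint`` and the
    response; a ``tissue`` column is included as a covariate when
    present with >1 level. Rows with missing values are dropped.

    Returns (per-term LRT table, Tukey pairwise table).
    """
    cols = [response, "age_class", "constraint"]
    has_tissue = "tissue" in data.columns and data["tissue"].nunique() > 1
    if has_tissue:
        cols.append("tissue")
    d = data[cols].dropna().copy()
    ages = sorted(d["age_class"].unique())
    if len(ages) < 2:
        raise ValueError("need >= 2 age classes present")
    y = d[response].to_numpy(float)
    n = len(y)

    blocks: dict[str, np.ndarray] = {
        "age_class": pd.get_dummies(d["age_class"], drop_first=True,
                                    dtype=float).to_numpy(),
        "constraint": d["constraint"].to_numpy(float)[:, None],
    }
    if has_tissue:
        blocks["tissue"] = pd.get_dummies(d["tissue"], drop_first=True,
                                          dtype=float).to_numpy()
    intercept = np.ones((n, 1))
    X_full = np.column_stack([intercept] + list(blocks.values()))
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        raise ValueError("rank-deficient design: some terms are aliased "
                         f"(rank {rank_full} < {X_full.shape[1]} columns)")
    rss_full = _rss(X_full, y)
    df_resid = n - rank_full

    rows = []
    for term in blocks:
        X_red = np.column_stack(
            [intercept] + [b for t, b in blocks.items() if t != term])
        rss_red = _rss(X_red, y)
        df_term = X_full.shape[1] - X_red.shape[1]
        chi2 = n * np.log(rss_red / rss_full)
        f_stat = ((rss_red - rss_full) / df_term) / (rss_full / df_resid)
        p = stats.f.sf(f_stat, df_term, df_resid)
        rows.append({"term": term, "chi2": chi2, "df": df_term,
                     "p_value": p, "n": n})
    terms = pd.DataFrame(rows).set_index("term")

    tukey = pairwise_tukeyhsd(y, d["age_class"].to_numpy())
    posthoc = pd.DataFrame(tukey.summary().data[1:],
                           columns=[str(c) for c in tukey.summary().data[0]])
    posthoc = posthoc.rename(columns={"p-adj": "p_adj"})
    return terms, posthoc


def bootstrap_class_means(values, labels, n_boot: int = 1000,
                          seed: int = 0) -> pd.DataFrame:
    """Percentile-bootstrap 95% CIs of the per-class mean.

    Classes of size 1 get a degenerate (zero-width) CI and a flag.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for cls in np.unique(labels):
        v = values[labels == cls]
        v = v[~np.isnan(v)]
        m = len(v)
        if m == 0:
            continue
        mean = float(v.mean())
        if m == 1:
            rows.append({"class": cls, "n": m, "mean": mean, "ci_low": mean,
                         "ci_high": mean, "degenerate": True})
            continue
        boots = rng.choice(v, size=(n_boot, m), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"class": cls, "n": m, "mean": mean,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("class")


def ks_set_enrichment(values: pd.Series, sets: dict[str, list[str]],
                      min_size: int = 5) -> pd.DataFrame:
    """Two-sample KS enrichment of gene sets on a per-gene score.

    For each set, members' values are compared against non-members'
    (flat enrichment, no graph structure); p-values are unadjusted and
    the direction is the sign of the member-minus-nonmember median
    difference. Sets with fewer than ``min_size`` members or
    non-members among the scored genes are skipped with a flag; a set
    equal to all genes is an error.
    """
    values = values.dropna()
    universe = set(values.index)
    rows = []
    for set_id, members in sets.items():
        inset = sorted(universe & set(members))
        outset = sorted(universe - set(members))
        if not outset:
            raise ValueError(f"set {set_id!r} covers every scored gene")
        if len(inset) < min_size or len(outset) < min_size:
            rows.append({"set_id": set_id, "n_set": len(inset),
                         "statistic": np.nan, "p_value": np.nan,
                         "direction": "none", "skipped": True})
            continue
        a = values.loc[inset].to_numpy()
        b = values.loc[outset].to_numpy()
        try:
            stat, p = stats.ks_2samp(a, b, method="exact")
        except (ValueError, OverflowError):   # pragma: no cover - fallback
            stat, p = stats.ks_2samp(a, b, method="asymp")
        med = float(np.median(a) - np.median(b))
        rows.append({
            "set_id": set_id, "n_set": len(inset), "statistic": float(stat),
            "p_value": float(p),
            "direction": "positive" if med > 0 else
            ("negative" if med < 0 else "none"),
            "skipped": False,
        })
    return pd.DataFrame(rows).set_index("set_id")
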