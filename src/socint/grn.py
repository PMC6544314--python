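"""Social gene regulatory network inference from nurse+larva meta-samples.

Meta-samples join the larval and nurse expression vectors from the same
colony and time point into one observation, with features labeled by
tissue of expression (the dual-transcriptome trick used in
host-symbiont studies). A per-target random-forest regression then
scores every other feature's importance for predicting each target
gene, yielding a directed importance matrix: entry (i, j) is the
regulatory effect of gene i on gene j. Averaging each gene's outgoing
importances over same-tissue targets gives within-tissue connectivity;
over other-tissue targets, social connectivity; their difference is the
sociality index.

The forest follows the GENIE3 recipe: each feature standardized to unit
variance, ``floor(sqrt(p - 1))`` candidate features per split,
importance measured as bootstrap-weighted total variance reduction
divided by tree count, no per-target renormalization, and the whole
reconstruction repeated over independently seeded runs whose matrices
are averaged (the algorithm is stochastic). Trees are grown by a
numba-compiled CART kernel so that repeated full reconstructions stay
cheap on a single core; the kernel is validated against sklearn's
random-forest importances in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .datamodel import DataValidationError, ExpressionMatrix

__all__ = [
    "MetaSampleMatrix",
    "RegulatoryMatrix",
    "build_meta_samples",
    "infer_regulatory_matrix",
    "connectivity_summary",
    "cross_tissue_gene_correlation",
    "SpearmanPair",
    "ranking_auroc",
]


# ----------------------------------------------------------------------
# numba CART kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _grow_tree(X, y, samples, k, inv_n, importance):  # pragma: no cover - numba
    n_node_total = samples.shape[0]
    p = X.shape[1]
    stack_s = np.empty(2 * n_node_total + 16, np.int64)
    stack_e = np.empty(2 * n_node_total + 16, np.int64)
    stack_s[0] = 0
    stack_e[0] = n_node_total
    top = 1
    feat = np.empty(p, np.int64)
    v = np.empty(n_node_total, np.float64)
    while top > 0:
        top -= 1
        s = stack_s[top]
        e = stack_e[top]
        m = e - s
        if m < 2:
            continue
        sy = 0.0
        sy2 = 0.0
        for ii in range(s, e):
            yy = y[samples[ii]]
            sy += yy
            sy2 += yy * yy
        if sy2 / m - (sy / m) ** 2 <= 1e-12:
            continue
        for f in range(p):
            feat[f] = f
        evaluated = 0
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for t in range(p):
            r = t + int(np.random.random() * (p - t))
            if r >= p:
                r = p - 1
            tmp = feat[t]
            feat[t] = feat[r]
            feat[r] = tmp
            f = feat[t]
            vmin = X[samples[s], f]
            vmax = vmin
            for ii in range(m):
                val = X[samples[s + ii], f]
                v[ii] = val
                if val < vmin:
                    vmin = val
                if val > vmax:
                    vmax = val
            if vmax - vmin <= 0.0:
                continue
            evaluated += 1
            order = np.argsort(v[:m], kind="mergesort")
            sl = 0.0
            best_local = -1.0
            thr_local = 0.0
            for ii in range(m - 1):
                o = order[ii]
                sl += y[samples[s + o]]
                if v[order[ii + 1]] - v[o] <= 0.0:
                    continue
                i_split = ii + 1
                sr = sy - sl
                score = sl * sl / i_split + sr * sr / (m - i_split)
                if score > best_local:
                    best_local = score
                    thr_local = 0.5 * (v[o] + v[order[ii + 1]])
            if best_local >= 0.0:
                dec = (best_local - sy * sy / m) / m
                if dec > best_gain:
                    best_gain = dec
                    best_f = f
                    best_thr = thr_local
            if evaluated >= k:
                break
        if best_f < 0 or best_gain <= 0.0:
            continue
        importance[best_f] += (m * inv_n) * best_gain
        i = s
        j = e - 1
        while i <= j:
            if X[samples[i], best_f] <= best_thr:
                i += 1
            else:
                tmp2 = samples[i]
                samples[i] = samples[j]
                samples[j] = tmp2
                j -= 1
        stack_s[top] = s
        stack_e[top] = i
        top += 1
        stack_s[top] = i
        stack_e[top] = e
        top += 1


@njit(cache=True)
def _forest_importance(X, y, k, n_trees, seeds):  # pragma: no cover - numba
    n, p = X.shape
    imp = np.zeros(p)
    inv_n = 1.0 / n
    samples = np.empty(n, np.int64)
    for t in range(n_trees):
        np.random.seed(seeds[t])
        for i in range(n):
            samples[i] = np.random.randint(0, n)
        _grow_tree(X, y, samples, k, inv_n, imp)
    return imp / n_trees


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class MetaSampleMatrix:
    """Feature x observation matrix of asinh-transformed abundance.

    Features are tissue-labeled genes (``larva::g0001``); observations
    are complete (colony, stage) pairings with both a larval and a nurse
    sample.
    """

    values: pd.DataFrame
    feature_tissue: pd.Series           # feature -> tissue label
    observations: pd.DataFrame          # per-observation colony and stage

    @property
    def n_observations(self) -> int:
        return self.values.shape[1]


@dataclass
class RegulatoryMatrix:
    """Directed gene -> gene importance matrix averaged over runs.

    Entry (i, j) is the importance of feature i for predicting feature
    j; the diagonal is exactly zero and entries are non-negative
    (impurity-importance convention).
    """

    importances: pd.DataFrame
    feature_tissue: pd.Series
    n_runs_averaged: int


def feature_label(tissue: str, gene: str) -> str:
    return f"{tissue}::{gene}"


def build_meta_samples(expr: ExpressionMatrix, larval_genes: list[str],
                       nurse_genes: list[str], nurse_tissue: str,
                       nurse_type: str = "stage_specific",
                       larva_caste: str = "worker") -> MetaSampleMatrix:
    """Join larval and nurse expression per colony into meta-samples.

    Pairings lacking either member are dropped; fewer than 3 complete
    pairings is an error.
    """
    larva = expr.select(tissue="larva", caste=larva_caste)
    nurse = expr.select(tissue=nurse_tissue, nurse_type=nurse_type)
    l_by_col = {c: sid for sid, c in larva.samples["colony"].items()}
    n_by_col = {c: sid for sid, c in nurse.samples["colony"].items()}
    common = sorted(set(l_by_col) & set(n_by_col),
                    key=lambda c: (larva.samples.loc[l_by_col[c], "stage"], c))
    if len(common) < 3:
        raise DataValidationError(
            f"only {len(common)} complete larva/{nurse_tissue} pairings; need >= 3"
        )
    l_vals = np.arcsinh(larva.values.loc[larval_genes,
                                         [l_by_col[c] for c in common]].to_numpy(float))
    n_vals = np.arcsinh(nurse.values.loc[nurse_genes,
                                         [n_by_col[c] for c in common]].to_numpy(float))
    features = ([feature_label("larva", g) for g in larval_genes]
                + [feature_label(nurse_tissue, g) for g in nurse_genes])
    values = pd.DataFrame(np.vstack([l_vals, n_vals]), index=features,
                          columns=common)
    tissue = pd.Series(["larva"] * len(larval_genes)
                       + [nurse_tissue] * len(nurse_genes), index=features)
    obs = pd.DataFrame({
        "colony": common,
        "stage": [larva.samples.loc[l_by_col[c], "stage"] for c in common],
    }).set_index("colony")
    return MetaSampleMatrix(values, tissue, obs)


def infer_regulatory_matrix(meta: MetaSampleMatrix, n_trees: int = 1000,
                            n_runs: int = 1, seed: int = 0) -> RegulatoryMatrix:
    """Per-target random-forest importances, averaged over ``n_runs`` runs.

    Each run re-fits every target's forest with seeds derived from
    (master seed, run index), and the full matrices are averaged. A
    zero-variance target yields a zero column with a warning.
    """
    if n_trees < 10:
        raise ValueError("n_trees must be >= 10")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    V = meta.values.to_numpy(float).T            # obs x features
    n, p = V.shape
    sd = V.std(axis=0)
    mean = V.mean(axis=0)
    zero_var = np.ptp(V, axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); their "
            "columns are set to 0", stacklevel=2)
    Vs = np.where(zero_var, 0.0, (V - mean) / np.where(zero_var, 1.0, sd))
    Vs = np.ascontiguousarray(Vs)
    k = max(1, int(np.sqrt(p - 1)))

    total = np.zeros((p, p))
    other_idx = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, run]))
        tree_seeds = rng.integers(1, 2 ** 31 - 1, size=(p, n_trees))
        mat = np.zeros((p, p))
        for j in range(p):
            if zero_var[j]:
                continue
            X = np.ascontiguousarray(Vs[:, other_idx[j]])
            imp = _forest_importance(X, np.ascontiguousarray(Vs[:, j]), k,
                                     n_trees, tree_seeds[j])
            mat[other_idx[j], j] = imp
        total += mat
    avg = total / n_runs
    np.fill_diagonal(avg, 0.0)
    feats = meta.values.index
    return RegulatoryMatrix(pd.DataFrame(avg, index=feats, columns=feats),
                            meta.feature_tissue.copy(), n_runs)


def connectivity_summary(reg: RegulatoryMatrix,
                         direction: str = "outgoing") -> pd.DataFrame:
    """Within-tissue and social connectivity per gene.

    For each gene i, within-tissue connectivity is the mean importance
    of i over same-tissue targets (j != i) and social connectivity the
    mean over other-tissue targets; the sociality index is their exact
    difference. ``direction="incoming"`` averages incoming effects
    instead (sensitivity switch).
    """
    if direction not in ("outgoing", "incoming"):
        raise ValueError("direction must be 'outgoing' or 'incoming'")
    A = reg.importances.to_numpy(float)
    if direction == "incoming":
        A = A.T
    feats = reg.importances.index
    tissues = reg.feature_tissue.loc[feats].to_numpy()
    rows = []
    for i, f in enumerate(feats):
        same = tissues == tissues[i]
        same_i = same.copy()
        same_i[i] = False
        within = A[i, same_i].mean() if same_i.any() else np.nan
        social = A[i, ~same].mean() if (~same).any() else np.nan
        rows.append({
            "feature": f,
            "gene_id": f.split("::", 1)[1],
            "tissue": tissues[i],
            "within_connectivity": within,
            "social_connectivity": social,
            "sociality_index": social - within,
        })
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class SpearmanPair:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def cross_tissue_gene_correlation(expr: ExpressionMatrix, gene_a: str,
                                  tissue_a: str, gene_b: str, tissue_b: str,
                                  nurse_type: str = "stage_specific",
                                  larva_caste: str = "worker") -> SpearmanPair:
    """Spearman correlation of two genes across complete colony pairings.

    Pairs the two strata by colony (each colony is one time point) and
    correlates gene_a's abundance in tissue_a with gene_b's in tissue_b.
    A constant vector leaves rho undefined and is flagged.
    """
    def stratum(tissue):
        if tissue == "larva":
            return expr.select(tissue="larva", caste=larva_caste)
        return expr.select(tissue=tissue, nurse_type=nurse_type)

    sa, sb = stratum(tissue_a), stratum(tissue_b)
    a_by_col = {c: sid for sid, c in sa.samples["colony"].items()}
    b_by_col = {c: sid for sid, c in sb.samples["colony"].items()}
    common = sorted(set(a_by_col) & set(b_by_col))
    if len(common) < 3:
        raise DataValidationError(
            f"only {len(common)} complete pairings; need >= 3")
    va = sa.values.loc[gene_a, [a_by_col[c] for c in common]].to_numpy(float)
    vb = sb.values.loc[gene_b, [b_by_col[c] for c in common]].to_numpy(float)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return SpearmanPair(np.nan, np.nan, len(common), defined=False)
    rho, p = stats.spearmanr(va, vb)
    return SpearmanPair(float(rho), float(p), len(common))


def ranking_auroc(scores, labels) -> float:
    """Area under the ROC curve for recovering labeled genes by a score."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(labels, dtype=int),
                               np.asarray(scores, dtype=float)))
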