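"""Core data containers, tabular I/O and expression-scale transforms.

The pipeline consumes FPKM-like gene x sample abundance tables together
with typed sample metadata describing the study design: worker-destined
larvae sampled across five developmental stages (L1..L5), the
stage-specific nurses that fed them (heads and abdomens sequenced
separately), and random nurses collected while feeding larvae of any
stage, which serve as a biological control. Each experimental colony is
sampled once, at the stage it was assigned to.

All downstream stages (module mining, differential expression, network
inference, evolutionary statistics) consume the :class:`ExpressionMatrix`
defined here, so validation is strict: abundances must be non-negative,
gene identifiers unique, and every expression column covered by a
metadata row.

File dialect: tab-separated, UTF-8, header row of sample ids, first
column gene ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "NURSE_TYPES",
    "STAGES",
    "CASTES",
    "METADATA_COLUMNS",
    "DataValidationError",
    "ExpressionMatrix",
    "load_expression",
    "write_expression",
    "load_annotations",
    "write_annotations",
    "stage_means",
    "log2fc_profiles",
    "stage_profiles",
    "asinh_transform",
    "expression_filter",
]

TISSUES = ("larva", "nurse_head", "nurse_abdomen")
NURSE_TYPES = ("stage_specific", "random", "not_applicable")
STAGES = ("L1", "L2", "L3", "L4", "L5")
CASTES = ("worker", "reproductive", "not_applicable")

METADATA_COLUMNS = [
    "sample_id",
    "tissue",
    "nurse_type",
    "stage",
    "colony",
    "caste",
    "queen_present",
]

ANNOTATION_COLUMNS = ["gene_id", "constraint", "age_class", "secreted", "gene_sets"]
AGE_CLASSES = ("ancient", "insect", "hymenoptera", "ant")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with typed sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM-like abundances, indexed by gene
        id, one column per sample id.
    samples
        DataFrame of sample metadata indexed by ``sample_id`` with
        columns ``tissue``, ``nurse_type``, ``stage``, ``colony``,
        ``caste``, ``queen_present``. Row order matches column order of
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # ------------------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        meta = self.samples
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene identifiers: {dups[:5]}")
        missing = [c for c in v.columns if c not in meta.index]
        if missing:
            raise DataValidationError(
                f"expression columns without metadata: {missing[:5]}"
            )
        # align metadata to column order
        if not meta.index.equals(pd.Index(v.columns)):
            name = meta.index.name
            self.samples = meta.loc[v.columns]
            self.samples.index.name = name
            meta = self.samples
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise DataValidationError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative abundance at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        for col, allowed in [
            ("tissue", TISSUES),
            ("nurse_type", NURSE_TYPES),
            ("stage", STAGES),
            ("caste", CASTES),
        ]:
            bad = set(meta[col]) - set(allowed)
            if bad:
                raise DataValidationError(f"invalid {col} values: {sorted(bad)}")
        larva = meta["tissue"] == "larva"
        if (meta.loc[larva, "nurse_type"] != "not_applicable").any():
            raise DataValidationError("larva samples must have nurse_type=not_applicable")
        if (meta.loc[~larva, "caste"] != "not_applicable").any():
            raise DataValidationError("nurse samples must have caste=not_applicable")
        key = meta[["tissue", "nurse_type", "stage", "colony"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise DataValidationError(
                f"duplicate (tissue, nurse_type, stage, colony) combination: {dup}"
            )

    # ------------------------------------------------------------------
    def select(self, **criteria) -> "ExpressionMatrix":
        """Return the sub-matrix of samples matching metadata criteria.

        Keyword values may be scalars or iterables, e.g.
        ``expr.select(tissue="larva", caste="worker")``.
        """
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            if val is None:
                continue
            if col not in self.samples.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.samples[col].isin(val)
            else:
                mask &= self.samples[col] == val
        ids = self.samples.index[mask]
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples.copy())


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise DataValidationError(f"cannot parse boolean value {x!r}")


def load_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV plus its sample-metadata TSV.

    Raises
    ------
    DataValidationError
        On missing metadata for a column (naming the column), on a
        non-numeric cell (with coordinates), on negative abundances or
        duplicate gene ids.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe = raw.apply(pd.to_numeric, errors="coerce")
    if probe.isna().any().any():
        bad = np.argwhere(probe.isna().to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell at gene {raw.index[bad[0]]!r}, "
            f"sample {raw.columns[bad[1]]!r} in {path}"
        )
    values = raw.astype(float)   # exact parse; to_numeric's fast path is lossy
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise DataValidationError(f"metadata missing columns: {missing_cols}")
    meta = meta.set_index("sample_id")
    meta["queen_present"] = meta["queen_present"].map(_parse_bool)
    uncovered = [c for c in values.columns if c not in meta.index]
    if uncovered:
        raise DataValidationError(
            f"no metadata row for expression column(s): {uncovered}"
        )
    meta = meta.loc[values.columns]
    meta.index.name = "sample_id"
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path) -> None:
    """Write the matrix and metadata as the TSV dialect `load_expression` reads."""
    # full-precision repr keeps the round-trip bitwise lossless
    expr.values.to_csv(path, sep="\t", index_label="gene_id",
                       float_format=lambda x: repr(float(x)))
    meta = expr.samples.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta[METADATA_COLUMNS].to_csv(metadata_path, sep="\t", index=False)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Load a per-gene annotation TSV.

    Columns: ``gene_id``, ``constraint`` (real in [0,1] or empty),
    ``age_class`` (ancient/insect/hymenoptera/ant or empty), ``secreted``
    (boolean or empty), ``gene_sets`` (semicolon-delimited ids).
    Returns a DataFrame indexed by gene id; ``gene_sets`` is a list.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str).set_index("gene_id")
    ann["constraint"] = pd.to_numeric(ann["constraint"], errors="raise")
    ok = ann["constraint"].dropna()
    if ((ok < 0) | (ok > 1)).any():
        bad = ok[(ok < 0) | (ok > 1)].index[0]
        raise DataValidationError(f"constraint outside [0,1] for gene {bad!r}")
    bad_age = set(ann["age_class"].dropna()) - set(AGE_CLASSES)
    if bad_age:
        raise DataValidationError(f"invalid age_class values: {sorted(bad_age)}")
    ann["secreted"] = ann["secreted"].map(
        lambda x: np.nan if pd.isna(x) or str(x) == "" else _parse_bool(x)
    )
    ann["gene_sets"] = ann["gene_sets"].map(
        lambda x: [] if pd.isna(x) or str(x) == "" else str(x).split(";")
    )
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["gene_sets"] = out["gene_sets"].map(";".join)
    out.to_csv(path, sep="\t", index_label="gene_id")


# ----------------------------------------------------------------------
# Transforms
# ----------------------------------------------------------------------

def stage_means(expr: ExpressionMatrix, tissue: str,
                nurse_type: str | None = None,
                caste: str | None = None) -> pd.DataFrame:
    """Per-stage mean abundance for one stratum.

    Returns a gene x 5 DataFrame (columns L1..L5), entry (g, s) being the
    arithmetic mean of gene g over the stratum's samples of stage s.
    Raises if any stage has zero samples in the stratum.
    """
    sub = expr.select(tissue=tissue, nurse_type=nurse_type, caste=caste)
    empty = [s for s in STAGES if (sub.samples["stage"] == s).sum() == 0]
    if empty:
        raise DataValidationError(
            f"stratum tissue={tissue!r} nurse_type={nurse_type!r} has no "
            f"samples for stage(s): {empty}"
        )
    cols = {}
    for s in STAGES:
        ids = sub.samples.index[sub.samples["stage"] == s]
        cols[s] = sub.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def log2fc_profiles(means: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Stage profiles: log2 fold-change of each stage mean vs. the L1 mean.

    ``profile[s] = log2((mean_s + pc) / (mean_L1 + pc))``; the first
    entry is exactly 0. The pseudocount keeps zero-expression stages
    finite (default 1.0 on the FPKM scale).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arr = means.to_numpy(float)
    prof = np.log2((arr + pseudocount) / (arr[:, :1] + pseudocount))
    prof[:, 0] = 0.0
    return pd.DataFrame(prof, index=means.index, columns=list(STAGES))


def stage_profiles(expr: ExpressionMatrix, tissue: str,
                   nurse_type: str | None = None, caste: str | None = None,
                   pseudocount: float = 1.0,
                   method: str = "ratio_of_means") -> pd.DataFrame:
    """Observed gene stage profiles for a stratum.

    ``method="ratio_of_means"`` (default) averages abundance within each
    stage first and then takes the log ratio to L1 -- robust to
    single-replicate zeros. ``method="geometric"`` averages per-sample
    ``log2(x + pc)`` within stages and differences against L1.
    """
    if method == "ratio_of_means":
        return log2fc_profiles(stage_means(expr, tissue, nurse_type, caste),
                               pseudocount)
    if method == "geometric":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        sub = expr.select(tissue=tissue, nurse_type=nurse_type, caste=caste)
        empty = [s for s in STAGES if (sub.samples["stage"] == s).sum() == 0]
        if empty:
            raise DataValidationError(f"no samples for stage(s): {empty}")
        logv = np.log2(sub.values + pseudocount)
        cols = {
            s: logv[sub.samples.index[sub.samples["stage"] == s]].mean(axis=1)
            for s in STAGES
        }
        prof = pd.DataFrame(cols)
        prof = prof.sub(prof["L1"], axis=0)
        prof["L1"] = 0.0
        return prof
    raise ValueError(f"unknown method {method!r}")


def asinh_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse hyperbolic sine transform of abundance (variance stabilizing).

    Maps x to ln(x + sqrt(x^2 + 1)); monotone, 0 -> 0, ~ln(2x) for large x.
    """
    return ExpressionMatrix(np.arcsinh(expr.values), expr.samples.copy())


def expression_filter(expr: ExpressionMatrix, min_mean: float = 1.0,
                      min_stages: int = 1,
                      tissue: str | None = None,
                      nurse_type: str | None = None,
                      caste: str | None = None) -> list[str]:
    """Genes whose per-stage mean abundance is >= ``min_mean`` in >= ``min_stages`` stages.

    Means are computed over the (optionally stratum-restricted) samples,
    grouped by stage. Returns the retained gene ids in input order.
    """
    if min_mean < 0 or min_stages < 0:
        raise ValueError("thresholds must be >= 0")
    sub = expr if (tissue is None and nurse_type is None and caste is None) else \
        expr.select(tissue=tissue, nurse_type=nurse_type, caste=caste)
    by_stage = sub.values.T.groupby(sub.samples["stage"]).mean().T
    keep = (by_stage >= min_mean).sum(axis=1) >= min_stages
    return list(sub.values.index[keep])
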