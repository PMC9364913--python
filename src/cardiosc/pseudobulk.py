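"""Sample-level pseudobulk aggregation and median-of-ratios normalization.

Raw per-cell counts are summed per gene within each sample, turning the
single-cell experiment into one bulk-like profile per subject.  Size factors
follow the median-of-ratios convention: the reference for each gene is its
geometric mean across samples (over genes positive in every sample), and a
sample's factor is the median of its ratios to that reference.  Downstream
transforms divide by the factor and take ``log2(x + 1)``; output metadata
records that the log transform is the plain shifted log of normalized
counts, not a variance-stabilizing regularized log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

SAMPLE_META_COLUMNS = ("condition", "sex", "age", "modality")


@dataclass
class PseudobulkMatrix:
    """Gene x sample summed counts with per-sample metadata."""

    values: np.ndarray  # int64, genes x samples
    gene_ids: list[str]
    sample_ids: list[str]
    meta: pd.DataFrame  # indexed by sample_id
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("pseudobulk dimensions do not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("pseudobulk counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValidationError("size factors must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def aggregate_pseudobulk(
    counts: CountMatrix,
    ann: pd.DataFrame,
    subset: list[str] | None = None,
    min_cells_warn: int = 10,
) -> PseudobulkMatrix:
    """Sum counts per gene within each sample.

    *subset* optionally restricts to cells whose ``cluster`` label is in the
    given list (e.g. one cell type).  Samples left without cells are dropped
    with a warning; samples with fewer than *min_cells_warn* cells are kept
    but warned about.  The grand total of the output equals the grand total
    of the selected cells exactly.
    """
    ann = ann.loc[counts.cell_ids]
    if subset is not None:
        known = set(ann["cluster"])
        unknown = set(subset) - known
        if unknown:
            raise ValidationError(f"subset names unknown cluster(s): {sorted(unknown)}")
        keep = ann["cluster"].isin(subset).to_numpy()
        counts = counts.subset_cells(keep)
        ann = ann.loc[keep]
    if counts.n_cells == 0:
        raise ValidationError("no cells left to aggregate")

    sample_ids = sorted(ann["sample_id"].unique())
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    # sparse matmul against a cell->sample indicator does the per-sample sums
    indicator = np.zeros((counts.n_cells, len(sample_ids)), dtype=np.int64)
    col = ann["sample_id"].map(sample_pos).to_numpy()
    indicator[np.arange(counts.n_cells), col] = 1
    values = np.asarray(counts.values @ indicator, dtype=np.int64)

    meta_rows = {}
    n_cells = ann.groupby("sample_id").size()
    for s in sample_ids:
        sub = ann[ann["sample_id"] == s]
        for c in ("condition", "sex", "modality"):
            if sub[c].nunique() != 1:
                raise ValidationError(f"sample {s} has inconsistent {c!r} metadata")
        meta_rows[s] = {
            "condition": sub["condition"].iloc[0],
            "sex": sub["sex"].iloc[0],
            "age": float(sub["age"].iloc[0]),
            "modality": sub["modality"].iloc[0],
            "n_cells": int(n_cells[s]),
        }
        if n_cells[s] < min_cells_warn:
            logger.warning(
                "sample %s has only %d cells after subsetting", s, n_cells[s]
            )
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    logger.info(
        "aggregated %d cells into %d pseudobulk samples", counts.n_cells, len(sample_ids)
    )
    return PseudobulkMatrix(values, list(counts.gene_ids), sample_ids, meta)


def estimate_size_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    Restricted to genes positive in every sample; the per-gene reference is
    the geometric mean across samples.
    """
    if pb.n_samples < 2:
        raise ValidationError("size factors need at least 2 samples")
    v = pb.values.astype(float)
    all_pos = np.all(v > 0, axis=1)
    if not all_pos.any():
        raise ValidationError("no gene is positive in every sample")
    pos = v[all_pos]
    ref = np.exp(np.log(pos).mean(axis=1, keepdims=True))
    sf = np.median(pos / ref, axis=0)
    logger.info(
        "size factors from %d all-positive genes: min %.3f max %.3f",
        int(all_pos.sum()),
        sf.min(),
        sf.max(),
    )
    return sf


def normalize_counts(
    pb: PseudobulkMatrix, size_factors: np.ndarray | None = None
) -> np.ndarray:
    """Divide each sample column by its size factor."""
    sf = size_factors if size_factors is not None else pb.size_factors
    if sf is None:
        sf = estimate_size_factors(pb)
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0):
        raise ValidationError("size factors must be positive")
    if sf.shape[0] != pb.n_samples:
        raise ValidationError("size factor vector length != number of samples")
    return pb.values / sf[None, :]


def log_transform(normalized: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise ``log2(x + pseudocount)`` of normalized counts."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size and normalized.min() < 0:
        raise ValidationError("log transform expects non-negative input")
    return np.log2(normalized + pseudocount)
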