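"""Gene scaling and per-cell gene-set z-score signatures.

Population signatures are scored per cell as the mean of per-gene
standardized (z-scored) log-normalized expression over the genes of the set.
A ``literal`` variant that adds the dataset cell count to the per-cell sum
before dividing by the set size is retained behind a flag; it differs from
the mean variant only by the cell-independent offset ``n_cells / |G|`` and
therefore induces identical cell rankings and identical cell-to-cell
differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, GeneSignature, ValidationError

logger = logging.getLogger(__name__)

VARIANTS = ("mean", "literal")


def lognormalize(counts: CountMatrix, target_depth: float | None = None) -> np.ndarray:
    """Depth-normalize and natural-log transform raw counts.

    Each cell is scaled to *target_depth* total UMI (dataset median depth by
    default), then ``ln(x + 1)`` is applied.  Returns a dense gene x cell
    float array.
    """
    depth = counts.n_umi().astype(float)
    if np.any(depth == 0):
        raise ValidationError("cannot depth-normalize cells with zero total UMI")
    if target_depth is None:
        target_depth = float(np.median(depth))
    x = counts.values.multiply(target_depth / depth[None, :]).toarray()
    return np.log1p(x)


def scale_genes(matrix: np.ndarray) -> np.ndarray:
    """Standardize each gene row to mean 0 and unit sample sd (ddof=1).

    Zero-variance rows — which a naive scaling would turn into NaN — are set
    to all-zero instead.  A single-cell matrix has no sample sd and raises.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a 2-D gene x cell matrix")
    if matrix.shape[1] < 2:
        raise ValidationError("scaling requires at least 2 cells")
    if not np.all(np.isfinite(matrix)):
        raise ValidationError("matrix contains non-finite values")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(matrix)
    nz = sd.ravel() > 0
    out[nz] = (matrix[nz] - mean[nz]) / sd[nz]
    return out


def signature_score(
    scaled: np.ndarray,
    gene_ids: list[str],
    signature: GeneSignature,
    variant: str = "mean",
) -> np.ndarray:
    """Score one signature for every cell of a scaled matrix.

    mean:    score(c) = sum_{g in G} scaled[g, c] / |G|
    literal: score(c) = (n_cells + sum_{g in G} scaled[g, c]) / |G|

    where G is the signature restricted to genes present in the matrix;
    absent genes are dropped with a warning.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"variant must be one of {VARIANTS}, got {variant!r}")
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = [pos[g] for g in signature.genes if g in pos]
    dropped = len(signature.genes) - len(idx)
    if dropped:
        logger.warning(
            "signature %r: %d of %d genes absent from the matrix",
            signature.name,
            dropped,
            len(signature.genes),
        )
    if not idx:
        raise ValidationError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    total = np.asarray(scaled)[idx].sum(axis=0)
    if variant == "mean":
        return total / len(idx)
    n_cells = scaled.shape[1]
    return (n_cells + total) / len(idx)


def score_signatures(
    scaled: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    signatures: list[GeneSignature],
    variant: str = "mean",
) -> pd.DataFrame:
    """Score several signatures; returns a cells x signatures DataFrame."""
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValidationError("signature names must be unique")
    cols = {
        s.name: signature_score(scaled, gene_ids, s, variant) for s in signatures
    }
    df = pd.DataFrame(cols, index=list(cell_ids))
    df.attrs["variant"] = variant
    return df


def read_signatures_csv(path) -> list[GeneSignature]:
    """Read signatures from a two-column CSV: set name, gene (one row per
    gene; header optional with columns named 'name' and 'gene')."""
    df = pd.read_csv(path, header=None, dtype=str)
    if list(df.iloc[0]) == ["name", "gene"]:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValidationError("signature CSV needs two columns: name, gene")
    sigs = [
        GeneSignature(str(name), list(dict.fromkeys(group.iloc[:, 1])))
        for name, group in df.groupby(df.columns[0], sort=False)
    ]
    logger.info("read %d signatures from %s", len(sigs), path)
    return sigs


def score_counts(
    counts: CountMatrix,
    signatures: list[GeneSignature],
    variant: str = "mean",
) -> pd.DataFrame:
    """Convenience: log-normalize, scale, and score raw counts in one call."""
    scaled = scale_genes(lognormalize(counts))
    return score_signatures(
        scaled, counts.gene_ids, counts.cell_ids, signatures, variant
    )
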