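"""Readers and writers for the on-disk formats the pipeline exchanges.

Count matrices use the 10x triplet convention: a coordinate Matrix Market
file ``matrix.mtx`` (1-based indices, integer field) next to ``features.tsv``
and ``barcodes.tsv`` with one identifier per line.  Cell metadata travels as
a UTF-8 comma-separated table with a required header.  The 1-based/0-based
index boundary lives entirely in this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ANNOTATION_COLUMNS,
    CONDITIONS,
    MODALITIES,
    SEXES,
    CountMatrix,
    GroundTruth,
    ValidationError,
    validate_annotation,
)

logger = logging.getLogger(__name__)

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"


def _read_id_file(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def _dedupe(ids: list[str], what: str) -> list[str]:
    """Disambiguate duplicate identifiers with '.1', '.2', ... suffixes."""
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
            n_dup += 1
        else:
            seen[x] = 0
            out.append(x)
    if n_dup:
        logger.warning("%d duplicate %s id(s) disambiguated with suffixes", n_dup, what)
    return out


def read_counts_10x(path: str | Path) -> CountMatrix:
    """Read a 10x triplet directory into a :class:`CountMatrix`.

    Genes come from ``features.tsv`` (first tab-separated field), cells from
    ``barcodes.tsv``.  Raises :class:`ValidationError` on missing files,
    header/id-file dimension mismatches, or negative/non-integer entries.
    """
    path = Path(path)
    for fname in (MATRIX_FILE, FEATURES_FILE, BARCODES_FILE):
        if not (path / fname).is_file():
            raise ValidationError(f"missing {fname} in {path}")
    mat = scipy.io.mmread(path / MATRIX_FILE)
    genes = _dedupe(_read_id_file(path / FEATURES_FILE), "feature")
    cells = _dedupe(_read_id_file(path / BARCODES_FILE), "barcode")
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix header declares {mat.shape} but id files list "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
    if data.size and (np.min(data) < 0 or not np.allclose(data, np.round(data))):
        raise ValidationError("matrix contains negative or non-integer entries")
    cm = CountMatrix(sp.csr_matrix(mat), genes, cells)
    logger.info("read %d genes x %d cells from %s", cm.n_genes, cm.n_cells, path)
    return cm


def write_counts_10x(counts: CountMatrix, path: str | Path) -> None:
    """Write a :class:`CountMatrix` as a 10x triplet directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = counts.values.tocoo()
    coo = sp.coo_matrix(
        (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
    )
    scipy.io.mmwrite(path / MATRIX_FILE, coo, field="integer")
    (path / FEATURES_FILE).write_text(
        "".join(f"{g}\n" for g in counts.gene_ids), encoding="utf-8"
    )
    (path / BARCODES_FILE).write_text(
        "".join(f"{c}\n" for c in counts.cell_ids), encoding="utf-8"
    )
    logger.info(
        "wrote %d genes x %d cells (%d nonzeros) to %s",
        counts.n_genes,
        counts.n_cells,
        coo.nnz,
        path,
    )


_ENUM_NORMALIZERS = {
    "modality": {m.lower(): m for m in MODALITIES},
    "condition": {c.lower(): c for c in CONDITIONS},
    "sex": {s.lower(): s for s in SEXES},
}

_REQUIRED_METADATA = [c for c in ANNOTATION_COLUMNS]


def read_cell_metadata(
    path: str | Path, counts: CountMatrix | None = None
) -> pd.DataFrame:
    """Read and validate a per-cell metadata CSV.

    Enumerated columns are normalized case-insensitively to the controlled
    vocabulary; ``age`` is parsed as a float.  When *counts* is supplied the
    cell ids must match the matrix exactly (and in order).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "cluster": str})
    if "cell_id" not in df.columns:
        raise ValidationError("metadata is missing required column 'cell_id'")
    missing = [c for c in _REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata is missing required column(s): {missing}")
    df = df.set_index("cell_id")
    for col, mapping in _ENUM_NORMALIZERS.items():
        vals = df[col].astype(str).str.lower()
        bad = sorted(set(vals) - set(mapping))
        if bad:
            raise ValidationError(f"unknown {col} value(s): {bad}")
        df[col] = vals.map(mapping)
    df["age"] = df["age"].astype(float)
    df["n_umi"] = df["n_umi"].astype(int)
    df["pct_mito"] = df["pct_mito"].astype(float)
    if df["doublet"].dtype != bool:
        df["doublet"] = (
            df["doublet"].astype(str).str.lower().map({"true": True, "false": False})
        )
        if df["doublet"].isna().any():
            raise ValidationError("doublet column must be boolean")
    validate_annotation(df, counts)
    logger.info("read metadata for %d cells from %s", len(df), path)
    return df


def write_cell_metadata(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index_label="cell_id")
    logger.info("wrote metadata for %d cells to %s", len(ann), path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1), encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def read_external_scores(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, score) CSV of external doublet scores."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("external score file needs columns cell_id,score")
    s = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
    logger.info("read %d external doublet scores from %s", len(s), path)
    return s
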