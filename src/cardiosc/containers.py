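"""Core in-memory containers shared across the pipeline.

The expression data model is deliberately small: a sparse gene x cell integer
count matrix with string identifiers (:class:`CountMatrix`), and a per-cell
annotation table kept as a :class:`pandas.DataFrame` indexed by cell id.
Columns of the annotation table follow the controlled vocabulary in
:data:`MODALITIES`, :data:`CONDITIONS` and :data:`SEXES`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MODALITIES = ("cell", "nucleus")
CONDITIONS = ("donor", "DCM")
SEXES = ("male", "female")

#: columns every complete cell annotation table must carry
ANNOTATION_COLUMNS = (
    "sample_id",
    "modality",
    "condition",
    "sex",
    "age",
    "cluster",
    "n_umi",
    "pct_mito",
    "doublet",
)

MITO_PREFIX = "MT-"


class ValidationError(ValueError):
    """Raised when a container or parameter object violates its contract."""


@dataclass
class CountMatrix:
    """Gene x cell matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        Sparse (CSR) or dense array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Ordered unique identifiers for rows and columns.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"cell_ids length {len(self.cell_ids)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell_ids are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("count matrix contains negative entries")
            if not np.issubdtype(data.dtype, np.integer) and not np.allclose(
                data, np.round(data)
            ):
                raise ValidationError("count matrix contains non-integer entries")

    # -- conveniences ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def n_umi(self) -> np.ndarray:
        """Per-cell total UMI count (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def mito_mask(self) -> np.ndarray:
        return np.array([g.startswith(MITO_PREFIX) for g in self.gene_ids])

    def pct_mito(self) -> np.ndarray:
        """Per-cell mitochondrial percentage in [0, 100]."""
        total = self.n_umi().astype(float)
        mito = np.asarray(self.values[self.mito_mask()].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * mito / total, 0.0)
        return pct

    def subset_cells(self, keep: np.ndarray | list) -> "CountMatrix":
        """Subset by boolean mask or by a list of cell ids (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in keep], dtype=int)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix(self.values[idx], list(genes), list(self.cell_ids))

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def validate_annotation(ann: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check a cell annotation table against its contract.

    Every required column must be present, enumerations must use the
    controlled vocabulary, ``pct_mito`` must lie in [0, 100], and — when a
    matrix is supplied — the index must match the matrix cell ids one-to-one.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation missing required column(s): {missing}")
    bad_mod = set(ann["modality"]) - set(MODALITIES)
    if bad_mod:
        raise ValidationError(f"unknown modality value(s): {sorted(bad_mod)}")
    bad_cond = set(ann["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition value(s): {sorted(bad_cond)}")
    bad_sex = set(ann["sex"]) - set(SEXES)
    if bad_sex:
        raise ValidationError(f"unknown sex value(s): {sorted(bad_sex)}")
    pm = ann["pct_mito"].to_numpy(float)
    if np.any((pm < 0) | (pm > 100)):
        raise ValidationError("pct_mito outside [0, 100]")
    if counts is not None:
        if list(ann.index) != list(counts.cell_ids):
            raise ValidationError("annotation index does not match matrix cell ids")


def annotate_from_counts(counts: CountMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Return *ann* with ``n_umi`` and ``pct_mito`` recomputed from *counts*."""
    out = ann.loc[counts.cell_ids].copy()
    out["n_umi"] = counts.n_umi()
    out["pct_mito"] = counts.pct_mito()
    return out


@dataclass
class GeneSignature:
    """A named, ordered, duplicate-free gene set."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GroundTruth:
    """Planted truth emitted by the synthetic-data generator.

    Used only by tests and calibration code; the pipeline itself never reads
    it.  Gene-level effects are signed log2 fold changes (condition DE) or
    signed Pearson targets (age genes).
    """

    true_type: pd.Series
    true_doublet: pd.Series
    de_genes: dict[str, float]
    age_genes: dict[str, float]
    sample_ages: dict[str, float]
    lib_sizes: pd.Series
    sample_depth: dict[str, float] = field(default_factory=dict)
    markers: dict[str, list[str]] = field(default_factory=dict)
    sex_genes: dict[str, list[str]] = field(default_factory=dict)
    mito_genes: list[str] = field(default_factory=list)
    doublet_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_type": self.true_type.to_dict(),
            "true_doublet": {k: bool(v) for k, v in self.true_doublet.items()},
            "de_genes": self.de_genes,
            "age_genes": self.age_genes,
            "sample_ages": self.sample_ages,
            "lib_sizes": {k: float(v) for k, v in self.lib_sizes.items()},
            "sample_depth": self.sample_depth,
            "markers": self.markers,
            "sex_genes": self.sex_genes,
            "mito_genes": self.mito_genes,
            "doublet_parents": {k: list(v) for k, v in self.doublet_parents.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_type=pd.Series(d["true_type"]),
            true_doublet=pd.Series(d["true_doublet"], dtype=bool),
            de_genes={k: float(v) for k, v in d["de_genes"].items()},
            age_genes={k: float(v) for k, v in d["age_genes"].items()},
            sample_ages={k: float(v) for k, v in d["sample_ages"].items()},
            lib_sizes=pd.Series(d["lib_sizes"], dtype=float),
            sample_depth={k: float(v) for k, v in d.get("sample_depth", {}).items()},
            markers=d.get("markers", {}),
            sex_genes=d.get("sex_genes", {}),
            mito_genes=d.get("mito_genes", []),
            doublet_parents={
                k: (v[0], v[1]) for k, v in d.get("doublet_parents", {}).items()
            },
        )
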