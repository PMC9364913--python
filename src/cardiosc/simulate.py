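"""Synthetic donor-vs-DCM two-modality single-cell count data with planted truth.

The generator emulates the design of a human heart-failure cohort profiled by
both single-cell (``cell``) and single-nucleus (``nucleus``) RNA-seq: two
condition groups (non-diseased donors and dilated-cardiomyopathy patients)
with many samples each, several discrete cell types with marker genes,
modality-specific sequencing depth and mitochondrial content, planted
condition-DE genes, planted age-correlated genes, sex-restricted genes, and
doublet barcodes formed by summing two cells of distinct types.

Counts are negative-binomial: for gene *g* in cell *c* the mean is

    mu[g, c] = w[g | sample, type] * L_c

where ``w`` is a per-(sample, type) relative-expression vector (lognormal
baseline times planted multiplicative effects, normalized to sum to one) and
``L_c`` is a lognormal per-cell library size around the modality depth.  The
NB is parameterized by mean and a shared dispersion ``alpha`` with
``Var = mu + alpha * mu**2``, sampled as a gamma-Poisson mixture.

Age effects are log-linear in standardized sample age with slope chosen from
the per-sample biological noise so that the sample-level Pearson correlation
with age approaches ``age_r_target``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    ANNOTATION_COLUMNS,
    CountMatrix,
    GroundTruth,
    ValidationError,
    annotate_from_counts,
)

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 25 donor and 13 DCM samples,
    nuclei shallower than cells (mean library ~2,849 vs ~5,000 UMI), low
    nuclear mitochondrial content, five major cell types with strong markers,
    50 condition-DE genes and 30 age-correlated genes at a target Pearson
    correlation of 0.8, and a 5% doublet rate.
    """

    n_samples_donor: int = 25
    n_samples_dcm: int = 13
    cells_per_sample: int = 200
    n_genes: int = 2000
    n_cell_types: int = 5
    markers_per_type: int = 10
    marker_log2fc: float = 2.0
    n_de_genes: int = 50
    de_log2fc: float = 1.0
    n_age_genes: int = 30
    age_r_target: float = 0.8
    doublet_rate: float = 0.05
    depth_mean_cell: float = 4000.0
    depth_mean_nucleus: float = 2849.0
    mito_frac_cell: float = 0.05
    mito_frac_nucleus: float = 0.01
    nb_dispersion: float = 0.1
    seed: int = 0
    # secondary knobs (kept explicit so studies of single factors can switch
    # the others off)
    lib_size_sigma: float = 0.3
    sample_depth_sigma: float = 0.0
    sample_noise_sigma: float = 0.25
    n_mito_genes: int = 10
    n_sex_genes: int = 6
    baseline_sigma: float = 1.0
    age_range: tuple[float, float] = (30.0, 70.0)
    composition_shift_type: int | None = None
    composition_shift_factor: float = 2.0

    def validate(self) -> None:
        positive_ints = (
            "n_samples_donor",
            "n_samples_dcm",
            "cells_per_sample",
            "n_genes",
            "n_cell_types",
            "markers_per_type",
        )
        for name in positive_ints:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("depth_mean_cell", "depth_mean_nucleus", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("n_de_genes", "n_age_genes", "n_mito_genes", "n_sex_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValidationError(
                f"doublet_rate must lie in [0, 0.5), got {self.doublet_rate}"
            )
        if not 0 < self.age_r_target < 1:
            raise ValidationError(
                f"age_r_target must lie in (0, 1), got {self.age_r_target}"
            )
        for name in ("mito_frac_cell", "mito_frac_nucleus"):
            if not 0 <= getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.n_cell_types < 2 and self.doublet_rate > 0:
            raise ValidationError("n_cell_types must be >= 2 to inject doublets")
        budget = (
            self.n_mito_genes
            + self.n_sex_genes
            + self.n_cell_types * self.markers_per_type
            + self.n_de_genes
            + self.n_age_genes
        )
        if budget > self.n_genes:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for the planted gene blocks "
                f"(need >= {budget})"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict]:
    """Lay out the gene panel and record which index block plays which role."""
    names: list[str] = []
    layout: dict = {}
    layout["mito"] = list(range(0, cfg.n_mito_genes))
    names += [f"MT-G{i}" for i in range(cfg.n_mito_genes)]
    n_male = cfg.n_sex_genes // 2
    n_female = cfg.n_sex_genes - n_male
    layout["sex_male"] = list(range(len(names), len(names) + n_male))
    names += [f"YLNK{i}" for i in range(n_male)]
    layout["sex_female"] = list(range(len(names), len(names) + n_female))
    names += [f"XLNK{i}" for i in range(n_female)]
    layout["markers"] = {}
    for t in range(cfg.n_cell_types):
        idx = list(range(len(names), len(names) + cfg.markers_per_type))
        layout["markers"][f"T{t}"] = idx
        names += [f"MK{t}-{j}" for j in range(cfg.markers_per_type)]
    layout["de"] = list(range(len(names), len(names) + cfg.n_de_genes))
    names += [f"DEG{i}" for i in range(cfg.n_de_genes)]
    layout["age"] = list(range(len(names), len(names) + cfg.n_age_genes))
    names += [f"AGEG{i}" for i in range(cfg.n_age_genes)]
    n_rest = cfg.n_genes - len(names)
    layout["null"] = list(range(len(names), len(names) + n_rest))
    names += [f"G{i:05d}" for i in range(n_rest)]
    return names, layout


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns the count matrix, the per-cell annotation table (cluster labels
    equal the true cell type for singlets and a dedicated per-parent-pair
    label for injected doublets) and the planted :class:`GroundTruth`.
    Deterministic for a fixed config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, layout = _gene_names(config)
    n_genes = config.n_genes
    types = [f"T{t}" for t in range(config.n_cell_types)]

    # baseline relative expression, shared across samples
    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_genes)
    # planted marker/DE/age genes are meant to emulate genes an analyst would
    # actually select (markers are top population-enriched genes, DE and age
    # genes must be quantifiable in pseudobulk), so their baselines come from
    # the well-expressed upper part of the lognormal rather than its tail
    for block in ("de", "age"):
        idx = layout[block]
        if idx:
            base[idx] = rng.lognormal(
                mean=config.baseline_sigma * 0.8,
                sigma=config.baseline_sigma * 0.5,
                size=len(idx),
            )
    for t_markers in layout["markers"].values():
        base[t_markers] = rng.lognormal(
            mean=config.baseline_sigma * 0.8,
            sigma=config.baseline_sigma * 0.5,
            size=len(t_markers),
        )

    # -- samples -----------------------------------------------------------
    sample_rows = []
    for i in range(config.n_samples_donor):
        sample_rows.append(("D%02d" % i, "donor", i % 2))
    for i in range(config.n_samples_dcm):
        sample_rows.append(("H%02d" % i, "DCM", i % 2))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "condition", "modk"])
    samples["modality"] = np.where(samples["modk"] == 0, "nucleus", "cell")
    samples = samples.drop(columns="modk").set_index("sample_id")
    samples["sex"] = [
        "male" if rng.random() < 0.5 else "female" for _ in range(len(samples))
    ]
    lo, hi = config.age_range
    samples["age"] = np.round(rng.uniform(lo, hi, size=len(samples)), 1)
    depth_mult = np.exp(rng.normal(0.0, config.sample_depth_sigma, size=len(samples)))
    samples["depth_mult"] = depth_mult

    age_z = (samples["age"] - samples["age"].mean()) / samples["age"].std(ddof=1)

    # planted signed effects
    de_sign = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
    age_sign = np.where(np.arange(config.n_age_genes) % 2 == 0, 1.0, -1.0)
    r = config.age_r_target
    sigma_log2 = config.sample_noise_sigma / LN2
    age_beta = sigma_log2 * r / np.sqrt(1.0 - r * r)  # log2 slope per sd(age)

    # per-gene per-sample biological noise (natural-log scale)
    noise = rng.normal(0.0, config.sample_noise_sigma, size=(n_genes, len(samples)))

    # -- per-(sample, type) relative-expression vectors --------------------
    mito_idx = np.array(layout["mito"], dtype=int)
    nonmito = np.setdiff1d(np.arange(n_genes), mito_idx)

    type_probs = {}
    for sid, row in samples.iterrows():
        p = np.ones(config.n_cell_types)
        if (
            config.composition_shift_type is not None
            and row["condition"] == "DCM"
        ):
            p[config.composition_shift_type] *= config.composition_shift_factor
        type_probs[sid] = p / p.sum()

    n_cells_total = len(samples) * config.cells_per_sample
    dense = np.empty((n_genes, n_cells_total), dtype=np.int32)
    cols: list[str] = []
    cell_rows: list[dict] = []
    lib_sizes: list[float] = []
    true_types: list[str] = []

    for s_pos, (sid, row) in enumerate(samples.iterrows()):
        w_sample = base * np.exp(noise[:, s_pos])
        if config.n_de_genes and row["condition"] == "DCM":
            w_sample = w_sample.copy()
            w_sample[layout["de"]] *= 2.0 ** (de_sign * config.de_log2fc)
        if config.n_age_genes:
            w_sample = w_sample.copy()
            w_sample[layout["age"]] *= 2.0 ** (
                age_sign * age_beta * age_z.loc[sid]
            )
        # sex-restricted block: expressed in one sex only
        w_sample = w_sample.copy()
        if row["sex"] == "male":
            w_sample[layout["sex_female"]] = 0.0
        else:
            w_sample[layout["sex_male"]] = 0.0

        mito_frac = (
            config.mito_frac_cell
            if row["modality"] == "cell"
            else config.mito_frac_nucleus
        )
        depth = (
            config.depth_mean_cell
            if row["modality"] == "cell"
            else config.depth_mean_nucleus
        ) * row["depth_mult"]

        # cell-type assignment for this sample
        t_idx = rng.choice(config.n_cell_types, size=config.cells_per_sample,
                           p=type_probs[sid])
        for t in range(config.n_cell_types):
            n_t = int(np.sum(t_idx == t))
            if n_t == 0:
                continue
            w = w_sample.copy()
            w[layout["markers"][types[t]]] *= 2.0 ** config.marker_log2fc
            # pin the mitochondrial share of the library to the modality value
            if mito_idx.size and mito_frac > 0:
                nonmito_sum = w[nonmito].sum()
                w[mito_idx] *= (
                    mito_frac / (1.0 - mito_frac) * nonmito_sum / w[mito_idx].sum()
                )
            elif mito_idx.size:
                w[mito_idx] = 0.0
            w = w / w.sum()

            lib = depth * np.exp(
                rng.normal(0.0, config.lib_size_sigma, size=n_t)
            )
            mu = w[:, None] * lib[None, :]
            lam = rng.gamma(
                shape=1.0 / config.nb_dispersion,
                scale=config.nb_dispersion * mu,
            )
            start = len(cols)
            dense[:, start : start + n_t] = rng.poisson(lam)
            for j in range(n_t):
                cid = f"{sid}-C{len(cols):05d}"
                cols.append(cid)
                cell_rows.append(
                    dict(
                        cell_id=cid,
                        sample_id=sid,
                        modality=row["modality"],
                        condition=row["condition"],
                        sex=row["sex"],
                        age=row["age"],
                        cluster=types[t],
                        doublet=False,
                    )
                )
                true_types.append(types[t])
                lib_sizes.append(lib[j])

    counts = CountMatrix(sp.csr_matrix(dense), genes, cols)
    ann = pd.DataFrame(cell_rows).set_index("cell_id")
    ann["n_umi"] = 0
    ann["pct_mito"] = 0.0
    ann = annotate_from_counts(counts, ann)[list(ANNOTATION_COLUMNS)]

    truth = GroundTruth(
        true_type=pd.Series(true_types, index=cols, name="true_type"),
        true_doublet=pd.Series(False, index=cols, name="true_doublet"),
        de_genes={
            genes[g]: float(de_sign[i] * config.de_log2fc)
            for i, g in enumerate(layout["de"])
        },
        age_genes={
            genes[g]: float(age_sign[i] * config.age_r_target)
            for i, g in enumerate(layout["age"])
        },
        sample_ages=samples["age"].to_dict(),
        lib_sizes=pd.Series(lib_sizes, index=cols, dtype=float),
        sample_depth=samples["depth_mult"].to_dict(),
        markers={t: [genes[g] for g in layout["markers"][t]] for t in types},
        sex_genes={
            "male": [genes[g] for g in layout["sex_male"]],
            "female": [genes[g] for g in layout["sex_female"]],
        },
        mito_genes=[genes[g] for g in layout["mito"]],
    )

    if config.doublet_rate > 0:
        counts, ann, truth = _inject(
            counts, ann, truth, config.doublet_rate, rng
        )

    logger.info(
        "simulated %d genes x %d cells (%d samples, %d doublets)",
        counts.n_genes,
        counts.n_cells,
        len(samples),
        int(truth.true_doublet.sum()),
    )
    return counts, ann, truth


def inject_doublets(
    counts: CountMatrix,
    ann: pd.DataFrame,
    rate: float,
    seed: int,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Append synthetic doublet barcodes to an existing dataset.

    Each doublet is the element-wise sum of two randomly paired cells of
    distinct cluster labels from the same sample (falling back to cross-sample
    pairing when a sample has a single cluster).  The number of doublets is
    Binomial(n_cells, rate).  Original cells are untouched; new barcodes get
    ``doublet=True`` and a dedicated ``doublet:<A>+<B>`` cluster label.
    """
    if not 0 <= rate < 0.5:
        raise ValidationError(f"doublet rate must lie in [0, 0.5), got {rate}")
    if ann["cluster"].nunique() < 2:
        raise ValidationError("need >= 2 distinct cell types to form doublets")
    if rate == 0:
        return counts, ann
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        true_type=ann["cluster"].copy(),
        true_doublet=pd.Series(False, index=ann.index),
        de_genes={},
        age_genes={},
        sample_ages={},
        lib_sizes=pd.Series(dtype=float),
    )
    counts2, ann2, _ = _inject(counts, ann, truth, rate, rng)
    return counts2, ann2


def _inject(
    counts: CountMatrix,
    ann: pd.DataFrame,
    truth: GroundTruth,
    rate: float,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    n = counts.n_cells
    n_doublets = int(rng.binomial(n, rate))
    if n_doublets == 0:
        return counts, ann, truth
    pos = {c: i for i, c in enumerate(counts.cell_ids)}
    by_sample = ann.groupby("sample_id", sort=True).groups
    multi = [
        s for s, idx in by_sample.items() if ann.loc[idx, "cluster"].nunique() >= 2
    ]

    pa_idx = np.empty(n_doublets, dtype=int)
    pb_idx = np.empty(n_doublets, dtype=int)
    new_ids = []
    new_rows = []
    parents: dict[str, tuple[str, str]] = {}
    for k in range(n_doublets):
        if multi:
            sid = multi[int(rng.integers(len(multi)))]
            pool = ann.loc[by_sample[sid]]
        else:
            pool = ann
        clusters = pool["cluster"].unique()
        ca, cb = rng.choice(clusters, size=2, replace=False)
        a = pool.index[pool["cluster"] == ca]
        b = pool.index[pool["cluster"] == cb]
        pa = a[int(rng.integers(len(a)))]
        pb = b[int(rng.integers(len(b)))]
        pa_idx[k], pb_idx[k] = pos[pa], pos[pb]
        label = "doublet:%s+%s" % tuple(sorted((str(ca), str(cb))))
        did = f"DBL-{k:05d}"
        new_ids.append(did)
        row = ann.loc[pa].to_dict()
        row["cluster"] = label
        row["doublet"] = True
        new_rows.append(row)
        parents[did] = (pa, pb)

    csc = counts.values.tocsc()
    block = csc[:, pa_idx] + csc[:, pb_idx]
    values = sp.hstack([counts.values, block], format="csr")
    merged = CountMatrix(values, list(counts.gene_ids), counts.cell_ids + new_ids)
    ann_new = pd.concat(
        [ann, pd.DataFrame(new_rows, index=new_ids).astype(ann.dtypes.to_dict())]
    )
    ann_new = annotate_from_counts(merged, ann_new)

    truth.true_type = pd.concat(
        [truth.true_type, pd.Series([ann_new.loc[d, "cluster"] for d in new_ids],
                                    index=new_ids)]
    )
    truth.true_doublet = pd.concat(
        [truth.true_doublet, pd.Series(True, index=new_ids)]
    )
    truth.doublet_parents.update(parents)
    if len(truth.lib_sizes):
        truth.lib_sizes = pd.concat(
            [
                truth.lib_sizes,
                pd.Series(
                    [
                        truth.lib_sizes[parents[d][0]] + truth.lib_sizes[parents[d][1]]
                        for d in new_ids
                    ],
                    index=new_ids,
                ),
            ]
        )
    logger.info("injected %d doublet barcodes at rate %.3f", n_doublets, rate)
    return merged, ann_new, truth
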