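"""Age-association pipeline on log pseudobulk expression.

Within one condition stratum (donor and DCM hearts are analyzed separately),
each gene's log2 normalized pseudobulk expression is screened by Pearson
correlation against sample age; genes with r strictly above 0.6 (below
-0.6) and screen p < 0.05 form the positive (negative) age signature.  Each
signature is then scored per sample — the mean of the member genes' rows
standardized across samples — and regressed on age by ordinary least
squares, with a two-tailed t-test on the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSignature, ValidationError
from .signatures import scale_genes

logger = logging.getLogger(__name__)


def gene_age_correlation(
    log_pb: np.ndarray, gene_ids: list[str], ages: np.ndarray
) -> pd.DataFrame:
    """Per-gene Pearson correlation with age and its two-sided p-value.

    p comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n-2 degrees of
    freedom.  Zero-variance genes get ``included=False`` and NaN statistics.
    """
    log_pb = np.asarray(log_pb, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if n < 3:
        raise ValidationError("age correlation needs at least 3 samples")
    if log_pb.shape[1] != n:
        raise ValidationError("expression columns != number of ages")
    if np.ptp(ages) == 0:
        raise ValidationError("ages are constant")

    age_c = ages - ages.mean()
    x = log_pb - log_pb.mean(axis=1, keepdims=True)
    sx = np.sqrt((x**2).sum(axis=1))
    sa = np.sqrt((age_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ age_c) / (sx * sa)
    included = sx > 0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly
    out = pd.DataFrame(
        {"pearson_r": r, "p": p, "included": included}, index=gene_ids
    )
    out.loc[~included, ["pearson_r", "p"]] = np.nan
    n_excl = int((~included).sum())
    if n_excl:
        logger.info("excluded %d zero-variance genes from the age screen", n_excl)
    return out


def build_age_signatures(
    corr: pd.DataFrame,
    r_cut: float = 0.6,
    p_cut: float = 0.05,
    adjust: bool = False,
) -> tuple[GeneSignature | None, GeneSignature | None]:
    """Split screened genes into positive and negative age signatures.

    Inequalities are strict (a gene at exactly r = 0.6 is excluded).  The
    screen p is used unadjusted by default; ``adjust=True`` applies BH first.
    Empty signatures are returned as None with a warning.
    """
    usable = corr[corr["included"]].copy()
    p = usable["p"].to_numpy()
    if adjust:
        from .diffexp import bh_adjust

        p = bh_adjust(p)
    sig_p = p < p_cut
    pos = usable.index[(usable["pearson_r"] > r_cut) & sig_p].tolist()
    neg = usable.index[(usable["pearson_r"] < -r_cut) & sig_p].tolist()
    for name, genes in (("positive", pos), ("negative", neg)):
        if not genes:
            logger.warning("%s age signature is empty", name)
    pos_sig = GeneSignature("age_positive", pos) if pos else None
    neg_sig = GeneSignature("age_negative", neg) if neg else None
    return pos_sig, neg_sig


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def signature_regression(
    log_pb: np.ndarray,
    gene_ids: list[str],
    signature: GeneSignature,
    ages: np.ndarray,
    top_n: int | None = None,
) -> RegressionSummary:
    """OLS of a per-sample signature score on age.

    The score is the mean over signature genes of their expression rows
    standardized across samples.  ``top_n`` restricts the signature to its
    n members most correlated with age (by |r|) before scoring, matching the
    plotting variant that regresses on the top 10 genes.
    """
    log_pb = np.asarray(log_pb, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValidationError("regression needs at least 3 samples")
    pos = {g: i for i, g in enumerate(gene_ids)}
    genes = [g for g in signature.genes if g in pos]
    if not genes:
        raise ValidationError(
            f"no gene of signature {signature.name!r} present in the matrix"
        )
    if top_n is not None and top_n < len(genes):
        corr = gene_age_correlation(
            log_pb[[pos[g] for g in genes]], genes, ages
        )
        genes = (
            corr["pearson_r"].abs().sort_values(ascending=False).index[:top_n].tolist()
        )
    idx = [pos[g] for g in genes]
    score = scale_genes(log_pb[idx]).mean(axis=0)
    fit = scipy.stats.linregress(ages, score)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=int(ages.size),
    )


@dataclass
class AgeAssociationResult:
    stratum: str
    correlation: pd.DataFrame
    positive: GeneSignature | None
    negative: GeneSignature | None
    regressions: dict[str, RegressionSummary]


def run_age_association(
    log_pb: np.ndarray,
    gene_ids: list[str],
    meta: pd.DataFrame,
    stratum: str,
    r_cut: float = 0.6,
    p_cut: float = 0.05,
    top_n: int | None = None,
) -> AgeAssociationResult:
    """Full age pipeline restricted to one condition stratum.

    Samples from the other condition never enter any step; the returned
    result records the stratum for bookkeeping.
    """
    keep = (meta["condition"] == stratum).to_numpy()
    if keep.sum() < 3:
        raise ValidationError(f"stratum {stratum!r} has fewer than 3 samples")
    sub = np.asarray(log_pb)[:, keep]
    ages = meta.loc[keep, "age"].to_numpy(float)
    corr = gene_age_correlation(sub, gene_ids, ages)
    pos, neg = build_age_signatures(corr, r_cut=r_cut, p_cut=p_cut)
    regressions = {}
    for sig in (pos, neg):
        if sig is not None:
            regressions[sig.name] = signature_regression(
                sub, gene_ids, sig, ages, top_n=top_n
            )
    logger.info(
        "age pipeline (%s, n=%d): %d positive / %d negative signature genes",
        stratum,
        int(keep.sum()),
        len(pos) if pos else 0,
        len(neg) if neg else 0,
    )
    return AgeAssociationResult(stratum, corr, pos, neg, regressions)
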