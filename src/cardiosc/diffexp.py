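"""Differential expression: pseudobulk NB Wald test, single-cell Wilcoxon
rank-sum test, BH adjustment, and the two-method intersection rule.

The pseudobulk test models size-factor-normalized per-sample counts as
negative binomial with Var = mu + alpha * mu^2 and a per-gene dispersion
estimated by pooled within-group method of moments (floored at 1e-8, the
Poisson limit).  The Wald statistic contrasts the two group means on the
natural-log scale with a delta-method standard error; log2 fold changes are
unshrunk and use a pseudocount on the normalized group means.  The method
tag in the result records these choices.

Gene lists used downstream are the intersection of the pseudobulk and
single-cell tests: significant in both, |log2FC| above the cutoff in both,
with matching sign, split into up- and down-regulated lists.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError
from .pseudobulk import PseudobulkMatrix, estimate_size_factors, normalize_counts

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
EXACT_MAX_N = 8  # largest min-group size for exact Wilcoxon enumeration


@dataclass
class DifferentialExpressionResult:
    """Per-gene table of a two-group DE test plus method metadata."""

    table: pd.DataFrame  # index gene; base_mean, log2fc, se, statistic, p, p_adj
    method: str
    params: dict = field(default_factory=dict)

    def significant(self, p_cut: float = 0.05, lfc_cut: float = 0.1) -> pd.DataFrame:
        t = self.table
        return t[(t["p"] < p_cut) & (t["log2fc"].abs() > lfc_cut)]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_groups(
    labels: pd.Series, group1: str | None, group2: str | None
) -> tuple[str, str]:
    uniq = sorted(labels.dropna().unique())
    if group1 is None or group2 is None:
        if len(uniq) != 2:
            raise ValidationError(
                f"grouping must define exactly 2 groups, found {uniq}"
            )
        group1, group2 = uniq
    for g in (group1, group2):
        if g not in set(uniq):
            raise ValidationError(f"group {g!r} not present in grouping")
    return group1, group2


def nb_wald_test(
    pb: PseudobulkMatrix,
    grouping: dict | pd.Series,
    group1: str | None = None,
    group2: str | None = None,
    min_base_mean: float = 1.0,
    pseudocount: float = 1.0,
    alpha_floor: float = ALPHA_FLOOR,
) -> DifferentialExpressionResult:
    """Negative-binomial Wald test on normalized pseudobulk counts.

    ``log2fc`` is group2 over group1.  BH adjustment runs over genes whose
    mean normalized count passes ``min_base_mean``; other genes keep their
    raw p but get ``p_adj = NaN``.
    """
    labels = pd.Series(grouping).reindex(pb.sample_ids)
    group1, group2 = _resolve_groups(labels, group1, group2)
    m1 = (labels == group1).to_numpy()
    m2 = (labels == group2).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples")

    sf = pb.size_factors if pb.size_factors is not None else estimate_size_factors(pb)
    norm = normalize_counts(pb, sf)
    x1, x2 = norm[:, m1], norm[:, m2]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pooled within-group method-of-moments dispersion, floored at the
    # Poisson limit
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (s2 - mu) / np.square(mu), 0.0)
    alpha = np.maximum(alpha, alpha_floor)

    log2fc = np.log2((mu2 + pseudocount) / (mu1 + pseudocount))
    # delta-method variance of ln(mean + pc) per group
    var1 = (mu1 + alpha * mu1**2) / (n1 * (mu1 + pseudocount) ** 2)
    var2 = (mu2 + alpha * mu2**2) / (n2 * (mu2 + pseudocount) ** 2)
    if pseudocount == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            var1 = np.where(mu1 > 0, (mu1 + alpha * mu1**2) / (n1 * mu1**2), np.inf)
            var2 = np.where(mu2 > 0, (mu2 + alpha * mu2**2) / (n2 * mu2**2), np.inf)
    se = np.sqrt(var1 + var2)
    delta_ln = np.log(mu2 + pseudocount) - np.log(mu1 + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta_ln / se, 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    all_zero = (mu1 == 0) & (mu2 == 0)
    p[all_zero] = 1.0
    z[all_zero] = 0.0
    log2fc[all_zero] = 0.0
    se[all_zero] = 0.0

    p_adj = np.full_like(p, np.nan)
    tested = base_mean >= min_base_mean
    if tested.any():
        p_adj[tested] = bh_adjust(p[tested])
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "statistic": z,
            "p": p,
            "p_adj": p_adj,
        },
        index=pb.gene_ids,
    )
    logger.info(
        "NB Wald %s vs %s: %d/%d genes pass base-mean filter, %d at p<0.05",
        group2,
        group1,
        int(tested.sum()),
        len(p),
        int((p[tested] < 0.05).sum()),
    )
    return DifferentialExpressionResult(
        table,
        method="nb_wald",
        params=dict(
            group1=group1,
            group2=group2,
            pseudocount=pseudocount,
            min_base_mean=min_base_mean,
            dispersion="pooled within-group method of moments",
            log2fc_shrinkage="none",
        ),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_ranksum_p(values: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Ties are handled by working with average ranks of the observed pooled
    values; the two-sided p is the permutation probability of a rank sum at
    least as far from its expectation as the observed one.
    """
    n = values.size
    ranks = scipy.stats.rankdata(values)
    observed = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    dev = abs(observed - expected)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - expected) >= dev - 1e-12:
            count += 1
    return count / total


def _normal_ranksum_p(values: np.ndarray, n1: int) -> float:
    """Two-sided normal approximation with tie correction and continuity
    correction."""
    n = values.size
    n2 = n - n1
    ranks = scipy.stats.rankdata(values)
    w = ranks[:n1].sum()
    ew = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w - ew) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * scipy.stats.norm.sf(z))


def wilcoxon_rank_sum_test(
    expr: np.ndarray,
    gene_ids: list[str],
    groups: pd.Series | np.ndarray,
    group1: str | None = None,
    group2: str | None = None,
    log2fc_cutoff: float = 0.1,
    only_positive: bool = False,
) -> DifferentialExpressionResult:
    """Per-gene Wilcoxon rank-sum test on log-normalized expression.

    Uses exact enumeration when the smaller group has <= 8 observations and
    the tie-corrected normal approximation (with continuity correction)
    otherwise.  ``log2fc`` is group2 over group1 on the de-logged means:
    ``log2((mean(expm1(x2)) + 1) / (mean(expm1(x1)) + 1))``.  With
    ``only_positive`` genes at or below the cutoff are dropped before BH
    adjustment.
    """
    expr = np.asarray(expr, dtype=float)
    labels = pd.Series(np.asarray(groups))
    group1, group2 = _resolve_groups(labels, group1, group2)
    m1 = (labels == group1).to_numpy()
    m2 = (labels == group2).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    exact = min(n1, n2) <= EXACT_MAX_N

    x1 = expr[:, m1]
    x2 = expr[:, m2]
    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    log2fc = np.log2((mean2 + 1.0) / (mean1 + 1.0))

    n_genes = expr.shape[0]
    p = np.empty(n_genes)
    stat = np.empty(n_genes)
    for g in range(n_genes):
        pooled = np.concatenate([x1[g], x2[g]])
        ranks = scipy.stats.rankdata(pooled)
        stat[g] = ranks[:n1].sum()
        if exact:
            p[g] = _exact_ranksum_p(pooled, n1)
        else:
            p[g] = _normal_ranksum_p(pooled, n1)
    base_mean = expr.mean(axis=1)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": np.nan,
            "statistic": stat,
            "p": p,
            "p_adj": np.nan,
        },
        index=gene_ids,
    )
    if only_positive:
        dropped = int((table["log2fc"] <= log2fc_cutoff).sum())
        table = table[table["log2fc"] > log2fc_cutoff]
        logger.info("only_positive: dropped %d genes at log2FC cutoff", dropped)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    logger.info(
        "Wilcoxon %s vs %s (%s branch): %d genes, %d at p<0.05",
        group2,
        group1,
        "exact" if exact else "normal",
        len(table),
        int((table["p"] < 0.05).sum()),
    )
    return DifferentialExpressionResult(
        table,
        method="wilcoxon",
        params=dict(
            group1=group1,
            group2=group2,
            branch="exact" if exact else "normal",
            log2fc_cutoff=log2fc_cutoff,
            only_positive=only_positive,
            log2fc_convention="log2((mean(expm1 g2)+1)/(mean(expm1 g1)+1))",
        ),
    )


def intersect_degs(
    pseudo: DifferentialExpressionResult,
    sc: DifferentialExpressionResult,
    p_cut: float = 0.05,
    lfc_cut: float = 0.1,
    p_col: str = "p",
) -> dict[str, list[str]]:
    """Genes called by both methods with matching direction.

    A gene qualifies when ``p < p_cut`` in both tests and ``|log2fc| >
    lfc_cut`` in both with the same sign.  Returns ``{"up": [...], "down":
    [...]}`` (direction of group2 relative to group1).
    """
    a, b = pseudo.table, sc.table
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValidationError("the two results share no genes")
    a = a.loc[shared]
    b = b.loc[shared]
    ok = (
        (a[p_col] < p_cut)
        & (b[p_col] < p_cut)
        & (a["log2fc"].abs() > lfc_cut)
        & (b["log2fc"].abs() > lfc_cut)
        & (np.sign(a["log2fc"]) == np.sign(b["log2fc"]))
    )
    up = sorted(shared[ok & (a["log2fc"] > 0)])
    down = sorted(shared[ok & (a["log2fc"] < 0)])
    logger.info("intersection: %d up, %d down of %d shared genes", len(up), len(down), len(shared))
    return {"up": up, "down": down}
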