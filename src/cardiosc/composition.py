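"""Per-sample cluster composition and Welch's t-test between groups.

Cell-state abundance is compared between condition groups on per-sample
proportions within a parent population (e.g. the share of each
cardiomyocyte state among a sample's cardiomyocytes), using the
unequal-variance two-tailed t-test with Welch-Satterthwaite degrees of
freedom.  Raw p-values are reported per cluster; a BH option exists but is
off by default.
"""

from __future__ import annotations

import logging

import pandas as pd
import scipy.stats

from .containers import ValidationError
from .diffexp import bh_adjust

logger = logging.getLogger(__name__)


def cluster_proportions(
    ann: pd.DataFrame, parent: list[str] | None = None
) -> pd.DataFrame:
    """Sample x cluster proportion table within a parent population.

    *parent* restricts to the listed cluster labels (None = all clusters).
    Samples with no cells in the parent population are dropped with a
    warning.  Rows sum to 1.
    """
    sub = ann if parent is None else ann[ann["cluster"].isin(parent)]
    if len(sub) == 0:
        raise ValidationError("parent population selects no cells")
    counts = pd.crosstab(sub["sample_id"], sub["cluster"])
    dropped = set(ann["sample_id"].unique()) - set(counts.index)
    if dropped:
        logger.warning(
            "%d sample(s) have no cells in the parent population: %s",
            len(dropped),
            sorted(dropped),
        )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [str(c) for c in props.columns]
    return props


def welch_t_test(
    table: pd.DataFrame,
    grouping: dict | pd.Series,
    group1: str | None = None,
    group2: str | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch's two-tailed t-test per cluster column of a proportion table.

    ``t`` is the group1-minus-group2 contrast.  Each group needs >= 2
    samples per cluster.
    """
    labels = pd.Series(grouping).reindex(table.index)
    uniq = sorted(labels.dropna().unique())
    if group1 is None or group2 is None:
        if len(uniq) != 2:
            raise ValidationError(f"grouping must define exactly 2 groups, got {uniq}")
        group1, group2 = uniq
    a = table[labels == group1]
    b = table[labels == group2]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    rows = {}
    for cluster in table.columns:
        res = scipy.stats.ttest_ind(a[cluster], b[cluster], equal_var=False)
        rows[cluster] = {
            "t": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
            "mean_" + str(group1): float(a[cluster].mean()),
            "mean_" + str(group2): float(b[cluster].mean()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if adjust:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    logger.info(
        "Welch t-test %s vs %s over %d clusters; min p = %.3g",
        group1,
        group2,
        len(out),
        out["p"].min(),
    )
    return out
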