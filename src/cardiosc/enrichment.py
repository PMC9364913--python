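"""Over-representation analysis against GMT gene-set collections.

Enrichment of a query gene list in each named set is tested by the
hypergeometric upper tail P(X >= k) — equivalently a one-sided Fisher exact
test on the 2x2 overlap table — within a stated gene universe, with BH
correction across the collection.  The universe should be the genes actually
tested in the originating DE analysis, not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import scipy.stats

from .containers import ValidationError
from .diffexp import bh_adjust

logger = logging.getLogger(__name__)

METHODS = ("hypergeometric", "fisher")


@dataclass
class GeneSetCollection:
    """Named gene sets (unique names, non-empty, duplicate-free)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            uniq = list(dict.fromkeys(str(g) for g in genes))
            if not uniq:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(uniq) != len(genes):
                logger.warning(
                    "gene set %r: removed %d duplicate gene(s)",
                    name,
                    len(genes) - len(uniq),
                )
            clean[str(name)] = uniq
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, gene, gene, ..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(parts)} field(s), needs >= 3"
                )
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            sets[name] = parts[2:]
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na", *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def ora_test(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Over-representation test of *query* within *universe* for each set.

    Returns a per-set table with overlap size ``k``, set size in the
    universe ``K``, p, and BH-adjusted p, sorted by p.
    """
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    uni = list(dict.fromkeys(str(g) for g in universe))
    if not uni:
        raise ValidationError("universe is empty")
    uni_set = set(uni)
    q = list(dict.fromkeys(str(g) for g in query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe were dropped", len(outside)
        )
        q = [g for g in q if g in uni_set]
    if not q:
        raise ValidationError("query is empty (after restriction to the universe)")
    N, n = len(uni), len(q)
    q_set = set(q)
    rows = {}
    for name, genes in sets.sets.items():
        in_uni = [g for g in genes if g in uni_set]
        K = len(in_uni)
        k = len(q_set.intersection(in_uni))
        if K == 0:
            p = 1.0
        elif method == "hypergeometric":
            p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(scipy.stats.fisher_exact(table, alternative="greater")[1])
        rows[name] = {"k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values("p")
    logger.info(
        "ORA (%s): %d sets tested, %d at adjusted p<0.05",
        method,
        len(out),
        int((out["p_adj"] < 0.05).sum()),
    )
    return out
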