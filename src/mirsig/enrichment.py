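"""Target-gene consolidation, hypergeometric gene-set enrichment with BH-FDR,
and the disease-relevance (ratio / p-value) screen."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe.

    If ``universe`` is omitted it defaults to the union of all sets (the true
    background of curated pathway databases is rarely published; an explicit
    universe can be supplied to override).
    """

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: genes & self.universe for name, genes in self.sets.items()}
        empty = [n for n, g in self.sets.items() if not g]
        if empty:
            raise ValueError(f"gene sets empty after universe restriction: {empty}")


def consolidate_targets(
    per_source_targets: Mapping[str, Mapping[str, set[str]]],
    min_sources: int = 2,
    experimental_sources: Sequence[str] = (),
) -> dict[str, set[str]]:
    """Consolidate predicted targets across evidence sources.

    ``per_source_targets`` maps source -> (mirna -> gene set).  Per miRNA, a
    gene is retained when supported by at least ``min_sources`` sources;
    genes from a source listed in ``experimental_sources`` are retained
    unconditionally (experimental evidence outranks prediction agreement).
    """
    if len(per_source_targets) < 2:
        raise ValueError("need at least two sources to consolidate")
    unknown = set(experimental_sources) - set(per_source_targets)
    if unknown:
        raise ValueError(f"unknown experimental sources: {sorted(unknown)}")
    exp = set(experimental_sources)
    support: dict[str, dict[str, int]] = {}
    forced: dict[str, set[str]] = {}
    for source, by_mirna in per_source_targets.items():
        for mirna, genes in by_mirna.items():
            tally = support.setdefault(mirna, {})
            for g in genes:
                tally[g] = tally.get(g, 0) + 1
            if source in exp:
                forced.setdefault(mirna, set()).update(genes)
    out: dict[str, set[str]] = {}
    for mirna, tally in support.items():
        kept = {g for g, c in tally.items() if c >= min_sources}
        kept |= forced.get(mirna, set())
        if kept:
            out[mirna] = kept
    return out


def hypergeom_enrich(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Exact hypergeometric over-representation test for every set.

    For a universe of N genes, a set of K and a query of n with k hits, the
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n); BH adjustment is
    applied across the collection.  Query genes outside the universe are
    dropped with a warning.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    N = len(collection.universe)
    outside = set(query) - collection.universe
    if outside:
        log.warning("hypergeom_enrich: dropping %d query genes outside the universe", len(outside))
    q = set(query) & collection.universe
    n = len(q)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        k = len(q & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0), k / K))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p", "ratio"]).set_index("set_name")
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df.sort_values(["p", "set_name"])


def relevance_screen(
    rows: pd.DataFrame,
    ratio_min: float = 0.15,
    p_max: float = 1e-4,
) -> pd.DataFrame:
    """Flag pathways with hits/size strictly above ``ratio_min`` and p below
    ``p_max``; returns a volcano-style table (ratio, -log10 p, flag).

    ``rows`` needs columns ``hits``, ``size`` and ``p`` (index = pathway).
    """
    required = {"hits", "size", "p"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (rows["hits"] > rows["size"]).any():
        raise ValueError("hits exceed set size")
    out = rows.copy()
    out["ratio"] = out["hits"] / out["size"]
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["flagged"] = (out["ratio"] > ratio_min) & (out["p"] < p_max)
    return out
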