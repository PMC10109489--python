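"""Gene-set over-representation by one-sided Fisher's exact test.

For a query gene list and a collection of gene sets over a universe of N
genes, each term is scored with the hypergeometric upper tail
P(X >= k | N, K, n) — the one-sided Fisher's exact test on the 2x2 table
(in query / not) x (in set / not). The universe defaults to the genes the
caller supplies (typically: all genes present in both the expression table
and the collection), since a web service's internal background is not
reproducible offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .deg import adjust_pvalues

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["term", "k", "K", "n", "N", "p", "p_bh", "genes"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")
        if not self.universe:
            self.universe = set().union(*self.sets.values())

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        from .io import read_gmt

        sets = {t: set(g) for t, g in read_gmt(path).items()}
        return cls(sets=sets, universe=set(universe or ()))

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Harmonize to a universe: clip sets to it, drop sets that vanish."""
        uni = set(universe)
        sets = {}
        for t, s in self.sets.items():
            clipped = s & uni
            if clipped:
                sets[t] = clipped
        dropped = len(self.sets) - len(sets)
        if dropped:
            logger.info("dropped %d gene sets with no gene in the universe", dropped)
        return GeneSetCollection(sets=sets, universe=uni)


def fisher_enrichment(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation of a query in every set.

    Query genes outside the universe are dropped (logged). Returns a frame
    sorted ascending by p (ties by term name) with BH-adjusted p-values.
    """
    query = set(query)
    matched = query & collection.universe
    unmatched = len(query) - len(matched)
    if unmatched:
        logger.info("dropped %d query genes absent from the universe", unmatched)
    if not matched:
        logger.warning("empty query after universe harmonization")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    N = len(collection.universe)
    n = len(matched)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & collection.universe
        K = len(members)
        overlap = sorted(matched & members)
        k = len(overlap)
        # hypergeometric upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0), ";".join(overlap)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "genes"])
    df["p_bh"] = adjust_pvalues(df["p"].to_numpy(), "BH")
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return df[RESULT_COLUMNS]


def filter_significant(
    results: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Keep terms with (raw or BH-adjusted) p strictly below alpha; order kept."""
    if results.empty:
        return results.copy()
    col = "p_bh" if use_adjusted else "p"
    return results[results[col] < alpha].reset_index(drop=True)
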