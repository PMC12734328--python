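"""Hypergeometric over-representation testing against GO/KEGG term maps.

The test is the one-sided hypergeometric upper tail (Fisher exact,
greater): with a universe of N genes of which K carry the term, the
probability that a query of n genes overlaps the term in ≥ k genes.
Benjamini–Hochberg adjustment is applied across all tested terms of one
annotation map; both raw p and q are reported. The universe should be
the analyzed gene space (genes surviving the zero-count filter), not
the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    terms: dict                      # term id -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe) or frozenset().union(*self.terms.values())
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")
            if not frozenset(genes) <= self.universe:
                raise ValueError(f"term {term} has genes outside the universe")
            self.terms[term] = frozenset(genes)

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationMap":
        terms, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                terms[fields[0]] = frozenset(g for g in fields[2:] if g)
                desc[fields[0]] = fields[1]
        if universe is None:
            universe = frozenset().union(*terms.values())
        return cls(terms, desc, frozenset(universe))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term, genes in self.terms.items():
                fh.write("\t".join([term, self.descriptions.get(term, "")]
                                   + sorted(genes)) + "\n")


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not 0 <= k <= min(n, K) <= N:
        raise ValueError(f"inconsistent sizes k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, ann: AnnotationMap) -> pd.DataFrame:
    """Over-representation table for a query gene set.

    One row per term overlapping the query (k ≥ 1), sorted by p, with BH q
    computed across all tested terms of the map. Query genes outside the
    universe are dropped (count in the `n_dropped` attribute of the frame).
    """
    query = set(query)
    dropped = query - ann.universe
    query &= ann.universe
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe dropped")
    if not query:
        warnings.warn("empty query after universe filtering")
        out = pd.DataFrame(columns=["term", "description", "k", "n", "K", "N",
                                    "p", "q", "genes"])
        out.attrs["n_dropped"] = len(dropped)
        return out
    N, n = len(ann.universe), len(query)
    rows = []
    for term, genes in ann.terms.items():
        overlap = query & genes
        rows.append((term, ann.descriptions.get(term, ""), len(overlap), n,
                     len(genes), N, hypergeom_test(len(overlap), n, len(genes), N),
                     ",".join(sorted(overlap))))
    table = pd.DataFrame(rows, columns=["term", "description", "k", "n", "K",
                                        "N", "p", "genes"])
    # BH across all tested terms, then keep terms with any overlap
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table[table["k"] >= 1].sort_values("p", kind="mergesort")
    table = table[["term", "description", "k", "n", "K", "N", "p", "q", "genes"]]
    table.attrs["n_dropped"] = len(dropped)
    return table.reset_index(drop=True)
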