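"""Hypergeometric gene-set over-representation with BH FDR.

Flat-term enrichment of a DE gene list against a detected-gene universe:
upper-tail hypergeometric p-values, Benjamini-Hochberg correction across
tested terms, term fold enrichment, percent of the term present in the DE
list, and per-term fractions of up- vs down-regulated members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .de import benjamini_hochberg


@dataclass
class GeneSetCollection:
    """term_id -> (name, gene set), harmonized against a universe."""

    terms: dict[str, tuple[str, set[str]]]
    universe: set[str] = field(default_factory=set)

    def harmonized(self) -> "GeneSetCollection":
        """Intersect every term with the universe; drop emptied terms."""
        if not self.universe:
            return self
        kept = {}
        for tid, (name, genes) in self.terms.items():
            g = genes & self.universe
            if g:
                kept[tid] = (name, g)
        return GeneSetCollection(kept, self.universe)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file: term_id <tab> description <tab> genes..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return terms


def write_gmt(terms: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(terms):
            name, genes = terms[tid]
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def hypergeom_enrich(
    de_genes,
    collection: GeneSetCollection,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment over all terms with k >= 1.

    For each term: ``p = P(X >= k)`` with X hypergeometric(N, K, n) where
    N is the universe size, K the term size, n the DE list size, and k
    the overlap. q-values are BH across the tested terms. Terms smaller
    than ``min_term_size`` are skipped as noise.
    """
    coll = collection.harmonized()
    universe = coll.universe
    if not universe:
        universe = set()
        for _, genes in coll.terms.values():
            universe |= genes
    de = set(de_genes)
    dropped = len(de - universe)
    if dropped:
        warnings.warn(
            f"{dropped} DE genes outside the universe dropped", stacklevel=2
        )
    de &= universe
    if not de:
        warnings.warn("empty DE list: no enrichment computed", stacklevel=2)
        return pd.DataFrame(
            columns=["term_id", "name", "k", "K", "n", "N", "p_value",
                     "q_value", "fold_enrichment", "pct_genes_term"]
        )
    N, n = len(universe), len(de)
    rows = []
    for tid, (name, genes) in coll.terms.items():
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(genes & de)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": tid, "name": name, "k": k, "K": K, "n": n, "N": N,
             "p_value": p, "fold_enrichment": (k / n) / (K / N),
             "pct_genes_term": 100.0 * k / K}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = benjamini_hochberg(table["p_value"].values)
        table = table.sort_values(
            ["p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    return table


def updown_fractions(
    table: pd.DataFrame,
    collection: GeneSetCollection,
    up_set,
    down_set,
) -> pd.DataFrame:
    """Add frac_up / frac_down columns: direction split of each term's DE hits."""
    up, down = set(up_set), set(down_set)
    if up & down:
        raise ValueError("up and down sets must be disjoint")
    de = up | down
    fu, fd = [], []
    for tid in table["term_id"]:
        genes = collection.terms[tid][1] & de
        k = len(genes)
        fu.append(len(genes & up) / k if k else 0.0)
        fd.append(len(genes & down) / k if k else 0.0)
    out = table.copy()
    out["frac_up"] = fu
    out["frac_down"] = fd
    return out
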