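"""miRNA-mRNA regulatory network construction.

Takes per-source miRNA->gene prediction tables (union-set semantics, with
a validated-targets table treated as one more source), keeps only pairs
whose miRNA and gene are differentially expressed in opposite directions
(the operational reading of "inversely correlated expression"), and
builds a bipartite network annotated with per-pair source provenance,
miRNA target-set overlap edges weighted by the Jaccard coefficient, and
optional protein-interaction overlay among target genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .simulate import TargetMap


def read_target_table(path, source_id: str) -> set[tuple[str, str]]:
    """Read one prediction table (TSV: mirna_id, gene_id[, source])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(zip(df["mirna_id"], df["gene_id"]))


def write_target_map(tm: TargetMap, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for src in sorted(tm.sources):
        rows = sorted(tm.sources[src])
        pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).assign(
            source=src
        ).to_csv(d / f"targets_{src}.tsv", sep="\t", index=False)


def harmonize_ids(
    pairs: set[tuple[str, str]],
    known_mirnas,
    known_genes,
    aliases: dict[str, str] | None = None,
) -> tuple[set[tuple[str, str]], int]:
    """Case-insensitive mapping of pairs onto the expression namespaces.

    Returns the mapped pairs and the number of rows dropped because
    either identifier could not be matched.
    """
    aliases = {k.lower(): v for k, v in (aliases or {}).items()}
    mir_lut = {m.lower(): m for m in known_mirnas}
    gene_lut = {g.lower(): g for g in known_genes}
    out: set[tuple[str, str]] = set()
    dropped = 0
    for m, g in pairs:
        ml, gl = m.lower(), g.lower()
        ml = aliases.get(ml, ml).lower() if ml in aliases else ml
        gl = aliases.get(gl, gl).lower() if gl in aliases else gl
        if ml in mir_lut and gl in gene_lut:
            out.add((mir_lut[ml], gene_lut[gl]))
        else:
            dropped += 1
    return out, dropped


def union_targets(
    tm: TargetMap, mirnas: set[str]
) -> tuple[dict[str, set[str]], dict[tuple[str, str], list[str]]]:
    """Union-set candidate targets restricted to the supplied miRNAs.

    Returns the per-miRNA candidate gene sets and, per pair, the list of
    supporting sources (validated sources included).
    """
    provenance: dict[tuple[str, str], list[str]] = {}
    for src in sorted(tm.sources):
        for pair in tm.sources[src]:
            if pair[0] in mirnas:
                provenance.setdefault(pair, []).append(src)
    candidates: dict[str, set[str]] = {}
    for m, g in provenance:
        candidates.setdefault(m, set()).add(g)
    return candidates, provenance


def anticorrelation_filter(
    provenance: dict[tuple[str, str], list[str]],
    de_mrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
) -> dict[tuple[str, str], list[str]]:
    """Keep pairs whose partners are DE in opposite directions.

    A pair (m, g) survives iff the miRNA and the gene both carry a DE
    call (direction up or down) and the directions differ -- miRNA up
    with gene down, or miRNA down with gene up.
    """
    opposite = {"up": "down", "down": "up"}
    mdir = de_mirna["direction"]
    gdir = de_mrna["direction"]
    out = {}
    for (m, g), sources in provenance.items():
        if m not in mdir.index or g not in gdir.index:
            continue
        dm, dg = mdir[m], gdir[g]
        if dm in opposite and dg == opposite[dm]:
            out[(m, g)] = sources
    return out


@dataclass
class IntegrationNetwork:
    """Bipartite miRNA-gene graph with Jaccard miRNA-overlap edges."""

    graph: nx.Graph
    overlap: nx.Graph
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def mirnas(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna"
        )

    @property
    def genes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"
        )

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.graph.neighbors(mirna))


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 for two empty sets."""
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def build_network(
    retained: dict[tuple[str, str], list[str]],
    validated_sources: set[str] = frozenset(),
    mirna_direction: pd.Series | None = None,
    gene_direction: pd.Series | None = None,
) -> IntegrationNetwork:
    """Assemble the bipartite graph plus the miRNA Jaccard-overlap graph.

    Edge ``evidence`` is ``validated`` when any supporting source is a
    validated table, else ``predicted``; miRNA pairs with overlapping
    target sets receive an overlap edge weighted by the Jaccard
    coefficient (zero-overlap edges are suppressed).
    """
    g = nx.Graph()
    for (m, gene), sources in sorted(retained.items()):
        is_val = bool(set(sources) & set(validated_sources))
        g.add_node(m, kind="mirna")
        g.add_node(gene, kind="gene")
        g.add_edge(
            m, gene,
            evidence="validated" if is_val else "predicted",
            sources=",".join(sorted(sources)),
        )
    if mirna_direction is not None:
        for n in g.nodes:
            if g.nodes[n]["kind"] == "mirna" and n in mirna_direction.index:
                g.nodes[n]["direction"] = mirna_direction[n]
    if gene_direction is not None:
        for n in g.nodes:
            if g.nodes[n]["kind"] == "gene" and n in gene_direction.index:
                g.nodes[n]["direction"] = gene_direction[n]
    mirnas = sorted(n for n, d in g.nodes(data=True) if d["kind"] == "mirna")
    for n in mirnas:
        g.nodes[n]["degree"] = g.degree(n)
    ov = nx.Graph()
    ov.add_nodes_from(mirnas)
    for i, a in enumerate(mirnas):
        ta = set(g.neighbors(a))
        for b in mirnas[i + 1:]:
            jc = jaccard(ta, set(g.neighbors(b)))
            if jc > 0:
                ov.add_edge(a, b, jaccard=jc)
    return IntegrationNetwork(g, ov, dict(retained))


def subnetwork(
    network: IntegrationNetwork,
    gene_set,
    ppi_edges: list[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Induced subgraph on a gene set plus its regulating miRNAs.

    User-supplied interaction edges are overlaid among genes; interactors
    absent from the network but present in ``ppi_edges`` and ``gene_set``
    are admitted as neutral nodes.
    """
    genes = set(gene_set)
    keep = {g for g in network.genes if g in genes}
    mirs = {
        m for m in network.mirnas if set(network.graph.neighbors(m)) & keep
    }
    sub = nx.Graph(network.graph.subgraph(keep | mirs))
    for a, b in ppi_edges or []:
        if a in genes and b in genes:
            for n in (a, b):
                if n not in sub:
                    sub.add_node(n, kind="gene", direction="ns")
            sub.add_edge(a, b, evidence="ppi", sources="ppi")
    return sub


def coregulation_table(network: IntegrationNetwork) -> pd.DataFrame:
    """Genes ranked by the number of regulating miRNAs (descending)."""
    rows = []
    for gene in network.genes:
        mirs = sorted(network.graph.neighbors(gene))
        rows.append(
            {"gene_id": gene, "n_mirnas": len(mirs), "mirnas": ",".join(mirs)}
        )
    return (
        pd.DataFrame(rows, columns=["gene_id", "n_mirnas", "mirnas"])
        .sort_values(["n_mirnas", "gene_id"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )


def export_edges_tsv(network: IntegrationNetwork, path) -> None:
    rows = []
    for u, v, d in network.graph.edges(data=True):
        m, g = (u, v) if network.graph.nodes[u]["kind"] == "mirna" else (v, u)
        rows.append(
            {"mirna_id": m, "gene_id": g, "evidence": d["evidence"],
             "sources": d["sources"]}
        )
    rows.sort(key=lambda r: (r["mirna_id"], r["gene_id"]))
    pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "evidence", "sources"]
    ).to_csv(path, sep="\t", index=False)


def export_graphml(network: IntegrationNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def export_sif(network: IntegrationNetwork, path) -> None:
    lines = []
    for u, v, d in network.graph.edges(data=True):
        m, g = (u, v) if network.graph.nodes[u]["kind"] == "mirna" else (v, u)
        lines.append(f"{m}\t{d['evidence']}\t{g}\n")
    with open(path, "w") as fh:
        fh.writelines(sorted(lines))
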