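"""NetworkDrawer-style coexpression networks and subnetwork enrichment.

Starting from a set of query genes, the strongest coexpressed genes are
retrieved, and every node is linked to its three strongest coexpressed
partners within the node set, giving a medium-density network regardless of
the query.  Subnetworks are detected by greedy modularity within connected
components, and each subnetwork is tested for over-representation of GO
terms and of promoter heptamer words (proximal window [-300, -1]) with a
one-sided hypergeometric test under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .coextable import CoexpressionTable

__all__ = [
    "CoexNetwork",
    "Subnetwork",
    "EnrichmentResult",
    "build_network",
    "flag_supported_edges",
    "detect_subnetworks",
    "enrich",
    "promoter_heptamers",
    "heptamer_categories",
]


@dataclass
class CoexNetwork:
    """Undirected coexpression graph with node roles and MR edge weights.

    Node attribute ``role`` is ``"query"`` (drawn white) or ``"retrieved"``
    (gray); edge attributes are ``mr`` and the boolean ``supported`` flag
    (coexpression corroborated by another dataset).
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tmr\tsupported\n")
            for a, b in self.edges:
                d = self.graph.edges[a, b]
                fh.write(f"{a}\t{b}\t{d['mr']:.6g}\t{int(d.get('supported', False))}\n")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    raw_p: float
    corrected_p: float
    members_with: int
    background_with: int


@dataclass
class Subnetwork:
    members: tuple[str, ...]
    enrichment: list[EnrichmentResult] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def build_network(
    queries: Sequence[str],
    coex: CoexpressionTable,
    n_retrieved_per_query: int = 20,
    edges_per_gene: int = 3,
) -> CoexNetwork:
    """Query genes plus their strongest coexpressed genes, top-3-edge wiring.

    The node set is the queries together with each query's
    ``n_retrieved_per_query`` lowest-MR genes.  Every node then nominates
    edges to its ``edges_per_gene`` strongest partners *within the node
    set*; nominations are deduplicated.
    """
    missing = [q for q in queries if q not in coex]
    if missing:
        raise KeyError(f"query genes absent from the table: {missing}")
    nodes: set[str] = set(queries)
    for q in queries:
        nodes.update(coex.ranked_list(q).top(n_retrieved_per_query))
    g = nx.Graph()
    for n in sorted(nodes):
        g.add_node(n, role="query" if n in set(queries) else "retrieved")
    for n in sorted(nodes):
        partners = [x for x in coex.ranked_list(n).genes if x in nodes]
        for p in partners[:edges_per_gene]:
            if not g.has_edge(n, p):
                g.add_edge(n, p, mr=coex.value(n, p), supported=False)
    return CoexNetwork(graph=g)


def flag_supported_edges(
    net: CoexNetwork,
    other_tables: Sequence[tuple[CoexpressionTable, Mapping[str, str]]],
    strong_mr: float = 500.0,
) -> None:
    """Mark edges whose orthologous pair is strongly coexpressed elsewhere.

    ``other_tables`` pairs each supporting dataset's MR table with a gene
    map from this network's gene space into that dataset.  An edge is
    supported when at least one other dataset shows the mapped pair at
    MR below ``strong_mr``.
    """
    for a, b in net.edges:
        supported = False
        for table, mapping in other_tables:
            ma, mb = mapping.get(a), mapping.get(b)
            if ma is None or mb is None or ma not in table or mb not in table:
                continue
            if ma != mb and table.value(ma, mb) < strong_mr:
                supported = True
                break
        net.graph.edges[a, b]["supported"] = supported


def detect_subnetworks(net: CoexNetwork) -> list[Subnetwork]:
    """Partition the network into subnetworks by greedy modularity merging.

    Each connected component is split with the Clauset–Newman–Moore greedy
    modularity heuristic; components with fewer than three nodes (or no
    internal edges) stay whole.  The partition covers every node and each
    part induces a connected subgraph.  Output is sorted lexicographically
    by member list for determinism.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    parts: list[tuple[str, ...]] = []
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        if sub.number_of_nodes() <= 2 or sub.number_of_edges() == 0:
            parts.append(tuple(sorted(comp)))
            continue
        communities = nx.community.greedy_modularity_communities(sub)
        parts.extend(tuple(sorted(c)) for c in communities)
    return [Subnetwork(members=p) for p in sorted(parts)]


def enrich(
    members: Iterable[str],
    categories: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per category, Bonferroni.

    ``categories`` maps each gene to the set of categories it carries (GO
    terms or heptamers present in its promoter); test GO terms and
    heptamers in separate calls so each family gets its own Bonferroni
    divisor.  Results are sorted by corrected p, then category.
    """
    members = sorted(set(members))
    background = sorted(set(background))
    if not background:
        raise ValueError("empty background")
    if not set(members) <= set(background):
        raise ValueError("subnetwork members must be contained in the background")
    bg_with: dict[str, int] = {}
    for g in background:
        for c in categories.get(g, ()):
            bg_with[c] = bg_with.get(c, 0) + 1
    n_tests = len(bg_with)
    m = len(background)
    n = len(members)
    results = []
    for cat in sorted(bg_with):
        k = sum(1 for g in members if cat in categories.get(g, ()))
        raw = float(hypergeom.sf(k - 1, m, bg_with[cat], n)) if k > 0 else 1.0
        raw = min(raw, 1.0)
        results.append(
            EnrichmentResult(
                category=cat,
                raw_p=raw,
                corrected_p=min(1.0, raw * n_tests),
                members_with=k,
                background_with=bg_with[cat],
            )
        )
    return sorted(results, key=lambda r: (r.corrected_p, r.raw_p, r.category))


def promoter_heptamers(
    promoter: str,
    window: tuple[int, int] = (-300, -1),
) -> set[str]:
    """Distinct 7-mers in the proximal promoter window.

    The promoter is given 5'->3' on the coding strand with its last base at
    position -1 (adjacent to the annotated start).  The sequence is clipped
    to the window before scanning; windows containing non-ACGT characters
    are skipped.  The category space is the 4^7 = 16,384 possible heptamers.
    """
    start, end = window
    if start > end or end > -1:
        raise ValueError("window must be (-upstream, -1)-style, start <= end <= -1")
    seq = promoter.upper()
    length = end - start + 1
    clipped = seq[len(seq) + start: len(seq) + end + 1] if len(seq) >= -start else seq[: len(seq) + end + 1]
    if len(clipped) < 7:
        warnings.warn("promoter window shorter than 7 nt; no heptamers", stacklevel=2)
        return set()
    found = set()
    for i in range(len(clipped) - 6):
        word = clipped[i:i + 7]
        if set(word) <= set("ACGT"):
            found.add(word)
    return found


def heptamer_categories(
    promoters: Mapping[str, str],
    window: tuple[int, int] = (-300, -1),
    include_reverse_complement: bool = False,
) -> dict[str, frozenset[str]]:
    """Per-gene heptamer presence sets, ready for :func:`enrich`."""
    comp = str.maketrans("ACGT", "TGCA")
    out = {}
    for gene, seq in promoters.items():
        words = promoter_heptamers(seq, window)
        if include_reverse_complement:
            words |= {w.translate(comp)[::-1] for w in set(words)}
        out[gene] = frozenset(words)
    return out
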