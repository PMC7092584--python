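"""Typed lncRNA-miRNA-mRNA network assembly and miRNA hub scoring.

Admission is resolved in a fixed, well-founded order (no iteration):

1. lncRNA nodes: maximum read count over the libraries strictly greater
   than ``min_reads`` (a count of exactly 10 is excluded) AND at least one
   apc or antisense link.
2. A miRNA has a "lncRNA-side" edge if the target table points it at an
   admitted lncRNA, or a precursor hit ties it to an admitted lncRNA.
3. mRNA nodes: differentially expressed in >= 1 contrast AND either
   apc/antisense-linked to an admitted lncRNA or targeted by a miRNA with
   a lncRNA-side edge.
4. miRNA nodes: >= 1 edge to an admitted lncRNA or admitted mRNA.

Edge types: mirna_targets_mrna, mirna_targets_lncrna,
lncrna_precursor_of_mirna, apc, antisense.  The hub score of a miRNA is
the number of distinct (lncRNA, mRNA) pairs it bridges through its
targeting edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .annotation_io import ExpressionTable
from .duplex_and_precursor import DuplexHit, PrecursorHit
from .positional_classifier import ApcLink

DEFAULT_MIN_READS = 10

NODE_TYPES = ("lncRNA", "miRNA", "mRNA")
EDGE_TYPES = (
    "mirna_targets_mrna",
    "mirna_targets_lncrna",
    "lncrna_precursor_of_mirna",
    "apc",
    "antisense",
)


@dataclass(frozen=True)
class HubScore:
    mirna_id: str
    score: int
    n_lnc: int
    n_mrna: int


class CeRNAGraph:
    """Thin typed wrapper over a MultiDiGraph keyed by edge type."""

    def __init__(self) -> None:
        self.g = nx.MultiDiGraph()
        self.n_skipped_targets = 0

    def add_node(self, node_id: str, node_type: str, **attrs) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"invalid node type {node_type!r}")
        self.g.add_node(node_id, node_type=node_type, **attrs)

    def add_edge(self, u: str, v: str, edge_type: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"invalid edge type {edge_type!r}")
        if u == v:
            raise ValueError("self-loops are not allowed")
        for node in (u, v):
            if node not in self.g:
                raise ValueError(f"edge endpoint {node!r} not in graph")
        if not self.g.has_edge(u, v, key=edge_type):
            self.g.add_edge(u, v, key=edge_type)

    def nodes_of_type(self, node_type: str) -> Set[str]:
        return {
            n for n, d in self.g.nodes(data=True) if d["node_type"] == node_type
        }

    def edges(self) -> Set[Tuple[str, str, str]]:
        return {(u, v, k) for u, v, k in self.g.edges(keys=True)}

    def neighbors_by_edge(self, node: str, edge_type: str) -> Set[str]:
        return {
            v for _, v, k in self.g.out_edges(node, keys=True) if k == edge_type
        }


def build_cerna(
    lnc_ids: Iterable[str],
    expr: ExpressionTable,
    de_mrna_ids: Set[str],
    mrna_ids: Set[str],
    apc_links: Sequence[ApcLink],
    duplex_hits: Sequence[DuplexHit],
    precursor_hits: Sequence[PrecursorHit],
    targets: Sequence[Tuple[str, str]],
    min_reads: int = DEFAULT_MIN_READS,
) -> CeRNAGraph:
    """Assemble the typed tri-partite graph from the upstream evidence."""
    lnc_ids = set(lnc_ids)

    # links per lncRNA (apc + antisense), restricted to known mRNAs
    lnc_partner: Dict[str, Set[Tuple[str, str]]] = {l: set() for l in lnc_ids}
    for link in apc_links:
        if link.lnc_id in lnc_ids and link.gene_id in mrna_ids:
            lnc_partner[link.lnc_id].add((link.gene_id, "apc"))
    for hit in duplex_hits:
        if hit.lnc_id in lnc_ids and hit.mrna_id in mrna_ids:
            lnc_partner[hit.lnc_id].add((hit.mrna_id, "antisense"))

    # step 1: lncRNA admission
    admitted_lnc = {
        l
        for l in lnc_ids
        if expr.max_over_libraries(l, "read_count") > min_reads and lnc_partner[l]
    }

    # target table split by endpoint type; unknown endpoints counted+skipped
    mirna_lnc_targets: Dict[str, Set[str]] = {}
    mirna_mrna_targets: Dict[str, Set[str]] = {}
    n_skipped = 0
    for mirna_id, target_id in targets:
        if target_id in lnc_ids:
            mirna_lnc_targets.setdefault(mirna_id, set()).add(target_id)
        elif target_id in mrna_ids:
            mirna_mrna_targets.setdefault(mirna_id, set()).add(target_id)
        else:
            n_skipped += 1

    precursor_of: Dict[str, Set[str]] = {}
    for hit in precursor_hits:
        if hit.lnc_id in lnc_ids:
            precursor_of.setdefault(hit.hairpin_id, set()).add(hit.lnc_id)

    # step 2: miRNAs with a lncRNA-side edge
    mirnas_with_lnc_side = {
        m
        for m in set(mirna_lnc_targets) | set(precursor_of)
        if (mirna_lnc_targets.get(m, set()) & admitted_lnc)
        or (precursor_of.get(m, set()) & admitted_lnc)
    }

    # step 3: mRNA admission
    linked_mrnas = {
        partner
        for l in admitted_lnc
        for partner, _ in lnc_partner[l]
    }
    mirna_reachable_mrnas = {
        t
        for m in mirnas_with_lnc_side
        for t in mirna_mrna_targets.get(m, set())
    }
    admitted_mrna = de_mrna_ids & (linked_mrnas | mirna_reachable_mrnas)

    # step 4: miRNA admission
    admitted_mirna = set()
    for m in set(mirna_lnc_targets) | set(mirna_mrna_targets) | set(precursor_of):
        touches = (
            (mirna_lnc_targets.get(m, set()) & admitted_lnc)
            or (precursor_of.get(m, set()) & admitted_lnc)
            or (mirna_mrna_targets.get(m, set()) & admitted_mrna)
        )
        if touches:
            admitted_mirna.add(m)

    graph = CeRNAGraph()
    graph.n_skipped_targets = n_skipped
    for l in sorted(admitted_lnc):
        graph.add_node(
            l, "lncRNA", max_read_count=expr.max_over_libraries(l, "read_count")
        )
    for m in sorted(admitted_mrna):
        graph.add_node(m, "mRNA", de=True)
    for m in sorted(admitted_mirna):
        graph.add_node(m, "miRNA")

    for l in sorted(admitted_lnc):
        for partner, kind in sorted(lnc_partner[l]):
            if partner in admitted_mrna:
                graph.add_edge(l, partner, kind)
    for m in sorted(admitted_mirna):
        for l in sorted(mirna_lnc_targets.get(m, set()) & admitted_lnc):
            graph.add_edge(m, l, "mirna_targets_lncrna")
        for t in sorted(mirna_mrna_targets.get(m, set()) & admitted_mrna):
            graph.add_edge(m, t, "mirna_targets_mrna")
        for l in sorted(precursor_of.get(m, set()) & admitted_lnc):
            graph.add_edge(l, m, "lncrna_precursor_of_mirna")
    return graph


def score_hubs(graph: CeRNAGraph) -> List[HubScore]:
    """Bridged-pair counts per miRNA, descending; ties break on id."""
    scores: List[HubScore] = []
    for m in graph.nodes_of_type("miRNA"):
        lnc_side = graph.neighbors_by_edge(m, "mirna_targets_lncrna")
        mrna_side = graph.neighbors_by_edge(m, "mirna_targets_mrna")
        scores.append(
            HubScore(m, len(lnc_side) * len(mrna_side), len(lnc_side), len(mrna_side))
        )
    scores.sort(key=lambda h: (-h.score, h.mirna_id))
    return scores


def write_graph_tables(graph: CeRNAGraph, node_path, edge_path) -> None:
    from .annotation_io import write_tsv

    node_rows = [
        (n, d["node_type"])
        for n, d in sorted(graph.g.nodes(data=True))
    ]
    write_tsv(node_path, ["id", "type"], node_rows)
    edge_rows = sorted(graph.edges())
    write_tsv(edge_path, ["source", "target", "edge_type"],
              [(u, v, k) for u, v, k in edge_rows])
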