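"""Per-miRNA protein-interaction network construction.

Each network has two layers: L0, the miRNA's consensus target genes, and L1,
the genes joined by a single protein-protein interaction to some L0 gene.
Expansion is one shell only, and the edge set is the full induced subgraph of
the PPI on L0 ∪ L1 (so L1-L1 interactions are kept; the layer node counts,
the only quantity the source tables print, are unaffected by that choice).
L1 membership is not restricted to differentially expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .consensus import ConsensusPair
from .io import UsageError, ppi_edge


@dataclass(frozen=True)
class PIN:
    mirna_id: str
    l0: frozenset[str]
    l1: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return self.l0 | self.l1

    def layer(self, gene: str) -> str:
        if gene in self.l0:
            return "L0"
        if gene in self.l1:
            return "L1"
        raise KeyError(gene)


@dataclass(frozen=True)
class PinSummary:
    mirna_id: str
    total: int
    l0_count: int
    l1_count: int


def _canonical_edges(ppi: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    edges = set()
    for a, b in ppi:
        e = ppi_edge(a, b)
        if e is not None:
            edges.add(e)
    return edges


def build_pin(mirna_id: str, l0_genes: Iterable[str], ppi: Iterable[tuple[str, str]]) -> PIN:
    """One-shell expansion of the target set through the PPI.

    Nodes are the L0 genes plus every gene sharing a PPI edge with an L0
    gene; edges are the induced PPI subgraph. Isolated L0 genes are allowed
    (a network may consist of targets only).
    """
    l0 = frozenset(l0_genes)
    if not l0:
        raise UsageError("l0_genes must be non-empty")
    edges = _canonical_edges(ppi)
    graph = nx.Graph(edges)
    l1 = frozenset(
        nbr for gene in l0 if gene in graph for nbr in graph.neighbors(gene)
    ) - l0
    nodes = l0 | l1
    induced = frozenset(e for e in edges if e[0] in nodes and e[1] in nodes)
    return PIN(mirna_id=mirna_id, l0=l0, l1=l1, edges=induced)


def build_pins(pairs: Iterable[ConsensusPair], ppi: Iterable[tuple[str, str]]) -> list[PIN]:
    """Group consensus pairs by miRNA and build one network per miRNA."""
    targets: dict[str, set[str]] = {}
    for p in pairs:
        targets.setdefault(p.mirna_id, set()).add(p.gene_id)
    edges = _canonical_edges(ppi)
    return [build_pin(m, targets[m], edges) for m in sorted(targets)]


def summarize_pins(pins: Iterable[PIN]) -> list[PinSummary]:
    summaries = [
        PinSummary(
            mirna_id=p.mirna_id,
            total=len(p.nodes),
            l0_count=len(p.l0),
            l1_count=len(p.l1),
        )
        for p in pins
    ]
    return sorted(summaries, key=lambda s: s.mirna_id)


def summary_table(pins: Iterable[PIN]) -> pd.DataFrame:
    rows = [
        {"mirna_id": s.mirna_id, "total": s.total,
         "l0_count": s.l0_count, "l1_count": s.l1_count}
        for s in summarize_pins(pins)
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "total", "l0_count", "l1_count"])
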