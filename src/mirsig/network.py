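"""Bipartite miRNA -> gene target network with per-edge evidence sources."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


@dataclass
class TargetNetwork:
    """miRNA–mRNA interaction network.

    Edges are stored as an adjacency mapping ``mirna -> {gene -> evidence
    source set}``; duplicate (mirna, gene) pairs are merged by unioning their
    evidence sources.
    """

    _adj: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str | Iterable[str]]]) -> "TargetNetwork":
        """Build a network from (mirna, gene, source-or-sources) triples."""
        net = cls()
        for mirna, gene, sources in edges:
            if isinstance(sources, str):
                sources = {sources}
            net.add_edge(mirna, gene, sources)
        return net

    def add_edge(self, mirna: str, gene: str, sources: Iterable[str]) -> None:
        sources = set(sources)
        if not sources:
            raise ValueError(f"edge ({mirna}, {gene}) has no evidence source")
        self._adj.setdefault(mirna, {}).setdefault(gene, set()).update(sources)

    # -- queries --------------------------------------------------------------

    @property
    def mirnas(self) -> list[str]:
        return sorted(self._adj)

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for targets in self._adj.values():
            out.update(targets)
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self._adj.values())

    def targets_of(self, mirna: str) -> set[str]:
        return set(self._adj.get(mirna, {}))

    def sources_of(self, mirna: str, gene: str) -> set[str]:
        return set(self._adj.get(mirna, {}).get(gene, set()))

    def gene_degree(self) -> dict[str, int]:
        """Number of distinct miRNAs targeting each gene."""
        deg: dict[str, int] = {}
        for targets in self._adj.values():
            for g in targets:
                deg[g] = deg.get(g, 0) + 1
        return deg

    def edges(self) -> list[tuple[str, str, frozenset[str]]]:
        return [
            (m, g, frozenset(src))
            for m in sorted(self._adj)
            for g, src in sorted(self._adj[m].items())
        ]

    def restrict_genes(self, keep: set[str]) -> "TargetNetwork":
        """Subnetwork induced by a gene set; miRNAs left with no edge are dropped."""
        sub = TargetNetwork()
        for mirna, targets in self._adj.items():
            kept = {g: set(src) for g, src in targets.items() if g in keep}
            if kept:
                sub._adj[mirna] = kept
        return sub
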