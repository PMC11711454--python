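"""Mixed gene graph: undirected and directed edges with provenance.

Undirected edges are first-class citizens — edges whose direction cannot be
identified are kept, not dropped.  Directed orientations (from v-structures,
Mendelian randomization, or prior knowledge) are never allowed to form a
directed cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

PROVENANCE_FLAGS = ("fdr_stable", "hd_stable", "v_structure", "mr_oriented", "prior", "validated")


@dataclass
class Edge:
    a: str
    b: str
    directed: bool = False
    src: Optional[str] = None  # tail of the arrow when directed
    p: Optional[float] = None
    provenance: set = field(default_factory=set)

    @property
    def dst(self) -> Optional[str]:
        if not self.directed:
            return None
        return self.b if self.src == self.a else self.a

    def key(self) -> frozenset:
        return frozenset((self.a, self.b))


class GeneGraph:
    """At most one edge per unordered gene pair; no self-loops."""

    def __init__(self, nodes: Iterable[str]):
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        self._edges: dict[frozenset, Edge] = {}

    # -- construction -----------------------------------------------------
    def add_edge(
        self,
        a: str,
        b: str,
        p: Optional[float] = None,
        provenance: Optional[Iterable[str]] = None,
    ) -> Edge:
        if a == b:
            raise ValueError("self-loops are not allowed")
        for n in (a, b):
            if n not in self.nodes:
                raise KeyError(f"node {n} not in graph")
        key = frozenset((a, b))
        if key in self._edges:
            e = self._edges[key]
            if p is not None:
                e.p = p
            if provenance:
                e.provenance |= set(provenance)
            return e
        e = Edge(a=a, b=b, p=p, provenance=set(provenance or ()))
        self._edges[key] = e
        return e

    def orient(self, src: str, dst: str, provenance: str, force: bool = False) -> bool:
        """Direct the existing edge src->dst.  Returns False (and leaves the
        edge as-is) if the orientation would create a directed cycle, or if
        the edge is already directed the other way and ``force`` is False."""
        key = frozenset((src, dst))
        e = self._edges.get(key)
        if e is None:
            raise KeyError(f"no edge between {src} and {dst}")
        if e.directed and e.src == src:
            e.provenance.add(provenance)
            return True
        if e.directed and not force:
            return False
        dg = self.directed_view()
        if dg.has_edge(dst, src):
            dg.remove_edge(dst, src)
        dg.add_edge(src, dst)
        if not nx.is_directed_acyclic_graph(dg):
            return False
        e.directed = True
        e.src = src
        e.provenance.add(provenance)
        return True

    # -- queries ----------------------------------------------------------
    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._edges

    def edge(self, a: str, b: str) -> Edge:
        return self._edges[frozenset((a, b))]

    def undirected_edge_set(self) -> set[frozenset]:
        return set(self._edges.keys())

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for key in self._edges:
            if gene in key:
                (other,) = key - {gene}
                out.add(other)
        return out

    def parents(self, gene: str) -> set[str]:
        """Direct upstream genes via directed edges only."""
        out = set()
        for e in self._edges.values():
            if e.directed and e.dst == gene:
                out.add(e.src)
        return out

    def directed_view(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        for e in self._edges.values():
            if e.directed:
                dg.add_edge(e.src, e.dst)
        return dg

    def undirected_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self._edges.values():
            g.add_edge(e.a, e.b)
        return g

    def copy(self) -> "GeneGraph":
        out = GeneGraph(self.nodes)
        for e in self._edges.values():
            ne = out.add_edge(e.a, e.b, p=e.p, provenance=set(e.provenance))
            ne.directed = e.directed
            ne.src = e.src
        return out

    def __len__(self) -> int:
        return len(self._edges)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        nd = sum(e.directed for e in self._edges.values())
        return f"GeneGraph({len(self.nodes)} nodes, {len(self._edges)} edges, {nd} directed)"
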