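"""Signed directed causal graphs over proteins, enzymes, complexes and metabolites.

The central container is :class:`CausalPKN`, a deduplicated set of signed
directed edges plus a node-kind annotation.  Edge identity is the triple
``(source, sign, target)``; provenance tags (``ppi``, ``allosteric``,
``metabolic``, ``transcriptional``) ride along but do not participate in
equality, and when the same triple arrives from several sources the first
provenance wins while all of them are recorded in an auxiliary map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

PROTEIN = "protein"
METABOLITE = "metabolite"
ENZYME_INSTANCE = "enzyme_instance"
COMPLEX = "complex"
NODE_KINDS = frozenset({PROTEIN, METABOLITE, ENZYME_INSTANCE, COMPLEX})

#: Namespace prefix that keeps metabolite identifiers disjoint from gene symbols.
METABOLITE_PREFIX = "metab__"


class PKNFormatError(ValueError):
    """Raised when an interaction/reaction table violates its dialect."""


class NamespaceError(ValueError):
    """Raised when one identifier is used both as a metabolite and as a protein."""


@dataclass(frozen=True)
class SignedEdge:
    """One causal interaction: ``source`` acts on ``target`` with ``sign``."""

    source: str
    sign: int
    target: str
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be -1 or +1, got {self.sign!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop edge not allowed: {self.source!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.source, self.sign, self.target)

    def __repr__(self) -> str:  # compact, SIF-like
        return f"SignedEdge({self.source};{self.sign:+d};{self.target})"


def is_metabolite_id(node: str) -> bool:
    return node.startswith(METABOLITE_PREFIX)


def _default_kind(node: str) -> str:
    return METABOLITE if is_metabolite_id(node) else PROTEIN


class CausalPKN:
    """A signed directed prior-knowledge network.

    Parameters
    ----------
    edges:
        Iterable of :class:`SignedEdge`; duplicates (same source/sign/target)
        are collapsed, keeping the first provenance seen.
    node_kind:
        Optional node -> kind map.  Nodes not listed get a kind inferred from
        their namespace (``metab__`` prefix -> metabolite, else protein).
    members:
        For ``enzyme_instance``/``complex`` nodes, the set of gene symbols
        behind the catalytic unit.  Used by the expression filter and by ORA.
    """

    def __init__(
        self,
        edges: Iterable[SignedEdge] = (),
        node_kind: Mapping[str, str] | None = None,
        members: Mapping[str, frozenset[str]] | None = None,
    ) -> None:
        self._edges: dict[tuple[str, int, str], SignedEdge] = {}
        self.provenances: dict[tuple[str, int, str], tuple[str, ...]] = {}
        self.node_kind: dict[str, str] = dict(node_kind or {})
        self.members: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in (members or {}).items()
        }
        for e in edges:
            self.add_edge(e)
        for node, kind in self.node_kind.items():
            if kind not in NODE_KINDS:
                raise ValueError(f"unknown node kind {kind!r} for node {node!r}")

    # -- construction -------------------------------------------------

    def add_edge(self, edge: SignedEdge) -> None:
        key = edge.key
        if key in self._edges:
            prev = self.provenances[key]
            if edge.provenance and edge.provenance not in prev:
                self.provenances[key] = prev + (edge.provenance,)
            return
        self._edges[key] = edge
        self.provenances[key] = (edge.provenance,) if edge.provenance else ()
        for node in (edge.source, edge.target):
            self.node_kind.setdefault(node, _default_kind(node))

    def set_kind(self, node: str, kind: str, members: Iterable[str] | None = None) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.node_kind[node] = kind
        if members is not None:
            self.members[node] = frozenset(members)

    # -- views ---------------------------------------------------------

    @property
    def edges(self) -> set[SignedEdge]:
        return set(self._edges.values())

    def edges_sorted(self) -> list[SignedEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def __contains__(self, edge: SignedEdge) -> bool:
        return edge.key in self._edges

    def has_node(self, node: str) -> bool:
        return node in self.node_kind

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[SignedEdge]:
        return iter(self.edges_sorted())

    @property
    def nodes(self) -> set[str]:
        return set(self.node_kind)

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, k in self.node_kind.items() if k == kind}

    def kind_of(self, node: str) -> str:
        return self.node_kind[node]

    def degree(self, node: str) -> int:
        return sum(1 for e in self._edges.values() if node in (e.source, e.target))

    def gene_symbols(self, node: str) -> frozenset[str]:
        """Gene symbols behind a node (protein: itself; catalytic: members)."""
        kind = self.node_kind.get(node, _default_kind(node))
        if kind == PROTEIN:
            return frozenset({node})
        if kind in (ENZYME_INSTANCE, COMPLEX):
            if node in self.members:
                return self.members[node]
            stem = node.split("__", 1)[0]
            return frozenset(stem.split("_"))
        return frozenset()

    def to_digraph(self) -> nx.DiGraph:
        """Collapse to an unsigned digraph (for reachability queries)."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.node_kind))
        for e in self.edges_sorted():
            g.add_edge(e.source, e.target)
        return g

    # -- derivation ----------------------------------------------------

    def copy(self) -> "CausalPKN":
        out = CausalPKN()
        out._edges = dict(self._edges)
        out.provenances = dict(self.provenances)
        out.node_kind = dict(self.node_kind)
        out.members = dict(self.members)
        return out

    def subgraph(self, nodes: Iterable[str]) -> "CausalPKN":
        """Vertex-induced subnetwork (keeps kinds/members of retained nodes)."""
        keep = set(nodes)
        out = CausalPKN()
        for e in self.edges_sorted():
            if e.source in keep and e.target in keep:
                out.add_edge(e)
                out.provenances[e.key] = self.provenances[e.key]
        for n in keep & set(self.node_kind):
            out.node_kind[n] = self.node_kind[n]
            if n in self.members:
                out.members[n] = self.members[n]
        return out

    def without_edges(self, edges: Iterable[SignedEdge]) -> "CausalPKN":
        drop = {e.key for e in edges}
        out = self.copy()
        for key in drop:
            out._edges.pop(key, None)
            out.provenances.pop(key, None)
        return out

    def remove_nodes(self, nodes: Iterable[str]) -> "CausalPKN":
        drop = set(nodes)
        out = self.subgraph(self.nodes - drop)
        return out

    def edge_provenances(self, edge: SignedEdge) -> tuple[str, ...]:
        return self.provenances.get(edge.key, ())

    def validate(self) -> None:
        for e in self._edges.values():
            for node in (e.source, e.target):
                if node not in self.node_kind:
                    raise ValueError(f"node {node!r} lacks a node_kind entry")
        for node, kind in self.node_kind.items():
            if kind == METABOLITE and not is_metabolite_id(node):
                raise NamespaceError(
                    f"metabolite node {node!r} lacks the {METABOLITE_PREFIX!r} prefix"
                )
            if kind != METABOLITE and is_metabolite_id(node):
                raise NamespaceError(
                    f"node {node!r} carries the metabolite prefix but kind {kind!r}"
                )

    def __repr__(self) -> str:
        return f"CausalPKN({len(self._edges)} edges, {len(self.node_kind)} nodes)"
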