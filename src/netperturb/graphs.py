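"""Mixed graphs for causal modelling of biomolecular networks.

The central object is the :class:`MixedGraph`, an acyclic directed mixed
graph (ADMG): directed edges encode causation, bidirected edges encode
latent confounding between a pair of observed biomolecules.  Nodes may
additionally carry a *latent* mark, which lets the same structure hold a
DAG with hidden variables before latent projection collapses them into
bidirected edges.

Separation in these graphs is *m-separation*, the ADMG generalisation of
d-separation: a path is blocked by a conditioning set ``z`` when some
non-collider on it is in ``z`` or some collider on it has no descendant
in ``z`` (a bidirected endpoint counts as an arrowhead).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "MixedGraph",
    "CIStatement",
    "GraphError",
    "ancestors",
    "descendants",
    "m_separated",
    "implied_independencies",
    "latent_project",
    "exogenize_latents",
]


class GraphError(ValueError):
    """Raised for structurally invalid graphs or malformed queries."""


def _canon_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class CIStatement:
    """A conditional independence claim ``left ⫫ right | given``."""

    left: str
    right: str
    given: frozenset[str]

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise GraphError("CIStatement requires two distinct variables")
        if self.left in self.given or self.right in self.given:
            raise GraphError("conditioning set may not contain the tested pair")
        object.__setattr__(self, "given", frozenset(self.given))
        # canonical orientation so (A,B|Z) == (B,A|Z)
        if self.right < self.left:
            left, right = self.right, self.left
            object.__setattr__(self, "left", left)
            object.__setattr__(self, "right", right)

    def __str__(self) -> str:
        cond = ", ".join(sorted(self.given))
        return f"{self.left} _||_ {self.right}" + (f" | {cond}" if cond else "")


@dataclass(frozen=True)
class MixedGraph:
    """Acyclic directed mixed graph with optional latent node marks.

    Parameters
    ----------
    nodes:
        Variable names.  Names are opaque, case-sensitive strings (gene
        symbols are case-meaningful).
    directed:
        Ordered pairs ``(u, v)`` meaning ``u -> v``.
    bidirected:
        Unordered pairs ``u <-> v``; stored canonically sorted.
    latent:
        Subset of ``nodes`` flagged as unobserved.
    """

    nodes: frozenset[str]
    directed: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    bidirected: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    latent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        nodes = frozenset(self.nodes)
        directed = frozenset(tuple(e) for e in self.directed)
        bidirected = frozenset(_canon_pair(*e) for e in self.bidirected)
        latent = frozenset(self.latent)
        for u, v in directed | bidirected:
            if u == v:
                raise GraphError(f"self-loop on {u!r}")
            if u not in nodes or v not in nodes:
                raise GraphError(f"edge endpoint not declared as node: ({u!r}, {v!r})")
        if not latent <= nodes:
            raise GraphError(f"latent marks on unknown nodes: {sorted(latent - nodes)}")
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        dg.add_edges_from(directed)
        if not nx.is_directed_acyclic_graph(dg):
            cyc = nx.find_cycle(dg)
            raise GraphError(f"directed part is cyclic: {cyc}")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "directed", directed)
        object.__setattr__(self, "bidirected", bidirected)
        object.__setattr__(self, "latent", latent)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        directed: Iterable[tuple[str, str]] = (),
        bidirected: Iterable[tuple[str, str]] = (),
        latent: Iterable[str] = (),
        nodes: Iterable[str] = (),
    ) -> "MixedGraph":
        directed = list(directed)
        bidirected = list(bidirected)
        all_nodes = set(nodes) | set(latent)
        for u, v in itertools.chain(directed, bidirected):
            all_nodes.update((u, v))
        return cls(frozenset(all_nodes), frozenset(directed), frozenset(bidirected), frozenset(latent))

    # -- basic accessors ------------------------------------------------------

    @property
    def observable(self) -> frozenset[str]:
        return self.nodes - self.latent

    def parents(self, v: str) -> set[str]:
        return {u for u, w in self.directed if w == v}

    def children(self, v: str) -> set[str]:
        return {w for u, w in self.directed if u == v}

    def siblings(self, v: str) -> set[str]:
        """Nodes joined to ``v`` by a bidirected edge."""
        return {u if w == v else w for u, w in self.bidirected if v in (u, w)}

    def adjacent(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed
            or (v, u) in self.directed
            or _canon_pair(u, v) in self.bidirected
        )

    def digraph(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        dg.add_edges_from(self.directed)
        return dg

    def topological_order(self) -> list[str]:
        """Deterministic topological order of the directed part."""
        return list(nx.lexicographical_topological_sort(self.digraph()))

    def _check_nodes(self, s: Iterable[str]) -> frozenset[str]:
        s = frozenset(s)
        unknown = s - self.nodes
        if unknown:
            raise GraphError(f"unknown node(s): {sorted(unknown)}")
        return s

    # -- derived graphs -------------------------------------------------------

    def subgraph(self, keep: Iterable[str]) -> "MixedGraph":
        keep = self._check_nodes(keep)
        return MixedGraph(
            keep,
            frozenset(e for e in self.directed if e[0] in keep and e[1] in keep),
            frozenset(e for e in self.bidirected if e[0] in keep and e[1] in keep),
            self.latent & keep,
        )

    def remove_incoming(self, targets: Iterable[str]) -> "MixedGraph":
        """Sever edges into ``targets`` (the do-operator mutilation).

        Bidirected edges at a target carry an arrowhead into it, so they
        are removed as well.
        """
        targets = self._check_nodes(targets)
        return MixedGraph(
            self.nodes,
            frozenset(e for e in self.directed if e[1] not in targets),
            frozenset(e for e in self.bidirected if not (e[0] in targets or e[1] in targets)),
            self.latent,
        )

    def with_bidirected(self, pairs: Iterable[tuple[str, str]]) -> "MixedGraph":
        extra = {_canon_pair(*p) for p in pairs}
        for u, v in extra:
            self._check_nodes((u, v))
        return MixedGraph(self.nodes, self.directed, self.bidirected | frozenset(extra), self.latent)


# ---------------------------------------------------------------------------
# reachability


def ancestors(g: MixedGraph, s: Iterable[str]) -> set[str]:
    """Reflexive ancestors of ``s`` along directed edges."""
    s = g._check_nodes(s)
    dg = g.digraph()
    out = set(s)
    for v in s:
        out |= nx.ancestors(dg, v)
    return out


def descendants(g: MixedGraph, s: Iterable[str]) -> set[str]:
    """Reflexive descendants of ``s`` along directed edges."""
    s = g._check_nodes(s)
    dg = g.digraph()
    out = set(s)
    for v in s:
        out |= nx.descendants(dg, v)
    return out


# ---------------------------------------------------------------------------
# m-separation

_HIDDEN = "hidden"  # tag inside tuple-valued synthetic nodes; cannot collide with str names


def _augmented_dag(g: MixedGraph) -> nx.DiGraph:
    """DAG with each bidirected edge replaced by a fresh hidden common cause.

    d-separation among the original nodes of this DAG coincides with
    m-separation in the mixed graph.
    """
    dg = g.digraph()
    for u, v in g.bidirected:
        h = (_HIDDEN, u, v)
        dg.add_edge(h, u)
        dg.add_edge(h, v)
    return dg


def m_separated(
    g: MixedGraph,
    a: Iterable[str],
    b: Iterable[str],
    z: Iterable[str] = (),
) -> bool:
    """Whether every path between ``a`` and ``b`` is blocked given ``z``."""
    a, b, z = g._check_nodes(a), g._check_nodes(b), g._check_nodes(z)
    if (a & b) or (a & z) or (b & z):
        raise GraphError("a, b, z must be pairwise disjoint")
    for s in (a, b, z):
        if s & g.latent:
            raise GraphError(f"latent nodes may not appear in a separation query: {sorted(s & g.latent)}")
    if not a or not b:
        return True
    return nx.is_d_separator(_augmented_dag(g), a, b, z)


def implied_independencies(
    g: MixedGraph,
    max_cond: int,
    policy: str = "ancestors",
) -> list[CIStatement]:
    """All conditional independencies the graph implies, up to ``max_cond``.

    For every non-adjacent pair of observable nodes, every conditioning
    set of size <= ``max_cond`` drawn from the candidate pool under which
    the pair is m-separated is emitted.  The pool is the pair's observable
    ancestors (``policy="ancestors"``, sound for minimal separators and
    tractable on realistic network sizes) or all other observables
    (``policy="all-observables"``).  Output order is deterministic:
    lexicographic by pair, then by conditioning-set size and contents.
    """
    if max_cond < 0:
        raise GraphError("max_cond must be >= 0")
    if policy not in ("ancestors", "all-observables"):
        raise GraphError(f"unknown candidate-set policy {policy!r}")
    obs = sorted(g.observable)
    out: list[CIStatement] = []
    for u, v in itertools.combinations(obs, 2):
        if g.adjacent(u, v):
            continue
        if policy == "ancestors":
            pool = sorted((ancestors(g, {u, v}) & g.observable) - {u, v})
        else:
            pool = [w for w in obs if w not in (u, v)]
        for k in range(min(max_cond, len(pool)) + 1):
            for cond in itertools.combinations(pool, k):
                if m_separated(g, {u}, {v}, set(cond)):
                    out.append(CIStatement(u, v, frozenset(cond)))
    return out


# ---------------------------------------------------------------------------
# latent projection and simplification


def latent_project(g: MixedGraph) -> MixedGraph:
    """Marginalise latent nodes, preserving observable m-separations.

    Directed ``u -> v`` survives when a directed path runs from ``u`` to
    ``v`` through latent intermediates only; a bidirected ``u <-> v``
    appears when a path ``u <- ... -> v`` exists whose intermediates are
    all latent non-colliders (equivalently, a latent source reaches both
    through latent intermediates).  Pre-existing bidirected edges are
    treated as hidden common causes and re-emerge between retained nodes.
    """
    obs = g.observable
    if not obs:
        raise GraphError("cannot project a graph whose nodes are all latent")
    # Uniform treatment: bidirected u<->v becomes hidden exogenous h -> u, h -> v.
    dg = _augmented_dag(g)
    hidden = {n for n in dg if isinstance(n, tuple)} | set(g.latent)

    def latent_reach(start: str) -> set[str]:
        # observables reachable from `start` by directed paths whose
        # intermediates are all latent/hidden
        seen: set[str] = set()
        reached: set[str] = set()
        stack = [start]
        while stack:
            n = stack.pop()
            for c in dg.successors(n):
                if c in obs:
                    reached.add(c)
                elif c not in seen:
                    seen.add(c)
                    stack.append(c)
        return reached

    directed: set[tuple[str, str]] = set()
    for u in obs:
        for w in latent_reach(u):
            if w != u:
                directed.add((u, w))
    bidirected: set[tuple[str, str]] = set()
    for t in hidden:
        reach = sorted(latent_reach(t))
        for u, w in itertools.combinations(reach, 2):
            bidirected.add(_canon_pair(u, w))
    return MixedGraph(frozenset(obs), frozenset(directed), frozenset(bidirected), frozenset())


def exogenize_latents(g: MixedGraph) -> MixedGraph:
    """Rewrite a latent DAG so every latent is exogenous with >= 2 children.

    Applies margin-preserving simplifications until fixpoint:

    * a latent with no children is dropped;
    * a latent with a single child is contracted (its parents become
      parents of the child);
    * a latent with parents keeps its children but its parents are
      rerouted directly to the children, making it exogenous.

    The observable margin (all m-separations among observables) equals
    that of :func:`latent_project`.
    """
    if g.bidirected:
        raise GraphError("exogenize_latents expects a DAG with latent marks, not an ADMG")
    nodes = set(g.nodes)
    directed = set(g.directed)
    latent = set(g.latent)

    def parents_of(v: str) -> set[str]:
        return {u for u, w in directed if w == v}

    def children_of(v: str) -> set[str]:
        return {w for u, w in directed if u == v}

    changed = True
    while changed:
        changed = False
        for l in sorted(latent):
            ch = children_of(l)
            pa = parents_of(l)
            if not ch:
                nodes.discard(l)
                latent.discard(l)
                directed = {e for e in directed if l not in e}
                changed = True
            elif len(ch) == 1:
                (c,) = ch
                nodes.discard(l)
                latent.discard(l)
                directed = {e for e in directed if l not in e}
                directed |= {(p, c) for p in pa if p != c}
                changed = True
            elif pa:
                directed -= {(p, l) for p in pa}
                directed |= {(p, c) for p in pa for c in ch if p != c}
                changed = True
            if changed:
                break
    return MixedGraph(frozenset(nodes), frozenset(directed), frozenset(), frozenset(latent))
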