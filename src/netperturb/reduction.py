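"""Nuisance-variable detection and query-specific graph simplification.

Large biomolecular networks carry many variables that a single causal
query does not need; worse, conditioning on some of them — descendants
of the exposure-to-outcome pathway that do not themselves feed the
outcome — can inflate both the bias and the asymptotic variance of an
effect estimator.  This module finds those nuisance variables, marks
them latent, and re-projects the graph, leaving a smaller network whose
observable margin is distribution-equivalent to the original on the
retained variables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphs import GraphError, MixedGraph, ancestors, descendants, exogenize_latents, latent_project

__all__ = [
    "ReductionReport",
    "causal_path_nodes",
    "find_nuisance_variables",
    "simplify_for_query",
]


@dataclass(frozen=True)
class ReductionReport:
    nuisance: frozenset[str]
    simplified: MixedGraph
    nodes_before: int
    nodes_after: int
    directed_before: int
    directed_after: int
    bidirected_before: int
    bidirected_after: int

    def to_json(self) -> dict:
        return {
            "nuisance": sorted(self.nuisance),
            "nodes": {"before": self.nodes_before, "after": self.nodes_after},
            "directed_edges": {"before": self.directed_before, "after": self.directed_after},
            "bidirected_edges": {"before": self.bidirected_before, "after": self.bidirected_after},
        }


def _check_query(g: MixedGraph, x: str, y: str) -> None:
    if x == y:
        raise GraphError("exposure and outcome must differ")
    for v in (x, y):
        if v not in g.nodes:
            raise GraphError(f"unknown node {v!r}")
        if v in g.latent:
            raise GraphError(f"query variable {v!r} is latent")


def causal_path_nodes(g: MixedGraph, x: str, y: str) -> set[str]:
    """Nodes on a proper directed path from ``x`` to ``y``, excluding ``x``.

    Equals ``descendants(x) ∩ ancestors(y) − {x}``; only directed edges
    count, bidirected confounding arcs carry no causal flow.
    """
    _check_query(g, x, y)
    return (descendants(g, {x}) & ancestors(g, {y})) - {x}


def find_nuisance_variables(g: MixedGraph, x: str, y: str) -> set[str]:
    """Observable variables irrelevant (and potentially harmful) to the query.

    A nuisance variable is a descendant of some node on the causal
    pathway from ``x`` to ``y`` that is not itself an ancestor of ``y``
    — downstream read-outs of the pathway that can only add noise or
    collider bias to the estimate.
    """
    _check_query(g, x, y)
    cp = causal_path_nodes(g, x, y)
    if not cp:
        return set()
    downstream = descendants(g, cp)
    keep = ancestors(g, {y}) | {x, y}
    return (downstream - keep) & g.observable


def simplify_for_query(g: MixedGraph, x: str, y: str) -> ReductionReport:
    """Mark nuisance variables latent and project them out of the graph.

    The returned graph is an ADMG over the retained observables whose
    m-separations (hence implied distributional constraints) agree with
    the input graph restricted to those variables.  Retained latents
    with fewer than two observable children vanish silently — they
    constrain nothing on the margin.
    """
    nuisance = find_nuisance_variables(g, x, y)
    marked = MixedGraph(g.nodes, g.directed, g.bidirected, g.latent | frozenset(nuisance))
    if marked.bidirected:
        simplified = latent_project(marked)
    else:
        simplified = latent_project(exogenize_latents(marked))
    return ReductionReport(
        nuisance=frozenset(nuisance),
        simplified=simplified,
        nodes_before=len(g.nodes),
        nodes_after=len(simplified.nodes),
        directed_before=len(g.directed),
        directed_after=len(simplified.directed),
        bidirected_before=len(g.bidirected),
        bidirected_after=len(simplified.bidirected),
    )
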