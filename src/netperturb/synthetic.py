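"""Ground-truth structural causal models for simulation studies.

Two generator families emulate the data regimes the workflow targets:

* :class:`LinearSCM` — linear-Gaussian models of steady-state abundance
  measurements across biological replicates, with latent confounders
  represented as exogenous hidden parents of observable pairs;
* :class:`DiscreteSCM` — small categorical models whose observational
  and interventional distributions can be enumerated exactly, serving
  as oracles for identification and plug-in estimation.

Both are fully seed-deterministic, and both support the do-operator:
sampling under ``do(X=x)`` severs the incoming edges of the target and
fixes its value, irrespective of its natural causes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .graphs import GraphError, MixedGraph
from .identify import DiscreteJoint

__all__ = [
    "LinearSCM",
    "DiscreteSCM",
    "random_scm",
    "sample",
    "true_effect",
    "random_discrete_scm",
    "exhaustive_joint",
    "exhaustive_interventional",
]


@dataclass(frozen=True)
class LinearSCM:
    """Linear-Gaussian SCM: ``V = intercept + sum_w weight * parent + noise``.

    ``graph`` is a DAG (directed edges only) whose latent-marked nodes
    are hidden confounders; weights map each directed edge to its
    coefficient and every node carries a Gaussian noise variance and an
    intercept.
    """

    graph: MixedGraph
    weights: Mapping[tuple[str, str], float]
    noise_var: Mapping[str, float]
    intercept: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph.bidirected:
            raise GraphError("LinearSCM graph must be a DAG (no bidirected edges)")
        if set(self.weights) != set(self.graph.directed):
            raise GraphError("weights must be defined for exactly the directed edges")
        for v in self.graph.nodes:
            if self.noise_var.get(v, 0.0) <= 0:
                raise GraphError(f"noise variance for {v!r} must be positive")

    def to_json(self) -> dict:
        g = self.graph
        return {
            "nodes": sorted(g.nodes),
            "latent": sorted(g.latent),
            "edges": [
                {"source": u, "target": v, "weight": self.weights[(u, v)]}
                for u, v in sorted(g.directed)
            ],
            "noise_var": {v: self.noise_var[v] for v in sorted(g.nodes)},
            "intercept": {v: self.intercept.get(v, 0.0) for v in sorted(g.nodes)},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "LinearSCM":
        g = MixedGraph.from_edges(
            directed=[(e["source"], e["target"]) for e in obj["edges"]],
            latent=obj["latent"],
            nodes=obj["nodes"],
        )
        weights = {(e["source"], e["target"]): e["weight"] for e in obj["edges"]}
        return cls(g, weights, obj["noise_var"], obj.get("intercept", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "LinearSCM":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def random_scm(
    n_nodes: int,
    edge_prob: float = 0.4,
    n_latent_confounders: int = 0,
    seed: int | np.random.Generator = 0,
) -> LinearSCM:
    """Random linear-Gaussian SCM on a random topological order.

    Observables are ``X1..Xn``; each latent confounder ``U``*j* is an
    exogenous hidden parent of one random observable pair.  Edge weights
    are uniform on ``±[0.3, 1.0]`` (the magnitude floor keeps generators
    away from near-unfaithful cancellations), noise variances uniform on
    ``[0.5, 1.5]``, intercepts zero.
    """
    if n_nodes < 2:
        raise GraphError("need at least two observable nodes")
    if not 0.0 <= edge_prob <= 1.0:
        raise GraphError("edge_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"X{i + 1}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    edges: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            edges.append((order[i], order[j]))
    latents = [f"U{k + 1}" for k in range(n_latent_confounders)]
    for u in latents:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        edges.append((u, names[a]))
        edges.append((u, names[b]))
    g = MixedGraph.from_edges(directed=edges, latent=latents, nodes=names)

    def draw_weight() -> float:
        return float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.0))

    weights = {e: draw_weight() for e in g.directed}
    noise = {v: float(rng.uniform(0.5, 1.5)) for v in g.nodes}
    return LinearSCM(g, weights, noise)


def sample(
    scm: LinearSCM,
    n: int,
    seed: int | np.random.Generator = 0,
    do: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Ancestral sampling of ``n`` replicates; latent columns are dropped.

    Under ``do``, each target's incoming edges are severed and its value
    held fixed at the requested level.
    """
    do = dict(do or {})
    unknown = set(do) - set(scm.graph.observable)
    if unknown:
        raise GraphError(f"do-targets must be observable: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for v in scm.graph.topological_order():
        if v in do:
            values[v] = np.full(n, float(do[v]))
            continue
        col = np.full(n, scm.intercept.get(v, 0.0))
        for p in scm.graph.parents(v):
            col = col + scm.weights[(p, v)] * values[p]
        col = col + rng.normal(0.0, np.sqrt(scm.noise_var[v]), size=n)
        values[v] = col
    cols = sorted(scm.graph.observable)
    return pd.DataFrame({c: values[c] for c in cols})


def true_effect(scm: LinearSCM, x: str, y: str) -> float:
    """Total causal effect of a unit shift in ``x`` on ``y``.

    Path tracing: the sum over all directed paths from ``x`` to ``y`` of
    the product of edge weights, computed by dynamic programming along a
    topological order.
    """
    for v in (x, y):
        if v not in scm.graph.observable:
            raise GraphError(f"{v!r} is not an observable node")
    total = {x: 1.0}
    for v in scm.graph.topological_order():
        if v == x or v not in scm.graph.nodes:
            continue
        acc = 0.0
        for p in scm.graph.parents(v):
            if p in total:
                acc += scm.weights[(p, v)] * total[p]
        if acc != 0.0 or any(p in total for p in scm.graph.parents(v)):
            total[v] = acc
    return total.get(y, 0.0)


def model_covariance(scm: LinearSCM) -> tuple[list[str], np.ndarray]:
    """Model-implied covariance of all nodes: ``(I-B)^-1 D (I-B)^-T``."""
    nodes = sorted(scm.graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    k = len(nodes)
    b = np.zeros((k, k))
    for (u, v), w in scm.weights.items():
        b[idx[v], idx[u]] = w
    d = np.diag([scm.noise_var[v] for v in nodes])
    inv = np.linalg.inv(np.eye(k) - b)
    return nodes, inv @ d @ inv.T


# ---------------------------------------------------------------------------
# discrete SCMs


@dataclass(frozen=True)
class DiscreteSCM:
    """Categorical SCM with per-node conditional probability tables.

    ``cpts[v]`` has one axis per parent (parents in ``parent_order[v]``)
    plus a final axis over the node's own levels; every slice along the
    last axis sums to one and all entries are strictly positive.
    """

    graph: MixedGraph
    cardinality: Mapping[str, int]
    parent_order: Mapping[str, tuple[str, ...]]
    cpts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.graph.bidirected:
            raise GraphError("DiscreteSCM graph must be a DAG with latent marks")
        for v in self.graph.nodes:
            pa = tuple(self.parent_order[v])
            if set(pa) != self.graph.parents(v):
                raise GraphError(f"parent_order mismatch at {v!r}")
            t = np.asarray(self.cpts[v], dtype=float)
            want = tuple(self.cardinality[p] for p in pa) + (self.cardinality[v],)
            if t.shape != want:
                raise GraphError(f"cpt shape for {v!r} is {t.shape}, expected {want}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise GraphError(f"cpt rows for {v!r} must sum to 1")
            if (t <= 0).any():
                raise GraphError(f"cpt for {v!r} must be strictly positive")

    def state_space(self) -> int:
        out = 1
        for v in self.graph.nodes:
            out *= self.cardinality[v]
        return out


def random_discrete_scm(
    n_obs: int,
    edge_prob: float = 0.5,
    n_latent_confounders: int = 0,
    cardinality: int = 2,
    seed: int | np.random.Generator = 0,
) -> DiscreteSCM:
    """Random strictly positive categorical SCM (Dirichlet CPT rows)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"X{i + 1}" for i in range(n_obs)]
    order = list(rng.permutation(names))
    edges: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n_obs), 2):
        if rng.random() < edge_prob:
            edges.append((order[i], order[j]))
    latents = [f"U{k + 1}" for k in range(n_latent_confounders)]
    for u in latents:
        a, b = rng.choice(n_obs, size=2, replace=False)
        edges.append((u, names[a]))
        edges.append((u, names[b]))
    g = MixedGraph.from_edges(directed=edges, latent=latents, nodes=names)
    card = {v: cardinality for v in g.nodes}
    parent_order = {v: tuple(sorted(g.parents(v))) for v in g.nodes}
    cpts = {}
    for v in g.nodes:
        shape = tuple(card[p] for p in parent_order[v]) + (card[v],)
        # Dirichlet rows, floored away from zero to keep positivity robust
        t = rng.dirichlet(np.ones(card[v]) * 2.0, size=shape[:-1]).reshape(shape)
        t = np.clip(t, 0.02, None)
        t = t / t.sum(axis=-1, keepdims=True)
        cpts[v] = t
    return DiscreteSCM(g, card, parent_order, cpts)


def _config_prob(scm: DiscreteSCM, assignment: dict[str, int], skip: frozenset[str]) -> float:
    p = 1.0
    for v in scm.graph.nodes:
        if v in skip:
            continue
        idx = tuple(assignment[q] for q in scm.parent_order[v]) + (assignment[v],)
        p *= float(scm.cpts[v][idx])
    return p


def exhaustive_joint(scm: DiscreteSCM) -> DiscreteJoint:
    """Exact observational joint over observables (latents summed out)."""
    if scm.state_space() > 10**6:
        raise GraphError("state space too large for exhaustive enumeration")
    obs = sorted(scm.graph.observable)
    lat = sorted(scm.graph.latent)
    shape = tuple(scm.cardinality[v] for v in obs)
    table = np.zeros(shape)
    all_vars = obs + lat
    for combo in itertools.product(*(range(scm.cardinality[v]) for v in all_vars)):
        assignment = dict(zip(all_vars, combo))
        table[tuple(assignment[v] for v in obs)] += _config_prob(scm, assignment, frozenset())
    return DiscreteJoint(obs, table)


def exhaustive_interventional(
    scm: DiscreteSCM, do: Mapping[str, int], y: str
) -> np.ndarray:
    """Exact ``P[y | do(...)]`` by truncated-factorisation enumeration.

    The intervened factors are deleted from the product and their values
    clamped; everything else (latents included) is summed out.
    """
    if scm.state_space() > 10**6:
        raise GraphError("state space too large for exhaustive enumeration")
    do = dict(do)
    for t in do:
        if t not in scm.graph.observable:
            raise GraphError(f"do-target {t!r} must be an observable node")
    free = [v for v in sorted(scm.graph.nodes) if v not in do]
    out = np.zeros(scm.cardinality[y])
    skip = frozenset(do)
    for combo in itertools.product(*(range(scm.cardinality[v]) for v in free)):
        assignment = dict(zip(free, combo))
        assignment.update(do)
        out[assignment[y]] += _config_prob(scm, assignment, skip)
    total = out.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise GraphError(f"interventional mass {total} != 1")
    return out / total
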