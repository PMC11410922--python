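"""Independent oracles used to pin down the implementation.

These deliberately avoid the code paths they check: m-separation is
re-derived by exhaustive simple-path enumeration with the blocking rule
applied literally; ancestor sets by boolean matrix powers; chi-squared
statistics by brute-force expected-count arithmetic; interventional
distributions by graph mutilation plus re-enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

from netperturb import MixedGraph


# ---------------------------------------------------------------------------
# ancestors by boolean matrix powers


def ancestors_matrix_power(g: MixedGraph, s: set[str]) -> set[str]:
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    k = len(nodes)
    adj = np.zeros((k, k), dtype=bool)
    for u, v in g.directed:
        adj[idx[v], idx[u]] = True  # reversed: row v reaches parents
    reach = np.eye(k, dtype=bool)
    power = np.eye(k, dtype=bool)
    for _ in range(k):
        power = power @ adj
        reach |= power
    out: set[str] = set()
    for v in s:
        out |= {nodes[j] for j in np.nonzero(reach[idx[v]])[0]}
    return out


# ---------------------------------------------------------------------------
# m-separation by simple-path enumeration


def _edges_at(g: MixedGraph, node: str):
    """All mixed edges incident to ``node`` as (other, mark_at_node, mark_at_other).

    Marks are 'head' (arrow pointing at the endpoint) or 'tail'.
    """
    for u, v in g.directed:
        if u == node:
            yield v, "tail", "head"
        elif v == node:
            yield u, "head", "tail"
    for u, v in g.bidirected:
        if u == node:
            yield v, "head", "head"
        elif v == node:
            yield u, "head", "head"


def _descendant_sets(g: MixedGraph) -> dict[str, set[str]]:
    out = {}
    for v in g.nodes:
        seen = {v}
        stack = [v]
        while stack:
            n = stack.pop()
            for c in (w for u, w in g.directed if u == n):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        out[v] = seen
    return out


def m_separated_paths(g: MixedGraph, a: set[str], b: set[str], z: set[str]) -> bool:
    """Walk every simple path between a and b and apply the blocking rule."""
    desc = _descendant_sets(g)

    def path_open(marks: list[tuple[str, str]], inner: list[str]) -> bool:
        # marks[i] = (mark at inner node i from previous edge, mark from next edge)
        for node, (m_in, m_out) in zip(inner, marks):
            collider = m_in == "head" and m_out == "head"
            if collider:
                if not (desc[node] & z):
                    return False
            else:
                if node in z:
                    return False
        return True

    def dfs(node: str, visited: set[str], inner: list[str], marks: list[tuple[str, str]], incoming_mark: str) -> bool:
        for other, mark_here, mark_other in _edges_at(g, node):
            if other in visited:
                continue
            new_inner = inner + [node] if incoming_mark is not None else inner
            new_marks = marks + [(incoming_mark, mark_here)] if incoming_mark is not None else marks
            if other in b:
                if path_open(new_marks, new_inner):
                    return True
                continue
            if dfs(other, visited | {other}, new_inner, new_marks, mark_other):
                return True
        return False

    for start in a:
        if dfs(start, {start} | (a - {start}), [], [], None):
            return False
    return True


# ---------------------------------------------------------------------------
# brute-force chi-squared over a contingency table


def chi2_stat_bruteforce(table: np.ndarray) -> tuple[float, int]:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    rows, cols = table.shape
    for i in range(rows):
        for j in range(cols):
            expected = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - expected) ** 2 / expected
    return stat, (rows - 1) * (cols - 1)


# ---------------------------------------------------------------------------
# total effect by explicit path enumeration


def total_effect_paths(scm, x: str, y: str) -> float:
    import networkx as nx

    dg = nx.DiGraph()
    dg.add_nodes_from(scm.graph.nodes)
    dg.add_edges_from(scm.graph.directed)
    total = 0.0
    for path in nx.all_simple_paths(dg, x, y):
        prod = 1.0
        for u, v in zip(path, path[1:]):
            prod *= scm.weights[(u, v)]
        total += prod
    return total


# ---------------------------------------------------------------------------
# interventional distribution by graph mutilation + enumeration


def interventional_by_mutilation(scm, do: dict[str, int], y: str) -> np.ndarray:
    """Clamp each do-target's CPT to a point mass, then re-enumerate."""
    from netperturb.synthetic import DiscreteSCM, exhaustive_joint

    cpts = {}
    for v in scm.graph.nodes:
        t = np.array(scm.cpts[v], dtype=float)
        if v in do:
            shape = t.shape
            t = np.full(shape, 1e-300)  # keep "strictly positive" invariant
            t[..., do[v]] = 1.0
            t = t / t.sum(axis=-1, keepdims=True)
        cpts[v] = t
    # sever incoming edges is unnecessary: a constant CPT ignores parents
    mutilated = DiscreteSCM(scm.graph, scm.cardinality, scm.parent_order, cpts)
    joint = exhaustive_joint(mutilated)
    axis = [i for i, v in enumerate(joint.variables) if v != y]
    return joint.table.sum(axis=tuple(axis))


# ---------------------------------------------------------------------------
# random graph generators for censuses


def random_admg(rng: np.random.Generator, n_nodes: int, p_dir: float = 0.35, p_bi: float = 0.2) -> MixedGraph:
    names = [f"V{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    directed = [
        (order[i], order[j])
        for i, j in itertools.combinations(range(n_nodes), 2)
        if rng.random() < p_dir
    ]
    bidirected = [
        (names[i], names[j])
        for i, j in itertools.combinations(range(n_nodes), 2)
        if rng.random() < p_bi
    ]
    return MixedGraph.from_edges(directed=directed, bidirected=bidirected, nodes=names)


def random_latent_dag(rng: np.random.Generator, n_nodes: int, p_dir: float = 0.4, p_latent: float = 0.3) -> MixedGraph:
    names = [f"V{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    directed = [
        (order[i], order[j])
        for i, j in itertools.combinations(range(n_nodes), 2)
        if rng.random() < p_dir
    ]
    latent = {v for v in names if rng.random() < p_latent}
    if len(latent) == len(names):
        latent.discard(order[-1])
    return MixedGraph.from_edges(directed=directed, latent=latent, nodes=names)
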