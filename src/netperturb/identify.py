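"""Causal-query identification on ADMGs via the recursive ID procedure.

Given an exposure ``X`` and outcome ``Y`` in an acyclic directed mixed
graph, :func:`identify` decides whether the interventional distribution
``P[Y | do(X=x)]`` is expressible as a functional of the observational
joint, and when it is, returns that functional as a symbolic
:class:`Estimand` tree.  The recursion decomposes the graph into
*districts* (connected components of the bidirected subgraph) and either
rewrites the query over smaller subgraphs or exhibits a hedge — the
structure witnessing non-identifiability.

Estimands evaluate numerically against a :class:`DiscreteJoint`
probability table, which is how correctness is defined and tested here:
an estimand is right when its value on any positive observational joint
consistent with the graph equals the true interventional distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .graphs import GraphError, MixedGraph, ancestors, latent_project

__all__ = [
    "Estimand",
    "PTerm",
    "Product",
    "SumOver",
    "Fraction",
    "IdentificationResult",
    "NotIdentifiable",
    "DiscreteJoint",
    "districts",
    "identify",
    "evaluate_estimand",
]


# ---------------------------------------------------------------------------
# estimand expression tree


class Estimand:
    """Base class for symbolic estimand expressions."""

    def free_vars(self) -> frozenset[str]:
        raise NotImplementedError

    def all_vars(self) -> frozenset[str]:
        """Every variable mentioned anywhere in the tree, bound or free."""
        raise NotImplementedError

    def to_json(self) -> dict:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pretty()

    def pretty(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class PTerm(Estimand):
    """Observational probability term ``P(outcomes | given)``."""

    outcomes: frozenset[str]
    given: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        object.__setattr__(self, "given", frozenset(self.given))
        if not self.outcomes:
            raise GraphError("PTerm needs at least one outcome variable")
        if self.outcomes & self.given:
            raise GraphError("PTerm outcomes and conditioning set overlap")

    def free_vars(self) -> frozenset[str]:
        return self.outcomes | self.given

    def all_vars(self) -> frozenset[str]:
        return self.outcomes | self.given

    def pretty(self) -> str:
        o = ", ".join(sorted(self.outcomes))
        if self.given:
            return f"P({o} | {', '.join(sorted(self.given))})"
        return f"P({o})"

    def to_json(self) -> dict:
        return {"kind": "p", "outcomes": sorted(self.outcomes), "given": sorted(self.given)}


@dataclass(frozen=True)
class Product(Estimand):
    factors: tuple[Estimand, ...]

    def free_vars(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for f in self.factors:
            out |= f.free_vars()
        return out

    def all_vars(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for f in self.factors:
            out |= f.all_vars()
        return out

    def pretty(self) -> str:
        return " ".join(f"[{f.pretty()}]" for f in self.factors)

    def to_json(self) -> dict:
        return {"kind": "product", "factors": [f.to_json() for f in self.factors]}


@dataclass(frozen=True)
class SumOver(Estimand):
    """Marginalisation: sum of ``expr`` over all values of ``variables``."""

    variables: frozenset[str]
    expr: Estimand

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", frozenset(self.variables))

    def free_vars(self) -> frozenset[str]:
        return self.expr.free_vars() - self.variables

    def all_vars(self) -> frozenset[str]:
        return self.expr.all_vars() | self.variables

    def pretty(self) -> str:
        v = ", ".join(sorted(self.variables))
        return f"Sum_{{{v}}} {self.expr.pretty()}"

    def to_json(self) -> dict:
        return {"kind": "sum", "variables": sorted(self.variables), "expr": self.expr.to_json()}


@dataclass(frozen=True)
class Fraction(Estimand):
    numerator: Estimand
    denominator: Estimand

    def free_vars(self) -> frozenset[str]:
        return self.numerator.free_vars() | self.denominator.free_vars()

    def all_vars(self) -> frozenset[str]:
        return self.numerator.all_vars() | self.denominator.all_vars()

    def pretty(self) -> str:
        return f"({self.numerator.pretty()}) / ({self.denominator.pretty()})"

    def to_json(self) -> dict:
        return {
            "kind": "fraction",
            "numerator": self.numerator.to_json(),
            "denominator": self.denominator.to_json(),
        }


def _product(factors: list[Estimand]) -> Estimand:
    if len(factors) == 1:
        return factors[0]
    return Product(tuple(factors))


def _sum_over(variables: Iterable[str], expr: Estimand) -> Estimand:
    variables = frozenset(variables) & expr.free_vars()
    if not variables:
        return expr
    if isinstance(expr, PTerm) and not expr.given:
        remaining = expr.outcomes - variables
        if remaining:  # marginal of a joint term is itself a joint term
            return PTerm(remaining)
    if isinstance(expr, SumOver):
        return SumOver(expr.variables | variables, expr.expr)
    return SumOver(variables, expr)


def _conditional(q: Estimand, v: str, prefix: frozenset[str]) -> Estimand:
    """Conditional ``Q(v | prefix)`` of the distribution expression ``q``.

    When ``q`` is a plain joint term the conditional simplifies to a
    single ``PTerm``; otherwise a fraction of marginalisations is built.
    """
    if isinstance(q, PTerm) and not q.given:
        # Q is the joint over q.outcomes
        scope = q.outcomes
        keep = (prefix | {v}) & scope
        return PTerm(frozenset({v}), frozenset(keep - {v}))
    scope = q.free_vars()
    num = _sum_over(scope - (prefix | {v}), q)
    den = _sum_over(scope - prefix, q)
    return Fraction(num, den)


# ---------------------------------------------------------------------------
# identification


@dataclass(frozen=True)
class IdentificationResult:
    status: str  # "identifiable" | "not_identifiable"
    estimand: Estimand | None = None
    witness: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("identifiable", "not_identifiable"):
            raise GraphError(f"bad status {self.status!r}")
        if (self.estimand is None) == (self.status == "identifiable"):
            raise GraphError("estimand must be present exactly when identifiable")


class NotIdentifiable(Exception):
    """Internal signal: a hedge was found."""

    def __init__(self, witness: str) -> None:
        super().__init__(witness)
        self.witness = witness


def districts(g: MixedGraph) -> list[frozenset[str]]:
    """Connected components of the bidirected subgraph over observables."""
    obs = g.observable
    comp: dict[str, set[str]] = {v: {v} for v in obs}
    for u, v in g.bidirected:
        if u in obs and v in obs and comp[u] is not comp[v]:
            merged = comp[u] | comp[v]
            for w in merged:
                comp[w] = merged
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for v in sorted(obs):
        d = frozenset(comp[v])
        if d not in seen:
            seen.add(d)
            out.append(d)
    return out


def _id(
    y: frozenset[str],
    x: frozenset[str],
    q: Estimand,
    g: MixedGraph,
    order: list[str],
) -> Estimand:
    """One call of the recursive identification procedure.

    ``order`` is a fixed topological order of the full graph; each level
    restricts it to the current scope.
    """
    v = frozenset(g.nodes)

    # line 1: no intervention left -> marginalise
    if not x:
        return _sum_over(v - y, q)

    # line 2: restrict to ancestors of y
    an_y = frozenset(ancestors(g, y))
    if v != an_y:
        return _id(y, x & an_y, _sum_over(v - an_y, q), g.subgraph(an_y), order)

    # line 3: enlarge x with variables that cannot affect y once x is fixed
    g_bar_x = g.remove_incoming(x)
    w = (v - x) - frozenset(ancestors(g_bar_x, y))
    if w:
        return _id(y, x | w, q, g, order)

    # line 4: factorise over the districts of G minus x
    ds = districts(g.subgraph(v - x))
    if len(ds) > 1:
        factors = [_id(s, v - s, q, g, order) for s in ds]
        return _sum_over(v - (y | x), _product(factors))

    (s,) = ds
    ds_full = districts(g)

    # line 5: the whole graph is one district -> hedge
    if len(ds_full) == 1 and ds_full[0] == v:
        raise NotIdentifiable(
            f"hedge: C-forests over district {sorted(v)} and subdistrict {sorted(s)}"
        )

    # line 6: s is itself a district of G -> chain-rule factorisation
    if s in ds_full:
        local = [n for n in order if n in v]
        factors = []
        for i, vi in enumerate(local):
            if vi in s:
                factors.append(_conditional(q, vi, frozenset(local[:i])))
        return _sum_over(s - y, _product(factors))

    # line 7: recurse into the enclosing district s'
    s_prime = next(d for d in ds_full if s <= d)
    local = [n for n in order if n in v]
    factors = []
    for i, vi in enumerate(local):
        if vi in s_prime:
            factors.append(_conditional(q, vi, frozenset(local[:i])))
    q_prime = _product(factors)
    return _id(y, x & s_prime, q_prime, g.subgraph(s_prime), order)


def identify(g: MixedGraph, x: str | Iterable[str], y: str | Iterable[str]) -> IdentificationResult:
    """Decide identifiability of ``P[y | do(x)]`` and return the estimand.

    The graph may contain latent marks; it is latent-projected to an
    ADMG over observables first.  ``x`` and ``y`` must be observable and
    disjoint.
    """
    xs = frozenset([x] if isinstance(x, str) else x)
    ys = frozenset([y] if isinstance(y, str) else y)
    if xs & ys:
        raise GraphError("exposure and outcome sets overlap")
    for n in xs | ys:
        if n not in g.nodes:
            raise GraphError(f"unknown node {n!r}")
        if n in g.latent:
            raise GraphError(f"query variable {n!r} is latent")
    admg = latent_project(g) if g.latent else g
    order = admg.topological_order()
    joint = PTerm(frozenset(admg.nodes))
    try:
        est = _id(ys, xs, joint, admg, order)
    except NotIdentifiable as exc:
        return IdentificationResult("not_identifiable", None, exc.witness)
    # The recursion may leave auxiliary intervened variables free (their
    # values are provably irrelevant to the query); average them against
    # their observational marginal, which preserves the value on every
    # distribution consistent with the graph.
    stray = est.free_vars() - xs - ys
    if stray:
        est = SumOver(stray, Product((PTerm(stray), est)))
    return IdentificationResult("identifiable", est, None)


# ---------------------------------------------------------------------------
# numeric evaluation


class DiscreteJoint:
    """Joint probability table over named discrete variables.

    ``table`` is an n-dimensional array whose axes follow ``variables``;
    entries sum to one.
    """

    def __init__(self, variables: list[str], table: np.ndarray) -> None:
        table = np.asarray(table, dtype=float)
        if table.ndim != len(variables):
            raise ValueError("table rank must match number of variables")
        if not np.isclose(table.sum(), 1.0, atol=1e-8):
            raise ValueError(f"joint must sum to 1, got {table.sum()}")
        if (table < 0).any():
            raise ValueError("negative probability entry")
        self.variables = list(variables)
        self.table = table
        self._axis = {v: i for i, v in enumerate(self.variables)}
        self._marginals: dict[frozenset[str], np.ndarray] = {}

    def cardinality(self, v: str) -> int:
        return self.table.shape[self._axis[v]]

    def marginal(self, vs: frozenset[str]) -> np.ndarray:
        """Marginal table over ``vs``, axes in self.variables order."""
        vs = frozenset(vs)
        if vs not in self._marginals:
            drop = tuple(i for i, v in enumerate(self.variables) if v not in vs)
            self._marginals[vs] = self.table.sum(axis=drop) if drop else self.table
        return self._marginals[vs]

    def prob(self, assignment: Mapping[str, int], vs: frozenset[str]) -> float:
        """P(vs = assignment restricted to vs)."""
        m = self.marginal(vs)
        idx = tuple(assignment[v] for v in self.variables if v in vs)
        return float(m[idx])


class EstimandEvalError(ValueError):
    """Raised when an estimand hits a zero-probability denominator."""


def _eval(e: Estimand, joint: DiscreteJoint, assignment: dict[str, int]) -> float:
    if isinstance(e, PTerm):
        num = joint.prob(assignment, e.outcomes | e.given)
        if not e.given:
            return num
        den = joint.prob(assignment, e.given)
        if den == 0.0:
            raise EstimandEvalError(f"zero-probability conditioning event in {e.pretty()}")
        return num / den
    if isinstance(e, Product):
        out = 1.0
        for f in e.factors:
            out *= _eval(f, joint, assignment)
        return out
    if isinstance(e, SumOver):
        total = 0.0
        svars = sorted(e.variables)
        saved = {v: assignment[v] for v in svars if v in assignment}  # shadowed bindings
        for combo in itertools.product(*(range(joint.cardinality(v)) for v in svars)):
            assignment.update(zip(svars, combo))
            total += _eval(e.expr, joint, assignment)
        for v in svars:
            del assignment[v]
        assignment.update(saved)
        return total
    if isinstance(e, Fraction):
        den = _eval(e.denominator, joint, assignment)
        if den == 0.0:
            raise EstimandEvalError(f"zero denominator in {e.denominator.pretty()}")
        return _eval(e.numerator, joint, assignment) / den
    raise TypeError(f"unknown estimand node {type(e).__name__}")


def evaluate_estimand(
    e: Estimand,
    joint: DiscreteJoint,
    intervention: Mapping[str, int],
    outcome: str,
) -> np.ndarray:
    """Evaluate an estimand into ``P[outcome | do(intervention)]``.

    Returns a probability vector over the outcome's levels, normalised;
    a deviation of the raw sum from one beyond numerical tolerance is an
    error, since a correct estimand integrates to one exactly.
    """
    missing = e.free_vars() - set(intervention) - {outcome}
    if missing:
        raise GraphError(f"estimand has unbound variables: {sorted(missing)}")
    card = joint.cardinality(outcome)
    vec = np.empty(card)
    for yv in range(card):
        assignment = dict(intervention)
        assignment[outcome] = yv
        vec[yv] = _eval(e, joint, assignment)
    total = vec.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise EstimandEvalError(f"estimand mass {total} differs from 1")
    return vec / total
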