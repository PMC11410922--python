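"""Estimators of causal queries from observational steady-state data.

Supported query forms are the average treatment effect
``ATE = E[Y|do(X=x1)] - E[Y|do(X=x0)]``, the interventional mean
``E[Y|do(X=x)]``, and the interventional distribution ``P[Y|do(X=x)]``.

Estimator families:

* covariate adjustment with the efficiency-oriented *optimal* set (the
  observable parents of the causal pathway), via ordinary least squares
  for approximately linear-Gaussian systems;
* nonparametric ATE estimators for binary exposures — outcome
  regression (g-computation), inverse-probability weighting with a
  logistic propensity model, and the doubly robust AIPW combination;
* a fully nonparametric plug-in that evaluates an identified estimand
  on the empirical joint of discrete data, covering queries (such as
  front-door graphs) that no adjustment set can reach.

Interval estimates are percentile bootstrap over replicate resampling,
seeded and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .graphs import GraphError, MixedGraph, ancestors, descendants, m_separated
from .identify import DiscreteJoint, Estimand, EstimandEvalError, evaluate_estimand, identify
from .reduction import causal_path_nodes

__all__ = [
    "CausalQuery",
    "EstimationResult",
    "EstimationError",
    "optimal_adjustment_set",
    "estimate_linear",
    "estimate_ate_nonparametric",
    "estimate_plugin_discrete",
    "select_estimator",
]


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class CausalQuery:
    """A single-exposure, single-outcome interventional query."""

    exposure: str
    outcome: str
    form: Literal["ate", "expected_value", "distribution"] = "ate"
    x1: float = 1.0
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.exposure == self.outcome:
            raise GraphError("exposure and outcome must differ")
        if self.form not in ("ate", "expected_value", "distribution"):
            raise GraphError(f"unknown query form {self.form!r}")


@dataclass(frozen=True)
class EstimationResult:
    point: float
    estimator: str
    adjustment_set: frozenset[str] | None = None
    interval: tuple[float, float] | None = None
    level: float | None = None
    bootstrap_draws: tuple[float, ...] | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval is not None:
            low, high = self.interval
            if not (low <= self.point <= high):
                raise EstimationError("interval must bracket the point estimate")

    def to_json(self) -> dict:
        return {
            "point": self.point,
            "estimator": self.estimator,
            "adjustment_set": sorted(self.adjustment_set) if self.adjustment_set is not None else None,
            "interval": list(self.interval) if self.interval else None,
            "level": self.level,
            "detail": {k: v for k, v in self.detail.items() if not isinstance(v, np.ndarray)},
        }


# ---------------------------------------------------------------------------
# adjustment sets


def _forbidden(g: MixedGraph, x: str, y: str) -> set[str]:
    cp = causal_path_nodes(g, x, y)
    return descendants(g, cp | {x}) if cp else {x}


def _proper_backdoor_graph(g: MixedGraph, x: str, y: str) -> MixedGraph:
    cp = causal_path_nodes(g, x, y)
    cut = frozenset((x, c) for c in g.children(x) if c in cp)
    return MixedGraph(g.nodes, g.directed - cut, g.bidirected, g.latent)


def is_valid_adjustment_set(g: MixedGraph, x: str, y: str, z: Iterable[str]) -> bool:
    """Generalised adjustment criterion, checked by m-separation.

    ``z`` is valid iff it avoids the forbidden set (descendants of the
    causal pathway, and ``x`` itself) and blocks every proper
    non-causal path from ``x`` to ``y`` — i.e. ``x`` and ``y`` are
    m-separated given ``z`` in the proper back-door graph.
    """
    z = frozenset(z)
    if z & _forbidden(g, x, y) or y in z:
        return False
    if z & g.latent:
        return False
    return m_separated(_proper_backdoor_graph(g, x, y), {x}, {y}, z)


def optimal_adjustment_set(g: MixedGraph, x: str, y: str) -> frozenset[str] | None:
    """Efficiency-oriented adjustment set, or ``None`` when none exists.

    The candidate is the observable parents of the causal-pathway nodes
    (minus the pathway and the exposure) — the set that minimises the
    asymptotic variance of adjusted estimators in linear systems.  Its
    validity is verified by m-separation in the proper back-door graph;
    if confounding arcs defeat it, the canonical ancestral set
    ``An(x,y) minus forbidden`` is tried before concluding that no
    valid adjustment set exists.
    """
    cp = causal_path_nodes(g, x, y)
    o = set()
    for c in cp:
        o |= g.parents(c)
    o -= cp | {x}
    o &= g.observable
    if is_valid_adjustment_set(g, x, y, o):
        return frozenset(o)
    fallback = (ancestors(g, {x, y}) & g.observable) - _forbidden(g, x, y) - {x, y}
    if is_valid_adjustment_set(g, x, y, fallback):
        return frozenset(fallback)
    return None


# ---------------------------------------------------------------------------
# linear estimator


def _ols(ymat: np.ndarray, design: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise EstimationError(f"rank-deficient design matrix (columns {names})")
    beta, *_ = np.linalg.lstsq(design, ymat, rcond=None)
    return beta


def _percentile_interval(
    draws: np.ndarray, point: float, level: float
) -> tuple[float, float]:
    lo = float(np.quantile(draws, (1 - level) / 2))
    hi = float(np.quantile(draws, 1 - (1 - level) / 2))
    return min(lo, point), max(hi, point)


def estimate_linear(
    data: pd.DataFrame,
    g: MixedGraph,
    q: CausalQuery,
    bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EstimationResult:
    """Covariate-adjusted ordinary least squares under linearity.

    Regresses the outcome on the exposure and the optimal adjustment
    set.  The exposure coefficient is the total causal effect per unit,
    so ``ATE(x1, x0) = beta_x * (x1 - x0)`` and
    ``E[Y|do(X=x)] = b0 + beta_x * x + sum_o beta_o * mean(o)``.  The
    ``distribution`` form reports the implied Gaussian (interventional
    mean, residual standard deviation).
    """
    adj = optimal_adjustment_set(g, q.exposure, q.outcome)
    if adj is None:
        raise EstimationError(
            "no valid adjustment set exists for this query; "
            "use the discrete plug-in estimator on the identified estimand"
        )
    cols = [q.exposure, *sorted(adj)]
    missing = [c for c in cols + [q.outcome] if c not in data.columns]
    if missing:
        raise EstimationError(f"columns missing from data: {missing}")
    n = len(data)
    if n <= len(adj) + 2:
        raise EstimationError(f"need n > |adjustment| + 2, got n = {n}")
    xmat = data[cols].to_numpy(dtype=float)
    yvec = data[q.outcome].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), xmat])

    def point_from(design_: np.ndarray, y_: np.ndarray, x_: np.ndarray) -> tuple[float, float]:
        beta = _ols(y_, design_, ["(intercept)", *cols])
        b0, bx, brest = beta[0], beta[1], beta[2:]
        if q.form == "ate":
            return float(bx * (q.x1 - q.x0)), float("nan")
        mean_adj = x_[:, 1:].mean(axis=0) if x_.shape[1] > 1 else np.empty(0)
        ev = float(b0 + bx * q.x1 + brest @ mean_adj)
        resid = y_ - design_ @ beta
        sd = float(np.sqrt(resid @ resid / max(len(y_) - design_.shape[1], 1)))
        return ev, sd
    point, resid_sd = point_from(design, yvec, xmat)

    draws = None
    interval = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        vals = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b], _ = point_from(design[idx], yvec[idx], xmat[idx])
            except EstimationError:
                vals[b] = np.nan
        draws = vals[~np.isnan(vals)]
        if len(draws):
            interval = _percentile_interval(draws, point, level)
    detail: dict = {"n": n}
    if q.form == "distribution":
        detail["distribution"] = {"family": "normal", "mean": point, "sd": resid_sd}
    return EstimationResult(
        point=point,
        estimator="linear",
        adjustment_set=adj,
        interval=interval,
        level=level if interval else None,
        bootstrap_draws=tuple(float(v) for v in draws) if draws is not None else None,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# nonparametric ATE estimators (binary exposure)


def _binary_exposure(data: pd.DataFrame, x: str) -> np.ndarray:
    vals = np.unique(data[x].to_numpy())
    if len(vals) != 2:
        raise EstimationError(f"exposure {x!r} must be binary, found levels {vals[:5]}")
    return (data[x].to_numpy() == vals.max()).astype(float)


def _propensity(t: np.ndarray, z: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    import statsmodels.api as sm

    design = sm.add_constant(z, has_constant="add")
    with np.errstate(all="ignore"):
        model = sm.GLM(t, design, family=sm.families.Binomial()).fit()
        e = np.asarray(model.predict(design))
    n_trunc = int(((e < eps) | (e > 1 - eps)).sum())
    return np.clip(e, eps, 1 - eps), n_trunc


def _arm_means(t, yvec, z):
    """Per-arm linear outcome models evaluated at every covariate row."""
    n = len(yvec)
    design = np.column_stack([np.ones(n), z]) if z.size else np.ones((n, 1))
    mu = np.empty((2, n))
    for arm in (0, 1):
        mask = t == arm
        if mask.sum() <= design.shape[1]:
            raise EstimationError(f"too few observations in exposure arm {arm}")
        beta, *_ = np.linalg.lstsq(design[mask], yvec[mask], rcond=None)
        mu[arm] = design @ beta
    return mu


def estimate_ate_nonparametric(
    data: pd.DataFrame,
    g: MixedGraph,
    q: CausalQuery,
    method: Literal["outcome_regression", "ipw", "aipw"] = "aipw",
    eps: float = 0.01,
    bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EstimationResult:
    """ATE for a binary exposure by adjustment-based nonparametric estimators.

    ``outcome_regression`` standardises per-arm outcome models over the
    covariate distribution; ``ipw`` reweights by the inverse estimated
    propensity (truncated to ``[eps, 1-eps]``); ``aipw`` combines both
    and is consistent when either model is correct (double robustness).
    """
    if q.form != "ate":
        raise EstimationError("nonparametric estimators support the ATE form only")
    adj = optimal_adjustment_set(g, q.exposure, q.outcome)
    if adj is None:
        raise EstimationError("no valid adjustment set exists for this query")
    t_all = _binary_exposure(data, q.exposure)
    y_all = data[q.outcome].to_numpy(dtype=float)
    z_all = data[sorted(adj)].to_numpy(dtype=float) if adj else np.empty((len(data), 0))

    def compute(t, yvec, z) -> tuple[float, int]:
        trunc = 0
        if method == "outcome_regression":
            mu = _arm_means(t, yvec, z)
            return float(mu[1].mean() - mu[0].mean()), trunc
        e, trunc = _propensity(t, z, eps)
        if method == "ipw":
            # Hajek-normalised inverse-probability weighting
            w1, w0 = t / e, (1 - t) / (1 - e)
            return float((w1 * yvec).sum() / w1.sum() - (w0 * yvec).sum() / w0.sum()), trunc
        mu = _arm_means(t, yvec, z)
        aug1 = mu[1] + t * (yvec - mu[1]) / e
        aug0 = mu[0] + (1 - t) * (yvec - mu[0]) / (1 - e)
        return float(aug1.mean() - aug0.mean()), trunc

    point, n_trunc = compute(t_all, y_all, z_all)
    draws = None
    interval = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(data)
        vals = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b], _ = compute(t_all[idx], y_all[idx], z_all[idx])
            except EstimationError:
                vals[b] = np.nan
        draws = vals[~np.isnan(vals)]
        if len(draws):
            interval = _percentile_interval(draws, point, level)
    detail = {"n": len(data), "propensity_truncated": n_trunc}
    return EstimationResult(
        point=point,
        estimator=method,
        adjustment_set=adj,
        interval=interval,
        level=level if interval else None,
        bootstrap_draws=tuple(float(v) for v in draws) if draws is not None else None,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# discrete plug-in on the identified estimand


def _empirical_joint(data: pd.DataFrame, variables: list[str]) -> tuple[DiscreteJoint, dict]:
    levels = {v: np.unique(data[v].to_numpy()) for v in variables}
    shape = tuple(len(levels[v]) for v in variables)
    codes = np.column_stack(
        [np.searchsorted(levels[v], data[v].to_numpy()) for v in variables]
    )
    table = np.zeros(shape)
    np.add.at(table, tuple(codes.T), 1.0)
    return DiscreteJoint(variables, table / table.sum()), levels


def _plugin_point(joint: DiscreteJoint, levels, e, q, xcode_map) -> float | np.ndarray:
    y = q.outcome
    yvals = levels[y].astype(float)

    def dist_at(xval) -> np.ndarray:
        return evaluate_estimand(e, joint, {q.exposure: xcode_map(xval)}, y)

    if q.form == "distribution":
        return dist_at(q.x1)
    if q.form == "expected_value":
        return float(dist_at(q.x1) @ yvals)
    return float(dist_at(q.x1) @ yvals - dist_at(q.x0) @ yvals)


def estimate_plugin_discrete(
    data: pd.DataFrame,
    e: Estimand,
    q: CausalQuery,
    bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EstimationResult:
    """Plug-in evaluation of an identified estimand on the empirical joint.

    Fully nonparametric: the observational joint is replaced by observed
    cell frequencies and the estimand tree is evaluated symbolically.
    Zero empirical cells hit by a denominator raise an error naming the
    offending term.
    """
    variables = sorted(e.all_vars() | {q.exposure, q.outcome})
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise EstimationError(f"columns missing from data: {missing}")
    joint, levels = _empirical_joint(data, variables)

    def xcode(xval):
        lv = levels[q.exposure]
        idx = np.searchsorted(lv, xval)
        if idx >= len(lv) or lv[idx] != xval:
            raise EstimationError(f"intervention value {xval!r} not observed for {q.exposure!r}")
        return int(idx)

    try:
        point = _plugin_point(joint, levels, e, q, xcode)
    except EstimandEvalError as exc:
        raise EstimationError(str(exc)) from exc
    is_dist = q.form == "distribution"
    draws = None
    interval = None
    if bootstrap > 0 and not is_dist:
        rng = np.random.default_rng(seed)
        n = len(data)
        vals = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                bj, blev = _empirical_joint(data.iloc[idx], variables)
                vals[b] = _plugin_point(bj, blev, e, q, xcode)
            except (EstimandEvalError, EstimationError, ValueError):
                vals[b] = np.nan
        draws = vals[~np.isnan(vals)]
        if len(draws):
            interval = _percentile_interval(draws, float(point), level)
    detail: dict = {"n": len(data)}
    if is_dist:
        detail["distribution"] = {
            "levels": [float(v) for v in levels[q.outcome]],
            "probabilities": [float(p) for p in point],
        }
        scalar = float(np.asarray(point) @ levels[q.outcome].astype(float))
    else:
        scalar = float(point)
    return EstimationResult(
        point=scalar,
        estimator="plugin",
        adjustment_set=None,
        interval=interval,
        level=level if interval else None,
        bootstrap_draws=tuple(float(v) for v in draws) if draws is not None else None,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# estimator selection


def select_estimator(
    g: MixedGraph,
    q: CausalQuery,
    data: pd.DataFrame,
    assume_linear: bool = True,
) -> str:
    """Deterministic estimator-selection policy.

    With a valid adjustment set and a continuous outcome the linear
    adjusted estimator is used; for a binary exposure with the
    linearity assumption released, AIPW.  Identifiable queries with no
    adjustment set fall back to the discrete plug-in when all relevant
    columns are discrete.  Anything else is an explicit unsupported
    case.
    """
    from .consistency import column_kinds

    res = identify(g, q.exposure, q.outcome)
    if res.status != "identifiable":
        raise EstimationError("query is not identifiable; no estimator applies")
    kinds = column_kinds(data)
    adj = optimal_adjustment_set(g, q.exposure, q.outcome)
    y_cont = kinds.get(q.outcome) == "continuous"
    if adj is not None:
        if y_cont:
            x_binary = data[q.exposure].nunique() == 2
            if x_binary and not assume_linear and q.form == "ate":
                return "aipw"
            return "linear"
        relevant = [q.exposure, q.outcome, *sorted(adj)]
        if all(kinds[c] == "discrete" for c in relevant):
            return "plugin"
        raise EstimationError(
            "no implemented estimator for a discrete outcome with mixed-type covariates"
        )
    relevant = sorted(res.estimand.free_vars() | {q.exposure, q.outcome})
    if all(kinds.get(c) == "discrete" for c in relevant):
        return "plugin"
    raise EstimationError(
        "query is identifiable but only via a non-adjustment functional, "
        "which requires discrete data for the plug-in estimator"
    )
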