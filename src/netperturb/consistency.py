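"""Graph–data consistency: test implied independencies, repair on failure.

A network that is faithful to the data should not imply conditional
independencies that the data reject.  This module enumerates the
independencies a mixed graph implies, tests each against the
observational table — Fisher-z (partial correlation) for continuous
columns, a stratified Pearson chi-squared test for discrete columns —
and reports the fraction of failures.  Failed pairs can then be
repaired by adding a bidirected edge, the graphical signature of an
unmeasured common cause.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import CIStatement, GraphError, MixedGraph, implied_independencies

__all__ = [
    "CITestResult",
    "ConsistencyReport",
    "column_kinds",
    "fisher_z_test",
    "chi_squared_test",
    "test_consistency",
    "repair_graph",
]


class DataError(ValueError):
    """Raised for tables that cannot support the requested test."""


def column_kinds(data: pd.DataFrame, overrides: dict[str, str] | None = None) -> dict[str, str]:
    """Classify each column as ``continuous`` or ``discrete``.

    Floating-point columns are continuous; integer, boolean, categorical
    and string columns are discrete.  ``overrides`` wins when supplied.
    """
    kinds: dict[str, str] = {}
    for c in data.columns:
        if overrides and c in overrides:
            kind = overrides[c]
            if kind not in ("continuous", "discrete"):
                raise DataError(f"override for {c!r} must be continuous|discrete")
            kinds[c] = kind
        elif pd.api.types.is_float_dtype(data[c]):
            kinds[c] = "continuous"
        else:
            kinds[c] = "discrete"
    return kinds


@dataclass(frozen=True)
class CITestResult:
    statement: CIStatement
    test_name: str  # fisher_z | chi_squared
    statistic: float
    p_value: float
    failed: bool
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConsistencyReport:
    results: tuple[CITestResult, ...]
    alpha: float
    max_cond: int
    skipped: tuple[str, ...] = ()

    @property
    def n_tests(self) -> int:
        return len(self.results)

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.results)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_tests if self.n_tests else 0.0

    def failed_pairs(self) -> list[tuple[str, str]]:
        pairs = {(r.statement.left, r.statement.right) for r in self.results if r.failed}
        return sorted(pairs)

    def to_json(self) -> dict:
        return {
            "alpha": self.alpha,
            "max_cond": self.max_cond,
            "n_tests": self.n_tests,
            "n_failed": self.n_failed,
            "failure_fraction": self.failure_fraction,
            "skipped": list(self.skipped),
            "results": [
                {
                    "left": r.statement.left,
                    "right": r.statement.right,
                    "given": sorted(r.statement.given),
                    "test": r.test_name,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "failed": r.failed,
                }
                for r in self.results
            ],
        }


# ---------------------------------------------------------------------------
# individual tests

_MAX_Z = 38.0  # beyond this the normal tail underflows to exactly 0


def fisher_z_test(data: pd.DataFrame, stmt: CIStatement, alpha: float = 0.01) -> CITestResult:
    """Fisher-z test of zero partial correlation for Gaussian data.

    The partial correlation ``r`` of the tested pair given the
    conditioning set is mapped to ``z = atanh(r) * sqrt(n - |given| - 3)``,
    which is standard normal under the null of conditional independence.
    """
    cols = [stmt.left, stmt.right, *sorted(stmt.given)]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns missing from data: {missing}")
    x = data[cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("tested columns contain missing values")
    n = x.shape[0]
    k = len(stmt.given)
    if n <= k + 3:
        raise DataError(f"need n > |given| + 3 (= {k + 3}), got n = {n}")
    corr = np.corrcoef(x, rowvar=False)
    if np.isnan(corr).any():
        bad = [cols[i] for i in range(len(cols)) if np.isnan(corr[i]).any()]
        raise DataError(f"constant column(s) make the test undefined: {bad}")
    if k == 0:
        r = corr[0, 1]
    else:
        # partial correlation = correlation of residuals after regressing
        # the pair on the conditioning set
        zmat = np.column_stack([np.ones(n), x[:, 2:]])
        if np.linalg.matrix_rank(zmat) < zmat.shape[1]:
            raise DataError(
                f"conditioning covariance is singular (collinear columns among {sorted(stmt.given)})"
            )
        coef, *_ = np.linalg.lstsq(zmat, x[:, :2], rcond=None)
        resid = x[:, :2] - zmat @ coef
        r = np.corrcoef(resid, rowvar=False)[0, 1]
        if np.isnan(r):
            raise DataError(
                f"pair is deterministically explained by the conditioning set {sorted(stmt.given)}"
            )
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        z = math.copysign(_MAX_Z, r)
    else:
        z = math.atanh(r) * math.sqrt(n - k - 3)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CITestResult(stmt, "fisher_z", z, p, p < alpha, {"partial_corr": r, "n": n})


def chi_squared_test(data: pd.DataFrame, stmt: CIStatement, alpha: float = 0.01) -> CITestResult:
    """Stratified Pearson chi-squared test of conditional independence.

    Within each configuration of the conditioning variables, the Pearson
    statistic of the left × right contingency table is computed; the
    statistics and their degrees of freedom are summed across strata.
    Strata too thin to test (a single observation, or a degenerate
    table) are skipped and counted.
    """
    cols = [stmt.left, stmt.right, *sorted(stmt.given)]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns missing from data: {missing}")
    sub = data[cols]
    if sub.isna().any().any():
        raise DataError("tested columns contain missing values")
    if stmt.given:
        groups = sub.groupby(list(sorted(stmt.given)), observed=True, sort=True)
        strata = [grp for _, grp in groups]
    else:
        strata = [sub]
    stat = 0.0
    dof = 0
    skipped = 0
    for grp in strata:
        if len(grp) < 2:
            skipped += 1
            continue
        table = pd.crosstab(grp[stmt.left], grp[stmt.right]).to_numpy(dtype=float)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            skipped += 1
            continue
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum @ colsum / table.sum()
        stat += float(((table - expected) ** 2 / expected).sum())
        dof += (table.shape[0] - 1) * (table.shape[1] - 1)
    if dof == 0:
        # nothing testable: treat as a vacuous pass
        return CITestResult(stmt, "chi_squared", 0.0, 1.0, False, {"skipped_strata": skipped, "dof": 0})
    p = float(stats.chi2.sf(stat, dof))
    return CITestResult(
        stmt, "chi_squared", stat, p, p < alpha, {"skipped_strata": skipped, "dof": dof}
    )


# ---------------------------------------------------------------------------
# report-level API


def test_consistency(
    g: MixedGraph,
    data: pd.DataFrame,
    alpha: float = 0.01,
    max_cond: int = 3,
    policy: str = "ancestors",
    fdr: bool = False,
    dtype_overrides: dict[str, str] | None = None,
) -> ConsistencyReport:
    """Test every graph-implied independence against the data.

    ``failed`` means ``p < alpha`` with no multiplicity correction by
    default (the raw failure percentage is the headline diagnostic); set
    ``fdr=True`` for Benjamini–Hochberg-adjusted decisions instead.
    Statements mixing continuous and discrete columns, or touching a
    constant column, are skipped and listed in the report.
    """
    obs = sorted(g.observable)
    missing = [v for v in obs if v not in data.columns]
    if missing:
        raise DataError(f"graph nodes missing from data columns: {missing}")
    kinds = column_kinds(data[obs], dtype_overrides)
    constant = {c for c in obs if data[c].nunique(dropna=False) <= 1}
    if constant:
        warnings.warn(f"constant column(s) excluded from testing: {sorted(constant)}")
    statements = implied_independencies(g, max_cond=max_cond, policy=policy)
    results: list[CITestResult] = []
    skipped: list[str] = []
    for stmt in statements:
        involved = [stmt.left, stmt.right, *sorted(stmt.given)]
        if constant & set(involved):
            skipped.append(f"{stmt}: constant column")
            continue
        tkinds = {kinds[c] for c in involved}
        if tkinds == {"continuous"}:
            results.append(fisher_z_test(data, stmt, alpha))
        elif tkinds == {"discrete"}:
            results.append(chi_squared_test(data, stmt, alpha))
        else:
            skipped.append(f"{stmt}: mixed continuous/discrete columns")
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests([r.p_value for r in results], alpha=alpha, method="fdr_bh")
        results = [
            CITestResult(r.statement, r.test_name, r.statistic, r.p_value, bool(rej), r.detail)
            for r, rej in zip(results, reject)
        ]
    return ConsistencyReport(tuple(results), alpha, max_cond, tuple(skipped))


def repair_graph(g: MixedGraph, report: ConsistencyReport) -> MixedGraph:
    """Add one bidirected edge per pair with at least one failed test.

    Multiple failures of the same pair under different conditioning sets
    collapse to a single edge; pairs already adjacent are left alone.
    The input graph is not modified.
    """
    new_pairs = [
        (u, v) for u, v in report.failed_pairs() if not g.adjacent(u, v)
    ]
    return g.with_bidirected(new_pairs) if new_pairs else g
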