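"""End-to-end perturbation-effect analysis in five steps.

Given a biomolecular network, a table of steady-state replicates, and a
causal query, :func:`run_workflow`:

1. tests every graph-implied conditional independence against the data
   and (optionally) repairs the graph with bidirected edges where tests
   fail;
2. checks identifiability of the query with the ID algorithm — on both
   the original and the repaired graph when repair ran, since repair
   can itself destroy identifiability;
3. finds the nuisance variables for the query;
4. marks them latent and emits the simplified network;
5. selects and runs an estimator, returning point, interval, or
   distribution estimates.

The outcome is a :class:`WorkflowReport`, a validated, JSON-serialisable
record of every step.
"""

from __future__ import annotations

import importlib.resources
import json
import time
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .consistency import repair_graph, test_consistency
from .estimate import (
    CausalQuery,
    EstimationError,
    estimate_ate_nonparametric,
    estimate_linear,
    estimate_plugin_discrete,
    select_estimator,
)
from .graphs import GraphError, MixedGraph
from .identify import identify
from .io import read_data, read_graph, write_graph, write_json
from .reduction import simplify_for_query

__all__ = ["WorkflowConfig", "WorkflowReport", "run_workflow", "NotIdentifiableError", "report_json_schema"]


class NotIdentifiableError(RuntimeError):
    """The query cannot be estimated from observational data alone."""


class WorkflowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.01, gt=0.0, lt=1.0)
    max_cond: int = Field(default=3, ge=0)
    repair: bool = True
    estimator: Literal["auto", "linear", "outcome_regression", "ipw", "aipw", "plugin"] = "auto"
    assume_linear: bool = True
    bootstrap: int = Field(default=1000, ge=0)
    level: float = Field(default=0.95, gt=0.0, lt=1.0)
    seed: int = 0
    ci_policy: Literal["ancestors", "all-observables"] = "ancestors"
    fdr: bool = False


class ConsistencySummary(BaseModel):
    n_tests: int
    n_failed: int
    failure_fraction: float
    alpha: float
    max_cond: int
    n_skipped: int
    repaired: bool
    bidirected_added: int


class IdentifiabilitySection(BaseModel):
    original: str
    repaired: Optional[str] = None
    estimand: Optional[str] = None
    estimand_tree: Optional[dict] = None
    witness: Optional[str] = None


class ReductionSection(BaseModel):
    nuisance: list[str]
    nodes_before: int
    nodes_after: int
    directed_before: int
    directed_after: int
    bidirected_before: int
    bidirected_after: int


class EstimateSection(BaseModel):
    estimator: str
    point: float
    interval: Optional[list[float]] = None
    level: Optional[float] = None
    adjustment_set: Optional[list[str]] = None
    distribution: Optional[dict] = None
    n: int


class StepStatus(BaseModel):
    name: str
    status: Literal["done", "skipped"]
    reason: Optional[str] = None
    seconds: float = 0.0


class WorkflowReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    exposure: str
    outcome: str
    query_form: str
    intervention: list[float]
    config: WorkflowConfig
    steps: list[StepStatus]
    consistency: Optional[ConsistencySummary] = None
    identifiability: Optional[IdentifiabilitySection] = None
    reduction: Optional[ReductionSection] = None
    estimate: Optional[EstimateSection] = None
    warnings: list[str] = Field(default_factory=list)


def report_json_schema() -> dict:
    return WorkflowReport.model_json_schema()


def shipped_schema() -> dict:
    ref = importlib.resources.files("netperturb") / "schema" / "report.schema.json"
    return json.loads(ref.read_text())


def _run_estimator(name: str, graph, data, query: CausalQuery, cfg: WorkflowConfig):
    common = dict(bootstrap=cfg.bootstrap, level=cfg.level, seed=cfg.seed)
    if name == "linear":
        return estimate_linear(data, graph, query, **common)
    if name in ("outcome_regression", "ipw", "aipw"):
        return estimate_ate_nonparametric(data, graph, query, method=name, **common)
    if name == "plugin":
        res = identify(graph, query.exposure, query.outcome)
        if res.status != "identifiable":
            raise EstimationError("plug-in estimator requires an identifiable query")
        return estimate_plugin_discrete(data, res.estimand, query, **common)
    raise EstimationError(f"unknown estimator {name!r}")


def run_workflow(
    graph: MixedGraph | str | Path,
    data,
    query: CausalQuery,
    config: WorkflowConfig | None = None,
    out_dir: str | Path | None = None,
    logger=None,
) -> WorkflowReport:
    """Run the five-step analysis and (optionally) write its artifacts.

    ``graph`` and ``data`` may be in-memory objects or file paths
    (graph TSV, data CSV).  When ``out_dir`` is given, the JSON report
    and the simplified network TSV (plus the repaired-and-simplified
    network when repair ran) are written there.
    """
    cfg = config or WorkflowConfig()
    if not isinstance(graph, MixedGraph):
        graph = read_graph(graph)
    if isinstance(data, (str, Path)):
        data = read_data(data)
    for v in (query.exposure, query.outcome):
        if v not in graph.observable:
            raise GraphError(f"query variable {v!r} is not an observable graph node")
        if v not in data.columns:
            raise GraphError(f"query variable {v!r} has no data column")

    def log(msg: str) -> None:
        if logger is not None:
            logger.info(msg)

    steps: list[StepStatus] = []
    warnings_list: list[str] = []
    report_kwargs: dict = {}

    # Step 1: consistency + optional repair -------------------------------
    t0 = time.perf_counter()
    con = test_consistency(
        graph, data, alpha=cfg.alpha, max_cond=cfg.max_cond, policy=cfg.ci_policy, fdr=cfg.fdr
    )
    repaired_graph = None
    added = 0
    if cfg.repair and con.n_failed:
        repaired_graph = repair_graph(graph, con)
        added = len(repaired_graph.bidirected) - len(graph.bidirected)
    report_kwargs["consistency"] = ConsistencySummary(
        n_tests=con.n_tests,
        n_failed=con.n_failed,
        failure_fraction=con.failure_fraction,
        alpha=cfg.alpha,
        max_cond=cfg.max_cond,
        n_skipped=len(con.skipped),
        repaired=repaired_graph is not None,
        bidirected_added=added,
    )
    steps.append(StepStatus(name="consistency", status="done", seconds=time.perf_counter() - t0))
    log(
        f"step 1: {con.n_tests} CI tests, {con.n_failed} failed "
        f"({100 * con.failure_fraction:.1f}%), {added} bidirected edges added"
    )
    working = repaired_graph if repaired_graph is not None else graph

    # Step 2: identifiability ---------------------------------------------
    t0 = time.perf_counter()
    id_orig = identify(graph, query.exposure, query.outcome)
    id_rep = identify(working, query.exposure, query.outcome) if repaired_graph is not None else None
    active = id_rep if id_rep is not None else id_orig
    report_kwargs["identifiability"] = IdentifiabilitySection(
        original=id_orig.status,
        repaired=id_rep.status if id_rep is not None else None,
        estimand=active.estimand.pretty() if active.estimand is not None else None,
        estimand_tree=active.estimand.to_json() if active.estimand is not None else None,
        witness=active.witness,
    )
    steps.append(StepStatus(name="identifiability", status="done", seconds=time.perf_counter() - t0))
    log(f"step 2: original {id_orig.status}" + (f", repaired {id_rep.status}" if id_rep else ""))
    if active.status != "identifiable":
        msg = (
            f"query P[{query.outcome}|do({query.exposure})] is not identifiable "
            "from observational data; additional experiments may be required"
        )
        warnings_list.append(msg)
        for name in ("reduction", "simplification", "estimation"):
            steps.append(StepStatus(name=name, status="skipped", reason="query not identifiable"))
        report = WorkflowReport(
            exposure=query.exposure,
            outcome=query.outcome,
            query_form=query.form,
            intervention=[query.x1] if query.form != "ate" else [query.x1, query.x0],
            config=cfg,
            steps=steps,
            warnings=warnings_list,
            **report_kwargs,
        )
        _write_outputs(report, None, None, out_dir)
        return report

    # Steps 3 and 4: nuisance detection + simplification -------------------
    t0 = time.perf_counter()
    red = simplify_for_query(working, query.exposure, query.outcome)
    report_kwargs["reduction"] = ReductionSection(
        nuisance=sorted(red.nuisance),
        nodes_before=red.nodes_before,
        nodes_after=red.nodes_after,
        directed_before=red.directed_before,
        directed_after=red.directed_after,
        bidirected_before=red.bidirected_before,
        bidirected_after=red.bidirected_after,
    )
    dt = time.perf_counter() - t0
    steps.append(StepStatus(name="reduction", status="done", seconds=dt / 2))
    steps.append(StepStatus(name="simplification", status="done", seconds=dt / 2))
    log(
        f"steps 3-4: {len(red.nuisance)} nuisance variables; "
        f"{red.nodes_before} -> {red.nodes_after} nodes"
    )

    # Step 5: estimation ---------------------------------------------------
    t0 = time.perf_counter()
    est_graph = red.simplified
    name = cfg.estimator
    if name == "auto":
        name = select_estimator(est_graph, query, data, assume_linear=cfg.assume_linear)
    result = _run_estimator(name, est_graph, data, query, cfg)
    dist = result.detail.get("distribution")
    report_kwargs["estimate"] = EstimateSection(
        estimator=result.estimator,
        point=result.point,
        interval=list(result.interval) if result.interval else None,
        level=result.level,
        adjustment_set=sorted(result.adjustment_set)
        if result.adjustment_set is not None
        else None,
        distribution=dist,
        n=result.detail.get("n", len(data)),
    )
    steps.append(StepStatus(name="estimation", status="done", seconds=time.perf_counter() - t0))
    log(f"step 5: {result.estimator} estimate {result.point:.4g}")

    report = WorkflowReport(
        exposure=query.exposure,
        outcome=query.outcome,
        query_form=query.form,
        intervention=[query.x1] if query.form != "ate" else [query.x1, query.x0],
        config=cfg,
        steps=steps,
        warnings=warnings_list,
        **report_kwargs,
    )
    repaired_simplified = None
    if repaired_graph is not None:
        repaired_simplified = red.simplified
        # also simplify the unrepaired graph for the two-analysis output
        red_orig = simplify_for_query(graph, query.exposure, query.outcome)
        _write_outputs(report, red_orig.simplified, repaired_simplified, out_dir)
    else:
        _write_outputs(report, red.simplified, None, out_dir)
    return report


def _write_outputs(report, simplified, repaired_simplified, out_dir) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(report.model_dump(), out / "report.json")
    if simplified is not None:
        write_graph(simplified, out / "simplified_graph.tsv")
    if repaired_simplified is not None:
        write_graph(repaired_simplified, out / "repaired_simplified_graph.tsv")
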