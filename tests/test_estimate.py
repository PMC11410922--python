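"""Adjustment sets and causal-effect estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netperturb import (
    CausalQuery,
    EstimationError,
    MixedGraph,
    estimate_ate_nonparametric,
    estimate_linear,
    estimate_plugin_discrete,
    exhaustive_interventional,
    identify,
    optimal_adjustment_set,
    random_scm,
    sample,
    select_estimator,
    true_effect,
)
from netperturb.estimate import is_valid_adjustment_set
from netperturb.synthetic import DiscreteSCM


class TestOptimalAdjustmentSet:
    def test_backdoor_triangle(self, backdoor):
        assert optimal_adjustment_set(backdoor, "X", "Y") == {"Z"}

    def test_lone_edge_is_empty(self):
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        assert optimal_adjustment_set(g, "X", "Y") == frozenset()

    def test_frontdoor_has_none(self, frontdoor):
        assert optimal_adjustment_set(frontdoor, "X", "Y") is None

    def test_exhaustive_subset_search_agrees(self, rng):
        """When the formula returns a set it is valid; when it returns
        none, no subset of observables is valid (brute force, small graphs)."""
        from _oracles import random_admg

        for _ in range(40):
            g = random_admg(rng, 6, p_bi=0.2)
            nodes = sorted(g.observable)
            x, y = rng.choice(nodes, size=2, replace=False)
            got = optimal_adjustment_set(g, x, y)
            others = [w for w in nodes if w not in (x, y)]
            any_valid = any(
                is_valid_adjustment_set(g, x, y, set(c))
                for k in range(len(others) + 1)
                for c in itertools.combinations(others, k)
            )
            if got is None:
                assert not any_valid
            else:
                assert is_valid_adjustment_set(g, x, y, got)

    def test_parents_of_mediators_included(self):
        g = MixedGraph.from_edges(
            directed=[("X", "M"), ("M", "Y"), ("W", "M"), ("Z", "X"), ("Z", "Y")]
        )
        o = optimal_adjustment_set(g, "X", "Y")
        assert o == {"W", "Z"}


class TestEstimateLinear:
    def test_unconfounded_recovers_slope(self):
        scm = random_scm(2, 1.0, 0, seed=1)
        g = scm.graph
        (edge,) = g.directed
        data = sample(scm, 5000, seed=2)
        q = CausalQuery(exposure=edge[0], outcome=edge[1], form="ate")
        res = estimate_linear(data, g, q, bootstrap=200, seed=3)
        se = np.std(res.bootstrap_draws)
        assert abs(res.point - scm.weights[edge]) < 3 * se

    def test_confounded_adjusted_vs_unadjusted(self, rng):
        """Adjustment recovers the direct effect; naive regression is biased."""
        n = 20_000
        z = rng.normal(size=n)
        x = 1.5 * z + rng.normal(size=n)
        y = 2.0 * x + 3.0 * z + rng.normal(size=n)
        data = pd.DataFrame({"X": x, "Y": y, "Z": z})
        g = MixedGraph.from_edges(directed=[("Z", "X"), ("X", "Y"), ("Z", "Y")])
        res = estimate_linear(data, g, CausalQuery("X", "Y"), bootstrap=0)
        assert res.point == pytest.approx(2.0, abs=0.05)
        naive = np.polyfit(x, y, 1)[0]
        assert abs(naive - 2.0) > 0.5

    def test_expected_value_form(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        data = pd.DataFrame({"X": x, "Y": y})
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        q = CausalQuery("X", "Y", form="expected_value", x1=2.0)
        res = estimate_linear(data, g, q, bootstrap=0)
        assert res.point == pytest.approx(5.0, abs=0.1)

    def test_distribution_form_reports_gaussian(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n, scale=1.5)
        data = pd.DataFrame({"X": x, "Y": y})
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        q = CausalQuery("X", "Y", form="distribution", x1=1.0)
        res = estimate_linear(data, g, q, bootstrap=0)
        dist = res.detail["distribution"]
        assert dist["family"] == "normal"
        assert dist["sd"] == pytest.approx(1.5, abs=0.1)

    def test_null_effect_interval_coverage(self, rng):
        """beta_X = 0: 95% bootstrap interval covers 0 in >=90/100 runs."""
        covered = 0
        runs = 100
        for i in range(runs):
            n = 400
            x = rng.normal(size=n)
            y = rng.normal(size=n)  # no effect
            data = pd.DataFrame({"X": x, "Y": y})
            g = MixedGraph.from_edges(directed=[("X", "Y")])
            res = estimate_linear(data, g, CausalQuery("X", "Y"), bootstrap=300, seed=i)
            low, high = res.interval
            covered += low <= 0.0 <= high
        assert covered >= 90

    def test_no_adjustment_set_raises_toward_plugin(self, frontdoor, rng):
        data = pd.DataFrame(rng.normal(size=(100, 3)), columns=["X", "M", "Y"])
        with pytest.raises(EstimationError, match="plug-in"):
            estimate_linear(data, frontdoor, CausalQuery("X", "Y"))

    def test_bootstrap_reproducible(self, rng):
        data = pd.DataFrame(rng.normal(size=(300, 2)), columns=["X", "Y"])
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        a = estimate_linear(data, g, CausalQuery("X", "Y"), bootstrap=100, seed=5)
        b = estimate_linear(data, g, CausalQuery("X", "Y"), bootstrap=100, seed=5)
        assert a.bootstrap_draws == b.bootstrap_draws
        assert a.interval == b.interval

    def test_invariant_to_row_order(self, rng):
        n = 500
        z = rng.normal(size=n)
        data = pd.DataFrame(
            {"Z": z, "X": z + rng.normal(size=n), "Y": z + rng.normal(size=n)}
        )
        g = MixedGraph.from_edges(directed=[("Z", "X"), ("X", "Y"), ("Z", "Y")])
        a = estimate_linear(data, g, CausalQuery("X", "Y"), bootstrap=0)
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = estimate_linear(shuffled, g, CausalQuery("X", "Y"), bootstrap=0)
        assert a.point == pytest.approx(b.point, rel=1e-9)


def _binary_confounded(rng, n, ate=1.5, confounded=True):
    z = rng.normal(size=n)
    logits = 0.8 * z if confounded else np.zeros(n)
    t = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(float)
    y = ate * t + (1.2 * z if confounded else 0.0) + rng.normal(size=n)
    return pd.DataFrame({"X": t, "Y": y, "Z": z})


_BINARY_GRAPH = MixedGraph.from_edges(directed=[("Z", "X"), ("X", "Y"), ("Z", "Y")])


class TestNonparametricATE:
    @pytest.mark.parametrize("method", ["outcome_regression", "ipw", "aipw"])
    def test_randomized_exposure_recovers_ate(self, method, rng):
        data = _binary_confounded(rng, 4000, ate=1.5, confounded=False)
        res = estimate_ate_nonparametric(
            data, _BINARY_GRAPH, CausalQuery("X", "Y"), method=method, bootstrap=150, seed=0
        )
        se = np.std(res.bootstrap_draws)
        assert abs(res.point - 1.5) < 3 * se

    @pytest.mark.parametrize("method", ["outcome_regression", "ipw", "aipw"])
    def test_confounded_exposure_recovers_ate(self, method, rng):
        data = _binary_confounded(rng, 6000, ate=1.5, confounded=True)
        res = estimate_ate_nonparametric(
            data, _BINARY_GRAPH, CausalQuery("X", "Y"), method=method, bootstrap=150, seed=0
        )
        se = np.std(res.bootstrap_draws)
        assert abs(res.point - 1.5) < 3 * se + 0.05

    def test_ipw_unbiased_across_replicates(self, rng):
        errs = []
        for i in range(60):
            data = _binary_confounded(rng, 1500, ate=1.0, confounded=True)
            res = estimate_ate_nonparametric(
                data, _BINARY_GRAPH, CausalQuery("X", "Y"), method="ipw", bootstrap=0
            )
            errs.append(res.point - 1.0)
        errs = np.asarray(errs)
        # mean error not significantly different from 0
        tstat = errs.mean() / (errs.std(ddof=1) / np.sqrt(len(errs)))
        assert abs(tstat) < 3.5

    def test_aipw_double_robustness_wrong_outcome_model(self, rng):
        """Outcome model misspecified (nonlinear truth): AIPW still unbiased."""
        n = 6000
        z = rng.normal(size=n)
        t = (rng.random(n) < 1.0 / (1.0 + np.exp(-0.8 * z))).astype(float)
        y = 1.5 * t + np.sin(2.0 * z) + z**2 + rng.normal(size=n)
        data = pd.DataFrame({"X": t, "Y": y, "Z": z})
        res = estimate_ate_nonparametric(
            data, _BINARY_GRAPH, CausalQuery("X", "Y"), method="aipw", bootstrap=150, seed=1
        )
        se = np.std(res.bootstrap_draws)
        assert abs(res.point - 1.5) < 3 * se + 0.05

    def test_nonbinary_exposure_rejected(self, rng):
        data = pd.DataFrame(
            {"X": rng.normal(size=100), "Y": rng.normal(size=100), "Z": rng.normal(size=100)}
        )
        with pytest.raises(EstimationError, match="binary"):
            estimate_ate_nonparametric(data, _BINARY_GRAPH, CausalQuery("X", "Y"))


def _frontdoor_discrete(seed):
    rng = np.random.default_rng(seed)
    g = MixedGraph.from_edges(
        directed=[("X", "M"), ("M", "Y"), ("U", "X"), ("U", "Y")], latent=["U"]
    )

    def rows(shape):
        t = rng.dirichlet([2, 2], size=shape)
        t = np.clip(t, 0.1, None)
        return t / t.sum(axis=-1, keepdims=True)

    return DiscreteSCM(
        g,
        {v: 2 for v in g.nodes},
        {v: tuple(sorted(g.parents(v))) for v in g.nodes},
        {"U": rows(()), "X": rows((2,)), "M": rows((2,)), "Y": rows((2, 2))},
    )


def _sample_discrete(scm, n, seed):
    rng = np.random.default_rng(seed)
    cols = {}
    for v in scm.graph.topological_order():
        pa = scm.parent_order[v]
        if pa:
            idx = tuple(cols[p] for p in pa)
            probs = scm.cpts[v][idx]
        else:
            probs = np.tile(scm.cpts[v], (n, 1))
        u = rng.random(n)
        cols[v] = (u > probs[..., 0]).astype(int) if probs.ndim == 2 else (u > probs[0]).astype(int)
    return pd.DataFrame({v: cols[v] for v in sorted(scm.graph.observable)})


class TestPluginDiscrete:
    def test_frontdoor_close_to_truth(self):
        scm = _frontdoor_discrete(17)
        data = _sample_discrete(scm, 20_000, seed=18)
        res_id = identify(scm.graph, "X", "Y")
        assert res_id.status == "identifiable"
        q = CausalQuery("X", "Y", form="distribution", x1=1)
        res = estimate_plugin_discrete(data, res_id.estimand, q, bootstrap=0)
        truth = exhaustive_interventional(scm, {"X": 1}, "Y")
        got = np.array(res.detail["distribution"]["probabilities"])
        assert 0.5 * np.abs(got - truth).sum() < 0.02  # total variation

    def test_independent_pair_reduces_to_marginal(self, rng):
        n = 5000
        data = pd.DataFrame(
            {"X": rng.integers(0, 2, n), "Y": rng.integers(0, 2, n)}
        )
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        res_id = identify(g, "X", "Y")
        q = CausalQuery("X", "Y", form="expected_value", x1=1)
        res = estimate_plugin_discrete(data, res_id.estimand, q, bootstrap=0)
        assert res.point == pytest.approx(data["Y"].mean(), abs=0.03)

    def test_bootstrap_interval_reproducible(self, rng):
        n = 2000
        data = pd.DataFrame(
            {"X": rng.integers(0, 2, n), "Y": rng.integers(0, 2, n)}
        )
        g = MixedGraph.from_edges(directed=[("X", "Y")])
        res_id = identify(g, "X", "Y")
        q = CausalQuery("X", "Y", form="ate", x1=1, x0=0)
        a = estimate_plugin_discrete(data, res_id.estimand, q, bootstrap=120, seed=9)
        b = estimate_plugin_discrete(data, res_id.estimand, q, bootstrap=120, seed=9)
        assert a.bootstrap_draws == b.bootstrap_draws
        assert a.interval == b.interval


class TestSelectEstimator:
    def test_continuous_backdoor_gives_linear(self, backdoor, rng):
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["X", "Y", "Z"])
        assert select_estimator(backdoor, CausalQuery("X", "Y"), data) == "linear"

    def test_binary_exposure_without_linearity_gives_aipw(self, backdoor, rng):
        data = pd.DataFrame(
            {
                "X": rng.integers(0, 2, 50).astype(float),
                "Y": rng.normal(size=50),
                "Z": rng.normal(size=50),
            }
        )
        got = select_estimator(backdoor, CausalQuery("X", "Y"), data, assume_linear=False)
        assert got == "aipw"

    def test_discrete_frontdoor_gives_plugin(self, frontdoor, rng):
        data = pd.DataFrame(
            {
                "X": rng.integers(0, 2, 50),
                "M": rng.integers(0, 2, 50),
                "Y": rng.integers(0, 2, 50),
            }
        )
        assert select_estimator(frontdoor, CausalQuery("X", "Y"), data) == "plugin"

    def test_continuous_frontdoor_unsupported(self, frontdoor, rng):
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["X", "M", "Y"])
        with pytest.raises(EstimationError, match="discrete"):
            select_estimator(frontdoor, CausalQuery("X", "Y"), data)

    def test_not_identifiable_raises(self, bow, rng):
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["X", "Y"])
        with pytest.raises(EstimationError, match="not identifiable"):
            select_estimator(bow, CausalQuery("X", "Y"), data)


class TestParameterRecovery:
    def test_median_ate_error_small_across_random_scms(self):
        """100 random confounded linear SCMs at n = 5000: median |error| < 0.05."""
        errors = []
        found = 0
        seed = 0
        while found < 100 and seed < 400:
            seed += 1
            scm = random_scm(
                n_nodes=6, edge_prob=0.4, n_latent_confounders=(seed % 3) + 1, seed=seed
            )
            g = scm.graph
            order = [v for v in g.topological_order() if v in g.observable]
            pair = next(
                (
                    (a, b)
                    for a in order
                    for b in reversed(order)
                    if a != b and true_effect(scm, a, b) != 0.0
                ),
                None,
            )
            if pair is None:
                continue
            x, y = pair
            adj = optimal_adjustment_set(g, x, y)
            if adj is None:
                continue
            data = sample(scm, 5000, seed=seed + 10_000)
            res = estimate_linear(data, g, CausalQuery(x, y), bootstrap=0)
            errors.append(abs(res.point - true_effect(scm, x, y)))
            found += 1
        assert found == 100
        assert np.median(errors) < 0.05
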