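import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stressnet.bn import Dag, fit_parameters
from stressnet.bn.fit import CPT, DiscreteBayesNet
from stressnet.inference import (
    EvidenceQuery,
    ImpossibleEvidenceError,
    PosteriorSummary,
    bayes_linreg,
    blanket_query_table,
    cpquery_lw,
    exact_query,
    markov_blanket,
    sample_conditional,
    sample_net,
)
from conftest import random_soft_net


def _single_node_net(p_hi=0.3):
    dag = Dag(["A"])
    cpt = CPT(parents=(), parent_cards=(), states=("lo", "hi"), table=np.array([[1 - p_hi, p_hi]]))
    return DiscreteBayesNet(dag=dag, states={"A": ("lo", "hi")}, cpts={"A": cpt})


# ---------------------------------------------------------------------------
# Markov blankets
# ---------------------------------------------------------------------------

class TestMarkovBlanket:
    def test_chain(self):
        dag = Dag("ABC", [("A", "B"), ("B", "C")])
        assert markov_blanket(dag, "B") == {"A", "C"}

    def test_collider_includes_spouse(self):
        dag = Dag("ABC", [("A", "C"), ("B", "C")])
        assert markov_blanket(dag, "A") == {"C", "B"}

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            markov_blanket(Dag("A"), "Z")

    def test_symmetry(self):
        for seed in range(10):
            net = random_soft_net(seed, n_nodes=5)
            for x, y in itertools.permutations(net.dag.nodes, 2):
                assert (y in markov_blanket(net.dag, x)) == (x in markov_blanket(net.dag, y))

    def test_blanket_renders_node_conditionally_independent(self):
        # P(X | blanket) equals P(X | everything else) by exact enumeration.
        net = random_soft_net(4, n_nodes=5)
        target = net.dag.nodes[0]
        mb = markov_blanket(net.dag, target)
        others = [n for n in net.dag.nodes if n != target]
        states = {n: net.states[n] for n in net.dag.nodes}
        worst = 0.0
        for combo in itertools.product(*[states[n] for n in others]):
            full_ev = dict(zip(others, combo))
            mb_ev = {k: v for k, v in full_ev.items() if k in mb}
            try:
                p_full = exact_query(net, EvidenceQuery(event={target: "s1"}, evidence=full_ev))
            except ImpossibleEvidenceError:
                continue
            p_mb = exact_query(net, EvidenceQuery(event={target: "s1"}, evidence=mb_ev))
            worst = max(worst, abs(p_full - p_mb))
        assert worst < 1e-9


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

class TestExactQuery:
    def test_single_node_marginal(self):
        net = _single_node_net(0.3)
        assert exact_query(net, EvidenceQuery(event={"A": "hi"})) == pytest.approx(0.3)

    def test_bayes_rule_by_hand(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": CPT((), (), ("l", "h"), np.array([[0.5, 0.5]])),
            "B": CPT(("A",), (2,), ("l", "h"), np.array([[0.9, 0.1], [0.1, 0.9]])),
        }
        net = DiscreteBayesNet(dag=dag, states={"A": ("l", "h"), "B": ("l", "h")}, cpts=cpts)
        p = exact_query(net, EvidenceQuery(event={"A": "h"}, evidence={"B": "h"}))
        assert p == pytest.approx(0.9)

    def test_zero_probability_evidence_raises(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": CPT((), (), ("l", "h"), np.array([[1.0, 0.0]])),
            "B": CPT(("A",), (2,), ("l", "h"), np.array([[0.5, 0.5], [0.5, 0.5]])),
        }
        net = DiscreteBayesNet(dag=dag, states={"A": ("l", "h"), "B": ("l", "h")}, cpts=cpts)
        with pytest.raises(ImpossibleEvidenceError):
            exact_query(net, EvidenceQuery(event={"B": "h"}, evidence={"A": "h"}))

    def test_event_and_evidence_disjoint(self):
        with pytest.raises(ValueError):
            EvidenceQuery(event={"A": "h"}, evidence={"A": "l"})


# ---------------------------------------------------------------------------
# Likelihood weighting
# ---------------------------------------------------------------------------

class TestCpqueryLw:
    def test_marginal_recovery(self):
        net = _single_node_net(0.3)
        res = cpquery_lw(net, EvidenceQuery(event={"A": "hi"}, n_samples=50_000, seed=0))
        assert abs(res.probability - 0.3) < 3 * res.std_error

    def test_agrees_with_exact_on_random_nets(self):
        ok = 0
        total = 0
        rng = np.random.default_rng(0)
        for seed in range(10):
            net = random_soft_net(seed, n_nodes=5)
            nodes = list(net.dag.nodes)
            for _ in range(3):
                k = rng.integers(1, 3)
                ev_nodes = list(rng.choice(nodes[1:], size=k, replace=False))
                ev = {n: net.states[n][rng.integers(0, 2)] for n in ev_nodes}
                q = EvidenceQuery(event={nodes[0]: "s1"}, evidence=ev, n_samples=20_000, seed=int(seed * 7 + total))
                try:
                    p_star = exact_query(net, q)
                    res = cpquery_lw(net, q)
                except ImpossibleEvidenceError:
                    continue
                total += 1
                ok += abs(res.probability - p_star) <= 3 * max(res.std_error, 1e-4)
        assert total >= 20
        assert ok / total >= 0.95

    def test_se_shrinks_as_root_n(self):
        net = random_soft_net(2, n_nodes=4)
        q_base = dict(event={net.dag.nodes[0]: "s1"}, evidence={net.dag.nodes[-1]: "s0"})
        ses = []
        for n in (10**3, 10**4, 10**5):
            res = cpquery_lw(net, EvidenceQuery(**q_base, n_samples=n, seed=1))
            ses.append(res.std_error)
        slope = np.polyfit(np.log10([1e3, 1e4, 1e5]), np.log10(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_impossible_evidence_signalled(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": CPT((), (), ("l", "h"), np.array([[1.0, 0.0]])),
            "B": CPT(("A",), (2,), ("l", "h"), np.array([[0.5, 0.5], [0.5, 0.5]])),
        }
        net = DiscreteBayesNet(dag=dag, states={"A": ("l", "h"), "B": ("l", "h")}, cpts=cpts)
        with pytest.raises(ImpossibleEvidenceError):
            cpquery_lw(net, EvidenceQuery(event={"B": "h"}, evidence={"A": "h"}, n_samples=1000, seed=0))

    def test_deterministic_given_seed(self):
        net = random_soft_net(3, n_nodes=4)
        q = EvidenceQuery(event={net.dag.nodes[0]: "s1"}, evidence={net.dag.nodes[1]: "s0"},
                          n_samples=5000, seed=42)
        assert cpquery_lw(net, q) == cpquery_lw(net, q)

    def test_continuous_evidence_matches_gaussian_conditioning(self):
        # x ~ N(0,1); y = 2 + 0.8 x + e, e ~ N(0, 0.5); g depends on nothing.
        # Exact: P(g) unchanged; also check a discrete child case below.
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 40_000)
        y = 2.0 + 0.8 * x + rng.normal(0, 0.5, 40_000)
        g = np.where(x + rng.normal(0, 0.8, 40_000) > 0, "hi", "lo")
        df = pd.DataFrame({"g": g, "x": x, "y": y})
        dag = Dag(["g", "x", "y"], [("x", "y"), ("g", "x")])
        net = fit_parameters(dag, df)
        # exact conditional: P(g=hi | y = y0) via Bayes on the two fitted
        # Gaussian mixtures P(y | g) (x integrated out analytically).
        lg_x = net.gaussians["x"]
        lg_y = net.gaussians["y"]
        p_hi = net.cpts["g"].table[0, list(net.states["g"]).index("hi")]
        y0 = 2.5
        comps = {}
        for gi, gstate in enumerate(net.states["g"]):
            mu_x = lg_x.coef[gi, 0]
            var_x = lg_x.sd[gi] ** 2
            mu_y = lg_y.coef[0, 0] + lg_y.coef[0, 1] * mu_x
            var_y = lg_y.sd[0] ** 2 + lg_y.coef[0, 1] ** 2 * var_x
            comps[gstate] = math.exp(-0.5 * (y0 - mu_y) ** 2 / var_y) / math.sqrt(var_y)
        prior = {s: net.cpts["g"].table[0, i] for i, s in enumerate(net.states["g"])}
        exact = prior["hi"] * comps["hi"] / sum(prior[s] * comps[s] for s in prior)
        res = cpquery_lw(net, EvidenceQuery(event={"g": "hi"}, evidence={"y": y0},
                                            n_samples=100_000, seed=3))
        assert abs(res.probability - exact) <= 3 * res.std_error


# ---------------------------------------------------------------------------
# Blanket tables
# ---------------------------------------------------------------------------

class TestBlanketQueryTable:
    def test_five_binary_variables_give_32_rows(self):
        net = random_soft_net(9, n_nodes=6)
        nodes = list(net.dag.nodes)
        table = blanket_query_table(net, (nodes[0], "s1"), tuple(nodes[1:]), n_samples=2000, seed=0)
        assert len(table) == 32
        assert (table["probability"].between(0, 1)).all()

    def test_probabilities_sorted_descending(self):
        net = random_soft_net(10, n_nodes=4)
        nodes = list(net.dag.nodes)
        table = blanket_query_table(net, (nodes[0], "s1"), tuple(nodes[1:]), n_samples=2000, seed=1)
        assert (table["probability"].diff().dropna() <= 1e-12).all()

    def test_continuous_grid_nine_rows(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5000)
        z = rng.normal(0, 1, 5000)
        g = np.where(x + z + rng.normal(0, 1, 5000) > 0, "yes", "no")
        df = pd.DataFrame({"g": g, "x": x, "z": z})
        net = fit_parameters(Dag(["g", "x", "z"], [("g", "x"), ("g", "z")]), df)
        table = blanket_query_table(net, ("g", "yes"), ("x", "z"), n_samples=5000, seed=2)
        assert len(table) == 9
        assert set(table["x"]) == {"-1 SD", "Mean", "+1 SD"}

    def test_zero_blanket_vars_gives_marginal(self):
        net = _single_node_net(0.3)
        table = blanket_query_table(net, ("A", "hi"), (), n_samples=50_000, seed=3)
        assert len(table) == 1
        assert table.loc[0, "probability"] == pytest.approx(0.3, abs=0.01)


# ---------------------------------------------------------------------------
# Conditional sampling
# ---------------------------------------------------------------------------

class TestSampleConditional:
    def test_root_gaussian_moments(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(3.0, 2.0, 5000)})
        net = fit_parameters(Dag(["x"]), df)
        draws = sample_conditional(net, ["x"], 10_000, seed=0)
        assert draws["x"].mean() == pytest.approx(3.0, abs=3 * 2.0 / math.sqrt(10_000) + 0.1)
        assert draws["x"].std() == pytest.approx(2.0, abs=0.1)

    def test_child_regression_slope_recovered(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 5000)
        y = 0.5 * x + rng.normal(0, 0.8, 5000)
        net = fit_parameters(Dag(["x", "y"], [("x", "y")]), pd.DataFrame({"x": x, "y": y}))
        draws = sample_conditional(net, ["x", "y"], 20_000, seed=1)
        slope = np.polyfit(draws["x"], draws["y"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_deterministic(self):
        net = random_soft_net(11, n_nodes=3)
        a = sample_conditional(net, list(net.dag.nodes), 100, seed=9)
        b = sample_conditional(net, list(net.dag.nodes), 100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_node_rejected(self):
        net = _single_node_net()
        with pytest.raises(KeyError):
            sample_conditional(net, ["missing"], 10)

    def test_sample_net_covers_all_nodes(self):
        net = random_soft_net(12, n_nodes=4)
        draws = sample_net(net, 50, seed=2)
        assert set(draws.columns) == set(net.dag.nodes)


# ---------------------------------------------------------------------------
# Bayesian linear regression
# ---------------------------------------------------------------------------

class TestBayesLinreg:
    def test_recovery_with_interaction(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(0, 1, 500)
        x2 = rng.normal(0, 1, 500)
        y = 0.41 * x1 - 0.19 * x2 + 0.0 * x1 * x2 + rng.normal(0, 0.5, 500)
        X = np.column_stack([x1, x2, x1 * x2])
        post = bayes_linreg(y, X, names=["x1", "x2", "x1:x2"], seed=0)
        for term, truth in (("x1", 0.41), ("x2", -0.19), ("x1:x2", 0.0)):
            row = post.coefficient(term)
            assert abs(row["estimate"] - truth) < 3 * row["error"], term
        inter = post.coefficient("x1:x2")
        assert inter["lower"] <= 0 <= inter["upper"]

    def test_null_calibration(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(0, 1, (200, 2))
            y = rng.normal(0, 1, 200)
            post = bayes_linreg(y, X, seed=seed, n_draws=2000, n_burn=200)
            rows = post.frame[post.frame["term"] != "intercept"]
            covered += int(((rows["lower"] <= 0) & (rows["upper"] >= 0)).all())
        assert covered >= 18

    def test_flat_prior_limit_matches_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (300, 2))
        y = X @ np.array([1.5, -0.7]) + rng.normal(0, 0.3, 300)
        post = bayes_linreg(y, X, prior_sd=1e4, seed=1, n_draws=8000)
        design = np.column_stack([np.ones(300), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(post.frame["estimate"].to_numpy(), ols, atol=1e-3 + 3 * 0.3 / math.sqrt(300))

    def test_interval_ordering(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (100, 1))
        y = rng.normal(0, 1, 100)
        post = bayes_linreg(y, X, seed=2, n_draws=1000, n_burn=100)
        assert isinstance(post, PosteriorSummary)
        f = post.frame
        assert ((f["lower"] <= f["estimate"]) & (f["estimate"] <= f["upper"])).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bayes_linreg(np.ones(5), np.ones((5, 1)))

    def test_rank_deficiency_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            bayes_linreg(np.ones(20), np.column_stack([x, 2 * x]))

    def test_bad_prior_sd(self):
        with pytest.raises(ValueError):
            bayes_linreg(np.ones(20), np.arange(20.0), prior_sd=0.0)
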