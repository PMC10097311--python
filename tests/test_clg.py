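"""CLG density, likelihood, MLE fitting, BIC and serialization."""

import itertools
import math

import numpy as np
import pytest

from apneadbn.clg import (CLGModel, ContinuousNodeParams, DBNStructure,
                          DiscreteNodeParams, ModelError, StructureError,
                          bic_score, build_lagged_table, clg_logdensity,
                          fit_mle, joint_loglik, load_model, model_from_dict,
                          model_to_dict, sample_model, save_model)


class TestStructureConstraints:
    KINDS = {"Ap": "discrete", "RR": "continuous"}

    def test_continuous_parent_of_discrete_forbidden(self):
        with pytest.raises(StructureError):
            DBNStructure(self.KINDS, 1, {(("RR", 0), ("Ap", 0))})

    def test_future_to_past_forbidden(self):
        with pytest.raises(StructureError):
            DBNStructure(self.KINDS, 1, {(("RR", 0), ("RR", 1))})

    def test_intra_slice_cycle_forbidden(self):
        kinds = {"a": "continuous", "b": "continuous"}
        with pytest.raises(StructureError):
            DBNStructure(kinds, 1, {(("a", 0), ("b", 0)),
                                    (("b", 0), ("a", 0))})

    def test_lag_beyond_order_forbidden(self):
        with pytest.raises(StructureError):
            DBNStructure(self.KINDS, 2, {(("RR", 3), ("RR", 0))})


class TestLaggedTable:
    def test_shape(self):
        series = {"a": np.arange(100.0), "b": np.arange(100.0) * 2}
        t = build_lagged_table(series, 5)
        assert t.shape == (95, 12)

    def test_lag_zero_identity(self):
        series = {"a": np.arange(10.0)}
        t = build_lagged_table(series, 0)
        np.testing.assert_array_equal(t["a@0"], np.arange(10.0))

    def test_shift_consistency(self):
        rng = np.random.default_rng(0)
        series = {"x": rng.normal(size=50)}
        t = build_lagged_table(series, 3)
        np.testing.assert_array_equal(t["x@1"].to_numpy()[1:],
                                      t["x@0"].to_numpy()[:-1])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_lagged_table({"a": np.arange(10.0),
                                "b": np.arange(9.0)}, 2)


class TestLogDensity:
    def test_standard_normal_at_zero(self):
        assert clg_logdensity(0.0, np.array([]), 1.0, np.array([]), 0.0) == \
            pytest.approx(-0.9189385332046727)

    def test_regression_mean_shift(self):
        # mean = 1 + 2*3 = 7; density at 7 equals standard normal at 0
        val = clg_logdensity(1.0, np.array([2.0]), 1.0, np.array([3.0]), 7.0)
        assert val == pytest.approx(-0.9189385332046727)

    def test_normalization_by_quadrature(self):
        from scipy.integrate import quad
        rng = np.random.default_rng(8)
        for _ in range(5):
            alpha = rng.normal()
            beta = rng.normal(size=2)
            sigma = rng.uniform(0.2, 2.0)
            zc = rng.normal(size=2)
            total, _ = quad(
                lambda z: math.exp(clg_logdensity(alpha, beta, sigma, zc, z)),
                -np.inf, np.inf)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ModelError):
            clg_logdensity(0.0, np.array([]), 0.0, np.array([]), 0.0)


def _single_binary_model(p1: float) -> CLGModel:
    struct = DBNStructure({"Ap": "discrete"}, 1, set())
    params = {"Ap": DiscreteNodeParams([], [0, 1],
                                       {(): np.array([1 - p1, p1])})}
    return CLGModel(structure=struct, params=params,
                    prior={"Ap": np.array([1 - p1, p1])},
                    states={"Ap": [0, 1]})


class TestJointLoglik:
    def test_single_fair_binary_node(self):
        model = _single_binary_model(0.5)
        data = build_lagged_table({"Ap": np.array([0, 1] * 6)}, 1)
        assert len(data) == 11
        assert joint_loglik(model, data) == pytest.approx(11 * math.log(0.5))

    def test_factorizes_over_independent_nodes(self, hmm_like_model):
        model, series = hmm_like_model
        struct = model.structure
        empty = struct.with_arcs(set())
        data = build_lagged_table(series, struct.order)
        m0 = fit_mle(empty, data, pseudocount=0.0)
        total = joint_loglik(m0, data)
        parts = 0.0
        for name in struct.variables:
            sub = DBNStructure({name: struct.variables[name]}, struct.order,
                               set())
            sm = fit_mle(sub, data[[c for c in data.columns
                                    if c.startswith(name + "@")]],
                         pseudocount=0.0)
            parts += joint_loglik(sm, data)
        assert total == pytest.approx(parts, abs=1e-8)

    def test_matches_term_by_term_reference(self):
        """Independent brute-force evaluation of the factorized density."""
        rng = np.random.default_rng(12)
        n = 50
        ap = rng.integers(0, 2, n + 1)
        rr = rng.normal(size=n + 1)
        kinds = {"Ap": "discrete", "RR": "continuous"}
        struct = DBNStructure(kinds, 1, {(("Ap", 1), ("Ap", 0)),
                                         (("Ap", 0), ("RR", 0)),
                                         (("RR", 1), ("RR", 0))})
        data = build_lagged_table({"Ap": ap, "RR": rr}, 1)
        model = fit_mle(struct, data, pseudocount=0.5)
        # reference: loop over rows, multiply conditionals by hand
        ref = 0.0
        cpt = model.params["Ap"].cpt
        tab = model.params["RR"].table
        for t in range(1, n + 1):
            p = cpt[(ap[t - 1],)][ap[t]]
            ref += math.log(p)
            alpha, beta, sigma = tab[(ap[t],)]
            mu = alpha + beta[0] * rr[t - 1]
            ref += math.log(1 / (sigma * math.sqrt(2 * math.pi))) \
                - 0.5 * ((rr[t] - mu) / sigma) ** 2
        assert joint_loglik(model, data) == pytest.approx(ref, abs=1e-8)

    def test_zero_probability_gives_minus_inf(self):
        model = _single_binary_model(0.5)
        model.params["Ap"].cpt[()] = np.array([1.0, 0.0])
        data = build_lagged_table({"Ap": np.array([0, 0, 1, 0])}, 1)
        assert joint_loglik(model, data) == -math.inf


class TestFitMLE:
    def test_regression_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.normal(size=n + 1)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, size=n + 1)
        kinds = {"x": "continuous", "y": "continuous"}
        struct = DBNStructure(kinds, 0, {(("x", 0), ("y", 0))})
        data = build_lagged_table({"x": x, "y": y}, 0)
        model = fit_mle(struct, data)
        alpha, beta, sigma = model.params["y"].table[()]
        assert abs(alpha - 1.0) < 0.05
        assert abs(beta[0] - 2.0) < 0.05
        assert abs(sigma - 0.1) < 0.02

    def test_cpt_empirical_frequencies(self):
        ap = np.array([1] * 30 + [0] * 70)
        struct = DBNStructure({"Ap": "discrete"}, 0, set())
        data = build_lagged_table({"Ap": ap}, 0)
        model = fit_mle(struct, data, pseudocount=0.0)
        np.testing.assert_allclose(model.params["Ap"].cpt[()], [0.7, 0.3])

    def test_no_parent_node_mean_and_ml_sd(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 2, size=400)
        struct = DBNStructure({"x": "continuous"}, 0, set())
        data = build_lagged_table({"x": x}, 0)
        model = fit_mle(struct, data)
        alpha, beta, sigma = model.params["x"].table[()]
        assert alpha == pytest.approx(x.mean())
        assert sigma == pytest.approx(x.std())  # divisor n, not n-1
        assert len(beta) == 0

    def test_cpt_rows_normalized(self, hmm_like_model):
        model, _ = hmm_like_model
        for probs in model.params["Ap"].cpt.values():
            assert abs(probs.sum() - 1.0) < 1e-10

    def test_parameter_recovery_improves_with_n(self):
        """Errors of the fitted (alpha, beta, sigma) shrink as n grows."""
        truth = (0.5, 1.5, 0.4)
        errs = {}
        for n in (500, 5000):
            rng = np.random.default_rng(n)
            x = rng.normal(size=n)
            y = truth[0] + truth[1] * x + rng.normal(0, truth[2], size=n)
            struct = DBNStructure({"x": "continuous", "y": "continuous"}, 0,
                                  {(("x", 0), ("y", 0))})
            data = build_lagged_table({"x": x, "y": y}, 0)
            a, b, s = fit_mle(struct, data).params["y"].table[()]
            errs[n] = abs(a - truth[0]) + abs(b[0] - truth[1]) \
                + abs(s - truth[2])
        assert errs[5000] < errs[500]


class TestBIC:
    @staticmethod
    def _xy_data(with_effect: bool, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (2.0 * x if with_effect else 0.0) + rng.normal(0, 0.1, size=n) \
            + (0.0 if with_effect else rng.normal(0, 1, size=n) * 0)
        if not with_effect:
            y = rng.normal(size=n)
        return build_lagged_table({"x": x, "y": y}, 0)

    KINDS = {"x": "continuous", "y": "continuous"}

    def test_spurious_arc_decreases_bic(self):
        data = self._xy_data(with_effect=False, seed=5)
        empty = DBNStructure(self.KINDS, 0, set())
        arc = DBNStructure(self.KINDS, 0, {(("x", 0), ("y", 0))})
        assert bic_score(arc, data) < bic_score(empty, data)

    def test_true_arc_increases_bic(self):
        data = self._xy_data(with_effect=True, seed=6)
        empty = DBNStructure(self.KINDS, 0, set())
        arc = DBNStructure(self.KINDS, 0, {(("x", 0), ("y", 0))})
        assert bic_score(arc, data) > bic_score(empty, data)

    def test_decomposes_over_nodes(self):
        data = self._xy_data(with_effect=True, seed=7)
        empty = DBNStructure(self.KINDS, 0, set())
        parts = 0.0
        for name in self.KINDS:
            sub = DBNStructure({name: "continuous"}, 0, set())
            parts += bic_score(sub, data[[name + "@0"]])
        assert bic_score(empty, data) == pytest.approx(parts, abs=1e-8)


class TestGaussianityAndSampling:
    def test_continuous_joint_is_multivariate_normal(self, hmm_like_model):
        """With the discrete path fixed, ancestral samples of the continuous
        nodes must match the closed-form Gaussian implied by (alpha, beta,
        sigma)."""
        model, _ = hmm_like_model
        # freeze Ap == 0 forever: deterministic CPTs
        frozen = model_from_dict(model_to_dict(model))
        for cfg in frozen.params["Ap"].cpt:
            frozen.params["Ap"].cpt[cfg] = np.array([1.0, 0.0])
        frozen.prior["Ap"] = np.array([1.0, 0.0])
        draws = sample_model(frozen, 30000, seed=13, burn=300)
        assert (draws["Ap"] == 0).all()
        # closed form for the stationary AR(1) marginals under Ap == 0
        for node in ("RR", "DS"):
            alpha, beta, sigma = frozen.params[node].table[(0,)]
            phi = beta[0]
            mean_cf = alpha / (1 - phi)
            var_cf = sigma ** 2 / (1 - phi ** 2)
            x = draws[node]
            assert x.mean() == pytest.approx(mean_cf, abs=0.05)
            assert x.var() == pytest.approx(var_cf, rel=0.1)

    def test_sampling_then_fitting_recovers_parameters(self, hmm_like_model):
        model, _ = hmm_like_model
        draws = sample_model(model, 5000, seed=21)
        data = build_lagged_table(draws, model.order)
        refit = fit_mle(model.structure, data, pseudocount=0.5)
        for node in ("RR", "DS"):
            for cfg, (a, b, s) in model.params[node].table.items():
                a2, b2, s2 = refit.params[node].table[cfg]
                assert a2 == pytest.approx(a, abs=0.08)
                np.testing.assert_allclose(b2, b, atol=0.08)
                assert s2 == pytest.approx(s, rel=0.2)


class TestSerialization:
    def test_round_trip_arcs_and_loglik(self, hmm_like_model, tmp_path):
        model, series = hmm_like_model
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.structure.arcs == model.structure.arcs
        data = build_lagged_table(series, model.order)
        assert joint_loglik(back, data) == pytest.approx(
            joint_loglik(model, data), abs=1e-10)

    def test_two_node_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        series = {"Ap": rng.integers(0, 2, 60), "RR": rng.normal(size=60)}
        struct = DBNStructure({"Ap": "discrete", "RR": "continuous"}, 1,
                              {(("Ap", 1), ("Ap", 0)),
                               (("RR", 1), ("RR", 0))})
        data = build_lagged_table(series, 1)
        model = fit_mle(struct, data)
        path = tmp_path / "m.json"
        save_model(model, path)
        assert load_model(path).structure.arcs == struct.arcs

    def test_undeclared_node_in_arc_rejected(self, hmm_like_model):
        model, _ = hmm_like_model
        d = model_to_dict(model)
        d["arcs"].append(["ghost", 1, "RR", 0])
        with pytest.raises(ValueError):
            model_from_dict(d)

    def test_unknown_kind_rejected(self, hmm_like_model):
        model, _ = hmm_like_model
        d = model_to_dict(model)
        d["nodes"]["RR"]["kind"] = "fuzzy"
        with pytest.raises(ValueError):
            model_from_dict(d)

    def test_structure_parameter_mismatch_rejected(self, hmm_like_model):
        model, _ = hmm_like_model
        d = model_to_dict(model)
        d["nodes"]["RR"]["cont_parents"] = [["DS", 2]]
        with pytest.raises(ValueError):
            model_from_dict(d)
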