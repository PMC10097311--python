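"""Filtering, prediction, smoothing and the enumeration oracle."""

import math

import numpy as np
import pytest

from apneadbn.clg import (CLGModel, ContinuousNodeParams, DBNStructure,
                          DiscreteNodeParams)
from apneadbn.inference import (CapabilityError, EvidenceError,
                                ProbabilitySignal, brute_force_posterior,
                                filter_posterior, fixed_lag_smooth,
                                predict_ahead, training_rmse)
from conftest import random_clg_model


def _hmm_l1_model(p_stay1=0.8, p_enter=0.2, mu0=0.0, mu1=2.0, sigma=1.0,
                  prior1=0.3):
    """Order-1 model equivalent to a textbook 2-state Gaussian HMM."""
    kinds = {"Ap": "discrete", "RR": "continuous"}
    struct = DBNStructure(kinds, 1, {(("Ap", 1), ("Ap", 0)),
                                     (("Ap", 0), ("RR", 0))})
    params = {
        "Ap": DiscreteNodeParams([("Ap", 1)], [0, 1], {
            (0,): np.array([1 - p_enter, p_enter]),
            (1,): np.array([1 - p_stay1, p_stay1]),
        }),
        "RR": ContinuousNodeParams([], [("Ap", 0)], {
            (0,): (mu0, np.array([]), sigma),
            (1,): (mu1, np.array([]), sigma),
        }),
    }
    return CLGModel(structure=struct, params=params,
                    prior={"Ap": np.array([1 - prior1, prior1])},
                    states={"Ap": [0, 1]})


def _hand_forward(model, ys):
    """Textbook HMM forward pass computed with explicit scalar algebra."""
    A = np.array([model.params["Ap"].cpt[(0,)],
                  model.params["Ap"].cpt[(1,)]])  # A[i, j] = P(j | i)
    out = []
    pi = model.prior["Ap"].copy()
    for y in ys:
        em = np.array([
            math.exp(-0.5 * ((y - model.params["RR"].table[(s,)][0])
                             / model.params["RR"].table[(s,)][2]) ** 2)
            / (model.params["RR"].table[(s,)][2] * math.sqrt(2 * math.pi))
            for s in (0, 1)])
        joint = (pi @ A) * em
        pi = joint / joint.sum()
        out.append(pi[1])
    return np.array(out)


class TestFilterPosterior:
    def test_matches_hand_computed_hmm_forward(self):
        model = _hmm_l1_model()
        ys = [0.5, 2.5, -1.0]
        sig = filter_posterior(model, {"RR": np.array([9.9] + ys)})
        # beat 0 is the prior; beats 1..3 follow the hand algebra on the
        # three informative observations
        expected = _hand_forward(model, ys)
        assert sig.prior_flag[0] and not sig.prior_flag[1:].any()
        assert sig.p[0] == pytest.approx(0.3)
        np.testing.assert_allclose(sig.p[1:], expected, atol=1e-12)

    def test_uninformative_model_returns_prior_chain(self):
        # no continuous node depends on Ap: posterior = prior chain marginal
        kinds = {"Ap": "discrete", "RR": "continuous"}
        struct = DBNStructure(kinds, 1, {(("Ap", 1), ("Ap", 0)),
                                         (("RR", 1), ("RR", 0))})
        params = {
            "Ap": DiscreteNodeParams([("Ap", 1)], [0, 1], {
                (0,): np.array([0.9, 0.1]),
                (1,): np.array([0.4, 0.6]),
            }),
            "RR": ContinuousNodeParams([("RR", 1)], [], {
                (): (0.0, np.array([0.5]), 1.0)}),
        }
        model = CLGModel(structure=struct, params=params,
                         prior={"Ap": np.array([0.75, 0.25])},
                         states={"Ap": [0, 1]})
        rng = np.random.default_rng(0)
        sig = filter_posterior(model, {"RR": rng.normal(size=30)})
        # chain marginal: p_{t+1} = 0.1 (1-p_t) + 0.6 p_t
        p = 0.25
        for t in range(1, 30):
            p = 0.1 * (1 - p) + 0.6 * p
            assert sig.p[t] == pytest.approx(p, abs=1e-10)

    def test_agrees_with_enumeration(self, hmm_like_model):
        model, series = hmm_like_model
        obs = {"RR": series["RR"][:12], "DS": series["DS"][:12]}
        f = filter_posterior(model, obs)
        b = brute_force_posterior(model, obs, mode="filter")
        np.testing.assert_allclose(f.p, b.p, atol=1e-9)

    def test_posterior_bounded(self, hmm_like_model):
        model, series = hmm_like_model
        sig = filter_posterior(model, {"RR": series["RR"][:300],
                                       "DS": series["DS"][:300]})
        assert np.all(sig.p >= 0) and np.all(sig.p <= 1)

    def test_missing_marker_is_evidence_error(self, hmm_like_model):
        model, series = hmm_like_model
        with pytest.raises(EvidenceError):
            filter_posterior(model, {"RR": series["RR"][:20]})

    def test_order_cap(self):
        model = _hmm_l1_model()
        object.__setattr__(model.structure, "order", 16)
        with pytest.raises(CapabilityError):
            filter_posterior(model, {"RR": np.zeros(20)})


class TestOracleBattery:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_filter_matches_enumeration_many_models(self, order):
        """Central correctness property: the 2^L forward recursion equals
        full-sequence enumeration on every tractable instance."""
        worst = 0.0
        for seed in range(17):
            model = random_clg_model(1000 * order + seed, order=order)
            rng = np.random.default_rng(seed)
            obs = {"RR": rng.normal(0, 1.5, size=10)}
            f = filter_posterior(model, obs)
            b = brute_force_posterior(model, obs, mode="filter")
            worst = max(worst, np.abs(f.p - b.p).max())
        assert worst < 1e-9

    def test_single_beat_bayes_rule(self):
        model = _hmm_l1_model(prior1=0.3, p_enter=0.3, p_stay1=0.3)
        # with P(Ap_t=1)=0.3 regardless of history, one observation y:
        # posterior = 0.3 N(y;2,1) / (0.3 N(y;2,1) + 0.7 N(y;0,1))
        y = 1.2
        sig = filter_posterior(model, {"RR": np.array([0.0, y])})
        n1 = math.exp(-0.5 * (y - 2) ** 2)
        n0 = math.exp(-0.5 * y ** 2)
        assert sig.p[1] == pytest.approx(0.3 * n1 / (0.3 * n1 + 0.7 * n0),
                                         abs=1e-12)

    def test_absorbing_cpt_monotone_smoothed_posterior(self):
        # once-started-never-stops support restriction: under a *fixed*
        # evidence set the events {Ap_t = 1} are nested in t, so the
        # smoothed marginal must be non-decreasing
        model = _hmm_l1_model(p_stay1=1.0, p_enter=0.1)
        rng = np.random.default_rng(5)
        b = brute_force_posterior(model, {"RR": rng.normal(size=14)},
                                  mode="smooth")
        assert np.all(np.diff(b.p) >= -1e-12)


class TestPredictAhead:
    def test_delta_zero_equals_filtering(self, hmm_like_model):
        model, series = hmm_like_model
        obs = {"RR": series["RR"][:40], "DS": series["DS"][:40]}
        f = filter_posterior(model, obs)
        p0 = predict_ahead(model, obs, 0)
        np.testing.assert_allclose(p0.p, f.p, atol=1e-12)

    def test_long_horizon_converges_to_stationary(self):
        model = _hmm_l1_model(p_stay1=0.8, p_enter=0.2)
        # stationary distribution of the 2-state chain via eigenvector
        A = np.array([[0.8, 0.2], [0.2, 0.8]])
        evals, evecs = np.linalg.eig(A.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = pi / pi.sum()
        sig = predict_ahead(model, {"RR": np.array([0.0, 2.0, 2.0, 0.0])},
                            delta_steps=200)
        np.testing.assert_allclose(sig.p[1:], pi[1], atol=1e-6)

    def test_absorbing_state_monotone_in_delta(self):
        model = _hmm_l1_model(p_stay1=1.0, p_enter=0.15)
        obs = {"RR": np.array([0.0, 0.3, -0.2, 0.1])}
        last = None
        for d in range(6):
            p = predict_ahead(model, obs, d).p[-1]
            if last is not None:
                assert p >= last - 1e-12
            last = p


class TestFixedLagSmoothing:
    def test_tau_zero_equals_filtering(self, hmm_like_model):
        model, series = hmm_like_model
        obs = {"RR": series["RR"][:60], "DS": series["DS"][:60]}
        f = filter_posterior(model, obs)
        s = fixed_lag_smooth(model, obs, tau=0)
        np.testing.assert_allclose(s.p[~f.prior_flag], f.p[~f.prior_flag],
                                   atol=1e-10)

    @pytest.mark.parametrize("tau", [1, 2, 5, 12])
    def test_matches_enumeration_smoother_when_window_covers_all(self, tau):
        """With tau >= remaining evidence, the fixed-lag estimate equals the
        full smoothed marginal from enumeration."""
        for seed in (0, 1, 2):
            model = random_clg_model(300 + seed, order=2)
            rng = np.random.default_rng(seed)
            n = 10
            obs = {"RR": rng.normal(size=n)}
            s = fixed_lag_smooth(model, obs, tau=tau)
            b = brute_force_posterior(model, obs, mode="smooth")
            # beats m with m + tau >= n - 1 see all the evidence
            for m in range(n):
                if m + tau >= n - 1 and not s.prior_flag[m]:
                    assert s.p[m] == pytest.approx(b.p[m], abs=1e-9)

    def test_smoothing_not_worse_than_filtering(self):
        """Total variation to the full smoother never increases when moving
        from filtering to fixed-lag smoothing."""
        for seed in range(8):
            model = random_clg_model(700 + seed, order=1)
            rng = np.random.default_rng(seed)
            obs = {"RR": rng.normal(size=9)}
            f = filter_posterior(model, obs)
            s = fixed_lag_smooth(model, obs, tau=4)
            b = brute_force_posterior(model, obs, mode="smooth")
            keep = ~f.prior_flag
            tv_f = np.abs(f.p[keep] - b.p[keep]).sum()
            tv_s = np.abs(s.p[keep] - b.p[keep]).sum()
            assert tv_s <= tv_f + 1e-9


class TestTrainingRMSE:
    def test_perfect_prediction(self):
        p = ProbabilitySignal(p=np.array([0.0, 1.0, 1.0, 0.0]))
        assert training_rmse(p, np.array([0, 1, 1, 0])) == 0.0

    def test_half_probability_on_balanced_labels(self):
        p = ProbabilitySignal(p=np.full(10, 0.5))
        assert training_rmse(p, np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        flag = np.zeros(50, dtype=bool)
        flag[:5] = True
        p = ProbabilitySignal(p=probs, prior_flag=flag)
        ref = math.sqrt(np.mean((probs[5:] - labels[5:]) ** 2))
        assert training_rmse(p, labels) == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch(self):
        p = ProbabilitySignal(p=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            training_rmse(p, np.array([1]))
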