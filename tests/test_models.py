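import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavarb import make_params, run_model, simulate_subject
from pavarb import models as M
from pavarb.task import GO, NOGO


def fresh_bayes_state(v0=0.5, eta0_pav=2.0, eta0_inst=2.0, n=4):
    return M.ValueState(
        v_inst=[[0.0, 0.0] for _ in range(n)],
        v_pav=[v0] * n,
        eta_inst=[[eta0_inst, eta0_inst] for _ in range(n)],
        eta_pav=[eta0_pav] * n,
    )


class TestRLOps:
    @pytest.mark.parametrize("vig,vin,vp,pi,b,expected", [
        (0.5, 0.2, 0.4, 0.0, 0.0, (0.5, 0.2)),
        (0.0, 0.0, 1.0, 2.0, 0.3, (2.3, 0.0)),
        (0.5, 0.2, -0.4, 1.0, 0.0, (0.1, 0.2)),  # avoidance flips preference
    ])
    def test_integrate(self, vig, vin, vp, pi, b, expected):
        p = make_params("rl", alpha=0.1, rho=1, pi=pi, b=b, xi=0)
        v_go, v_nogo = M.rl_integrate(vig, vin, vp, p)
        assert (v_go, v_nogo) == pytest.approx(expected)

    def test_action_prob_cases(self):
        assert M.rl_action_prob(0, 0, 0.0) == pytest.approx(0.5)
        assert M.rl_action_prob(3.7, -1.2, 1.0) == pytest.approx(0.5)
        # softmax * (1 - xi) + xi/2 at a unit value difference
        assert M.rl_action_prob(1, 0, 0.1) == pytest.approx(0.7080, abs=1e-4)

    def test_action_prob_rejects_bad_lapse(self):
        with pytest.raises(M.InvalidParametersError):
            M.rl_action_prob(0, 0, 1.5)

    def test_update_examples(self):
        p = make_params("rl", alpha=0.5, rho=2, pi=0, b=0, xi=0)
        s = fresh_bayes_state(v0=0.0)
        M.rl_update(s, 0, GO, 1, p)
        assert s.v_inst[0][GO] == pytest.approx(1.0)  # 0 + 0.5*(2-0)

        p2 = make_params("rl", alpha=0.1, rho=1, pi=0, b=0, xi=0)
        s2 = fresh_bayes_state(v0=0.0)
        s2.v_pav[1] = 0.4
        before_untaken = s2.v_inst[1][NOGO]
        M.rl_update(s2, 1, GO, 0, p2)
        assert s2.v_pav[1] == pytest.approx(0.36)
        assert s2.v_inst[1][NOGO] == before_untaken

    def test_zero_learning_rate_freezes_state(self):
        p = make_params("rl", alpha=0.0, rho=1, pi=0, b=0, xi=0)
        s = fresh_bayes_state(v0=0.0)
        s.v_inst[0][GO] = 0.3
        M.rl_update(s, 0, GO, 1, p)
        assert s.v_inst[0][GO] == 0.3 and s.v_pav[0] == 0.0


class TestBayesOps:
    def test_posterior_mean_recursion(self):
        """v = 0.5 with eta0 = 2 plus one success gives (a+1)/(a+b+1) = 2/3."""
        s = fresh_bayes_state(v0=0.5, eta0_pav=2.0)
        M.bayes_value_update(s, 0, GO, 1)
        assert s.eta_pav[0] == 3.0
        assert s.v_pav[0] == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_infinitely_confident_prior_never_moves(self):
        s = fresh_bayes_state(v0=0.5, eta0_pav=1e12)
        M.bayes_value_update(s, 0, GO, 1)
        assert s.v_pav[0] == pytest.approx(0.5, abs=1e-9)

    def test_all_success_sequence_converges_monotonically(self):
        s = fresh_bayes_state(v0=-0.3, eta0_pav=2.0)
        prev = s.v_pav[0]
        for _ in range(500):
            M.bayes_value_update(s, 0, GO, 1)
            assert s.v_pav[0] >= prev
            prev = s.v_pav[0]
        assert s.v_pav[0] == pytest.approx(1.0, abs=0.01)

    def test_untaken_action_count_unchanged(self):
        s = fresh_bayes_state()
        M.bayes_value_update(s, 0, GO, 1)
        assert s.eta_inst[0][NOGO] == 2.0 and s.eta_inst[0][GO] == 3.0

    @pytest.mark.parametrize("v,action,expected", [
        (0.7, NOGO, 0.0), (0.7, GO, 0.7), (-0.5, GO, -0.5)])
    def test_pav_value(self, v, action, expected):
        assert M.bayes_pav_value(v, action) == expected

    @pytest.mark.parametrize("vi,vp,w,expected", [
        (0.8, 0.4, 0.0, 0.8), (0.8, 0.4, 1.0, 0.4), (0.8, 0.4, 0.5, 0.6)])
    def test_integrate_convex(self, vi, vp, w, expected):
        assert M.bayes_integrate(vi, vp, w) == pytest.approx(expected)

    def test_integrate_rejects_bad_weight(self):
        with pytest.raises(ValueError):
            M.bayes_integrate(0.5, 0.5, 1.2)

    def test_action_prob(self):
        assert M.bayes_action_prob(0.9, -0.4, 0.0) == pytest.approx(0.5)
        assert M.bayes_action_prob(1.0, 0.0, 2.0) == pytest.approx(0.8808, abs=1e-4)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-50, 50),
           st.floats(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_softmax_shift_invariance(self, v_go, v_nogo, shift, beta):
        p1 = M.bayes_action_prob(v_go, v_nogo, beta)
        p2 = M.bayes_action_prob(v_go + shift, v_nogo + shift, beta)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert 0.0 <= p1 <= 1.0


class TestLogOdds:
    def test_identical_predictors_give_zero_evidence(self):
        for r in (-1, 0, 1):
            assert M.logodds_update(1.3, 0.6, 0.6, r) == pytest.approx(1.3)

    def test_event_and_nonevent_updates(self):
        assert M.logodds_update(0.0, 0.8, 0.4, 1) == pytest.approx(
            math.log(2), abs=1e-4)
        assert M.logodds_update(0.0, 0.8, 0.4, 0) == pytest.approx(
            math.log(0.2 / 0.6), abs=1e-4)

    def test_loss_counts_as_event(self):
        assert M.logodds_update(0.0, 0.8, 0.4, -1) == pytest.approx(math.log(2))

    def test_clipping_keeps_evidence_finite(self):
        dl = M.logodds_update(0.0, 0.0, 1.0, 1)
        assert math.isfinite(dl)

    @pytest.mark.parametrize("L,w", [(0.0, 0.5), (math.log(3), 0.75),
                                     (50.0, 1.0), (-50.0, 0.0)])
    def test_weight_from_logodds(self, L, w):
        assert M.weight_from_logodds(L) == pytest.approx(w, abs=1e-6)

    def test_weight_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            M.weight_from_logodds(math.inf)

    def test_predictive_event_prob_bounds(self):
        # uniform smoothing: zero-count estimate is 1/2, zero value with
        # count eta gives 1/(eta+2)
        assert M.predictive_event_prob(0.0, 0.0) == pytest.approx(0.5)
        assert M.predictive_event_prob(0.0, 8.0) == pytest.approx(0.1)
        assert M.predictive_event_prob(1.0, 8.0) == pytest.approx(0.9)


class TestEngineContracts:
    def test_uniform_policy_loglik(self, eeg_config):
        p = make_params("adaptive", beta=0.0, v0_pav=0.5,
                        eta0_pav=2, eta0_inst=2)
        d, _ = simulate_subject(eeg_config, "adaptive", p, seed=0)
        stim, act, out = d.arrays("s0")
        _, ll, _ = run_model(stim, act, out, "adaptive", p)
        assert ll.sum() == pytest.approx(len(stim) * math.log(0.5))

    @pytest.mark.parametrize("model_label,kwargs", [
        ("rl", dict(alpha=0.3, rho=3.0, pi=1.5, b=0.4, xi=0.05)),
        ("fixed", dict(beta=4.0, v0_pav=0.4, eta0_pav=3, eta0_inst=3,
                       w_fixed=0.6)),
        ("adaptive", dict(beta=4.0, v0_pav=0.4, eta0_pav=3, eta0_inst=3)),
    ])
    def test_simulate_evaluate_roundtrip(self, eeg_config, model_label, kwargs):
        """Likelihood evaluation on a model's own simulated actions
        reproduces the simulated P(Go) trace exactly (shared engine)."""
        p = make_params(model_label, **kwargs)
        d, sim_trace = simulate_subject(eeg_config, model_label, p, seed=7)
        stim, act, out = d.arrays("s0")
        p_go, _, eval_trace = run_model(stim, act, out, model_label, p)
        np.testing.assert_array_equal(p_go, sim_trace.p_go)
        np.testing.assert_array_equal(eval_trace.w, sim_trace.w)
        np.testing.assert_array_equal(eval_trace.v_pav, sim_trace.v_pav)

    def test_trial1_adaptive_matches_fixed_at_half(self, eeg_config):
        """Before any data the adaptive weight is exactly the fixed
        model's w = 0.5 given identical priors."""
        common = dict(beta=3.0, v0_pav=0.4, eta0_pav=2, eta0_inst=2)
        ada = M.make_agent("adaptive", make_params("adaptive", **common))
        fix = M.make_agent("fixed", make_params("fixed", w_fixed=0.5, **common))
        assert ada.w == 0.5
        for s in range(4):
            assert ada.p_go(s) == fix.p_go(s)

    def test_adaptive_reduces_to_fixed_without_logodds_update(
            self, eeg_config, monkeypatch):
        common = dict(beta=3.0, v0_pav=0.4, eta0_pav=2, eta0_inst=2)
        d, _ = simulate_subject(
            eeg_config, "fixed", make_params("fixed", w_fixed=0.5, **common),
            seed=3)
        stim, act, out = d.arrays("s0")
        monkeypatch.setattr(M, "logodds_update", lambda L, *a: L)
        p_ada, ll_ada, _ = run_model(stim, act, out, "adaptive",
                                     make_params("adaptive", **common))
        p_fix, ll_fix, _ = run_model(stim, act, out, "fixed",
                                     make_params("fixed", w_fixed=0.5, **common))
        np.testing.assert_allclose(p_ada, p_fix, atol=1e-12)

    def test_rl_with_decaying_rate_matches_bayes_update(self):
        """alpha = 1/eta schedule with rho = 1 reproduces the Bayesian
        posterior-mean recursion."""
        rng = np.random.default_rng(5)
        outcomes = rng.choice([-1, 0, 1], size=50)
        sb = fresh_bayes_state(v0=0.5, eta0_pav=2.0, eta0_inst=2.0)
        v_rl, eta = 0.5, 2.0
        for r in outcomes:
            M.bayes_value_update(sb, 0, GO, int(r))
            eta += 1.0
            p = make_params("rl", alpha=1.0 / eta, rho=1.0, pi=0, b=0, xi=0)
            v_rl = v_rl + p.alpha * (p.rho * r - v_rl)
            assert v_rl == pytest.approx(sb.v_pav[0], abs=1e-12)

    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=60),
           st.floats(0.05, 1.0), st.floats(-1, 1), st.floats(1, 20))
    @settings(max_examples=60, deadline=None)
    def test_values_stay_bounded(self, outcomes, alpha, v0, eta0):
        """Both update rules keep values in [-1, 1] for outcomes in
        {-1, 0, 1}."""
        s = fresh_bayes_state(v0=v0, eta0_pav=eta0, eta0_inst=eta0)
        p = make_params("rl", alpha=alpha, rho=1.0, pi=0, b=0, xi=0)
        s_rl = fresh_bayes_state(v0=0.0)
        s_rl.v_pav[0] = v0
        for r in outcomes:
            M.bayes_value_update(s, 0, GO, r)
            M.rl_update(s_rl, 0, GO, r, p)
            assert -1.0 <= s.v_pav[0] <= 1.0
            assert -1.0 <= s.v_inst[0][GO] <= 1.0
            assert -1.0 <= s_rl.v_pav[0] <= 1.0

    def test_uncontrollable_outcomes_drive_weight_up(self):
        """When outcomes are independent of actions, the stimulus-only
        predictor wins evidence and w drifts above its 0.5 start."""
        p = make_params("adaptive", beta=3.0, v0_pav=0.3,
                        eta0_pav=3, eta0_inst=3)
        finals = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            T = 240
            stim = rng.integers(0, 4, size=T)
            act = rng.integers(0, 2, size=T)
            # event probability 0.5 regardless of action; sign by valence
            sign = np.where(stim % 2 == 0, 1, -1)
            out = np.where(rng.random(T) < 0.5, sign, 0)
            _, _, trace = run_model(stim, act, out, "adaptive", p)
            finals.append(trace.w[-1])
        assert np.mean(finals) > 0.5

    def test_mismatched_params_rejected(self):
        with pytest.raises(M.InvalidParametersError):
            M.make_agent("rl", make_params("adaptive", beta=1, v0_pav=0,
                                           eta0_pav=2, eta0_inst=2))
        with pytest.raises(M.InvalidParametersError):
            M.make_agent("fixed", make_params("adaptive", beta=1, v0_pav=0,
                                              eta0_pav=2, eta0_inst=2))

    def test_unknown_stimulus_id_rejected(self):
        p = make_params("adaptive", beta=1, v0_pav=0, eta0_pav=2, eta0_inst=2)
        with pytest.raises(ValueError):
            run_model([7], [1], [1], "adaptive", p)
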