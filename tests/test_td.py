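"""TD(lambda) critic: elementary updates, oracle equivalence, convergence."""
import numpy as np
import pytest

from tdtiming import (
    BasisConfig,
    CriticState,
    FeatureMap,
    LearnerConfig,
    PavlovianTD,
    predict_value,
    run_pavlovian_session,
    td_error,
    update_traces,
    update_weights,
)
from tdtiming.tasks import make_pavlovian_task


class TestElementaryOps:
    def test_value_is_dot_product(self):
        s = CriticState(np.array([1.0, 2.0]), np.zeros(2))
        assert predict_value(s, [0.5, 0.25]) == 1.0
        assert predict_value(CriticState.zeros(4), np.ones(4)) == 0.0
        one_hot = np.eye(3)[1]
        assert predict_value(CriticState(np.array([3.0, 5.0, 7.0]), np.zeros(3)), one_hot) == 5.0

    def test_value_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_value(CriticState.zeros(3), np.ones(4))

    @pytest.mark.parametrize(
        "r, v_next, v_curr, gamma, expected",
        [(1, 0, 0, 0.98, 1.0), (0, 1, 0.98, 0.98, 0.0), (0, 0, 1, 0.98, -1.0)],
    )
    def test_prediction_error(self, r, v_next, v_curr, gamma, expected):
        assert td_error(r, v_next, v_curr, gamma) == pytest.approx(expected)

    def test_trace_update(self):
        s = CriticState(np.zeros(2), np.array([1.0, 1.0]))
        out = update_traces(s, np.zeros(2), 0.98, 0.95)
        np.testing.assert_allclose(out.traces, [0.931, 0.931])
        # lambda = 0 reduces to the TD(0) trace e' = x
        out0 = update_traces(s, np.array([0.2, 0.7]), 0.98, 0.0)
        np.testing.assert_array_equal(out0.traces, [0.2, 0.7])

    def test_weight_update(self):
        s = CriticState.zeros(2)
        out = update_weights(s, alpha=0.01, delta=1.0, traces=np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.weights, [0.01, 0.0])
        same = update_weights(s, alpha=0.01, delta=0.0, traces=np.ones(2))
        np.testing.assert_array_equal(same.weights, s.weights)

    def test_nonfinite_delta_surfaces(self):
        with pytest.raises(FloatingPointError):
            update_weights(CriticState.zeros(2), 0.01, np.nan, np.ones(2))


def _reference_td0(timelines, basis, learner):
    """Independent TD(0) oracle: explicit loops, no eligibility traces.

    Mirrors the documented step semantics (inclusive value, lookahead
    target, pre-trial baseline step, terminal value 0) using only
    elementary numpy operations.
    """
    fmap = FeatureMap(basis)
    w = np.zeros(fmap.n_features(timelines[0]))
    all_deltas, all_values = [], []
    for tl in timelines:
        X = fmap.trial_matrix(tl)
        r = np.zeros(tl.duration_steps)
        if tl.reward_step is not None:
            r[tl.reward_step] = tl.reward_magnitude
        deltas = [learner.gamma * float(w @ X[0])]
        values = [0.0]
        for t in range(tl.duration_steps):
            v = float(w @ X[t])
            v_next = float(w @ X[t + 1]) if t + 1 < tl.duration_steps else 0.0
            delta = r[t] + learner.gamma * v_next - v
            w = w + learner.alpha * delta * X[t]
            deltas.append(delta)
            values.append(v)
        all_deltas.append(np.array(deltas))
        all_values.append(np.array(values))
    return all_values, all_deltas


class TestSessionEngine:
    def test_empty_task_is_empty_result(self):
        res = run_pavlovian_session([], BasisConfig(), LearnerConfig())
        assert res.n_trials == 0

    def test_td0_oracle_equivalence(self):
        basis = BasisConfig(n_features=10)
        learner = LearnerConfig(alpha=0.05, gamma=0.98, lam=0.0)
        tls = make_pavlovian_task(1.0, 20)
        ref_values, ref_deltas = _reference_td0(tls, basis, learner)
        sess = run_pavlovian_session(tls, basis, learner)
        for rec, rv, rd in zip(sess.trials, ref_values, ref_deltas):
            np.testing.assert_allclose(rec.value, rv, atol=1e-12)
            np.testing.assert_allclose(rec.delta, rd, atol=1e-12)

    def test_deterministic_rerun(self):
        tls = make_pavlovian_task(2.0, 30)
        a = run_pavlovian_session(tls)
        b = run_pavlovian_session(tls)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.trials[-1].delta, b.trials[-1].delta)

    def test_step_record_invariant(self):
        """delta = reward + gamma * value_next - value at every step."""
        tls = make_pavlovian_task(1.0, 5)
        learner = LearnerConfig()
        sess = run_pavlovian_session(tls, learner=learner, learn=False)
        rec = sess.trials[0]
        v_next = np.append(rec.value[1:], 0.0)
        np.testing.assert_allclose(
            rec.delta, rec.reward + learner.gamma * v_next - rec.value, atol=1e-12
        )

    def test_csc_convergence_to_discounted_closed_form(self):
        tls = make_pavlovian_task(1.0, 400)
        gamma = 0.98
        res = PavlovianTD(
            tls,
            basis=BasisConfig(kind="csc", n_features=None),
            learner=LearnerConfig(alpha=0.1, gamma=gamma, lam=0.95),
        ).fit()
        T = tls[0].reward_step
        values = res.value_curve()[: T + 1]
        analytic = gamma ** (T - np.arange(T + 1))
        assert np.max(np.abs(values - analytic)) < 0.01
        assert abs(res.final_trial().delta_at(T)) < 0.01

    def test_untrained_reward_is_fully_surprising(self):
        tls = make_pavlovian_task(2.0, 1)
        sess = run_pavlovian_session(tls)
        rec = sess.trials[0]
        assert rec.delta_at(tls[0].reward_step) == pytest.approx(1.0)
        assert rec.onset_delta() == pytest.approx(0.0)

    def test_long_run_accumulations_stay_finite(self):
        # ~1e6 learning steps at the conditioning defaults
        n_trials = int(1e6 // 61) + 1
        tls = make_pavlovian_task(1.0, n_trials)
        sess = run_pavlovian_session(tls)
        assert np.all(np.isfinite(sess.weights))
        assert np.all(np.isfinite(sess.trials[-1].delta))


class TestModelAPI:
    def test_fit_returns_results_with_summary(self):
        res = PavlovianTD(make_pavlovian_task(1.0, 10)).fit()
        text = res.summary()
        assert "alpha" in text and "trials: 10" in text
        df = res.to_frame()
        assert {"trial", "step", "value", "delta", "reward"} <= set(df.columns)

    def test_probe_runs_frozen(self):
        res = PavlovianTD(make_pavlovian_task(1.0, 50)).fit()
        before = res.weights.copy()
        res.probe(make_pavlovian_task(1.0, 3))
        np.testing.assert_array_equal(res.weights, before)
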