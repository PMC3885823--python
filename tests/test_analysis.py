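"""Session summaries: response curves, peak fits, psychometrics, PE read-outs."""
import numpy as np
import pytest

from tdtiming import BasisConfig, LearnerConfig
from tdtiming.analysis import (
    ResponseCurve,
    event_pe_summary,
    peak_statistics,
    psychometric,
    response_curve,
)
from tdtiming.tasks import TrialTimeline, make_pavlovian_task
from tdtiming.td import SessionResult, TrialRecord, run_pavlovian_session


def _action_session(actions_per_trial, duration=100, actions=("respond", "withhold"),
                    trial_type="peak_probe", timelines=None):
    """Assemble a SessionResult directly from per-trial action index arrays."""
    trials = []
    for i, acts in enumerate(actions_per_trial):
        n = len(acts)
        trials.append(
            TrialRecord(
                trial=i,
                trial_type=trial_type,
                step=np.arange(-1, n),
                value=np.zeros(n + 1),
                delta=np.zeros(n + 1),
                reward=np.zeros(n + 1),
                action=np.concatenate(([len(actions)], acts)),
                p_respond=np.full(n + 1, np.nan),
            )
        )
    tls = timelines or [
        TrialTimeline(duration_steps=duration, trial_type=trial_type)
        for _ in actions_per_trial
    ]
    return SessionResult(
        trials, np.zeros(1), BasisConfig(), LearnerConfig(), tls,
        actions=tuple(actions),
    )


class TestResponseCurve:
    def test_never_responding_gives_zero_curve(self):
        sess = _action_session([np.ones(100, dtype=int)] * 5)
        curve = response_curve(sess, bin_s=1.0)
        assert np.all(curve.rate == 0.0)

    def test_always_responding_gives_unit_curve(self):
        sess = _action_session([np.zeros(100, dtype=int)] * 5)
        curve = response_curve(sess, bin_s=1.0)
        assert np.all(curve.rate == 1.0)
        assert curve.n_trials == 5

    def test_rate_matches_bernoulli_policy(self):
        rng = np.random.default_rng(0)
        p = 0.3
        acts = [(rng.random(100) > p).astype(int) for _ in range(200)]
        curve = response_curve(_action_session(acts), bin_s=1.0)
        se = np.sqrt(p * (1 - p) / (200 * 20))
        assert np.all(np.abs(curve.rate - p) < 4 * se)

    def test_no_matching_trials_is_an_error(self):
        sess = _action_session([np.zeros(10, dtype=int)], trial_type="train")
        with pytest.raises(ValueError):
            response_curve(sess, trial_filter="peak_probe")


class TestPeakStatistics:
    def _curve(self, mu, sd, amp=0.5, base=0.1, tmax=60.0, bin_s=1.0):
        t = np.arange(bin_s / 2, tmax, bin_s)
        rate = base + amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
        return ResponseCurve(t, rate, n_trials=100)

    def test_parameter_recovery_noise_free(self):
        stats = peak_statistics(self._curve(mu=20.0, sd=5.0))
        assert stats.peak_time_s == pytest.approx(20.0, rel=0.05)
        assert stats.spread_s == pytest.approx(5.0, rel=0.05)
        assert stats.fit_quality > 0.999

    def test_time_stretch_doubles_spread(self):
        a = peak_statistics(self._curve(20.0, 5.0))
        b = peak_statistics(self._curve(40.0, 10.0, tmax=120.0))
        assert b.spread_s == pytest.approx(2 * a.spread_s, rel=0.05)
        assert b.peak_time_s == pytest.approx(2 * a.peak_time_s, rel=0.05)

    def test_baseline_does_not_move_peak(self):
        lo = peak_statistics(self._curve(20.0, 5.0, base=0.05))
        hi = peak_statistics(self._curve(20.0, 5.0, base=0.45))
        assert hi.peak_time_s == pytest.approx(lo.peak_time_s, abs=0.2)

    def test_triangular_curve_center(self):
        t = np.arange(0.5, 40.0)
        rate = np.clip(1 - np.abs(t - 20.0) / 10.0, 0, None) * 0.8
        stats = peak_statistics(ResponseCurve(t, rate, n_trials=10))
        assert stats.peak_time_s == pytest.approx(20.0, abs=1.0)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            peak_statistics(ResponseCurve(np.arange(5.0), np.zeros(5), 1))


class TestPsychometric:
    def _session(self, per_duration_choices):
        """per_duration_choices: {duration_s: list of 'short'/'long'}."""
        actions = ("short", "long", "withhold")
        trials, tls = [], []
        i = 0
        for dur_s, choices in per_duration_choices.items():
            for c in choices:
                dur = int(dur_s * 20)
                a = np.full(dur + 20, 3)
                a[dur + 1] = actions.index(c)
                trials.append(
                    TrialRecord(
                        trial=i, trial_type="bisection_probe",
                        step=np.arange(-1, dur + 19),
                        value=np.zeros(dur + 20), delta=np.zeros(dur + 20),
                        reward=np.zeros(dur + 20), action=a,
                        p_respond=np.full(dur + 20, np.nan),
                    )
                )
                tls.append(
                    TrialTimeline(
                        duration_steps=dur + 19, trial_type="bisection_probe",
                        response_window=(dur, dur + 19), probe_duration_s=dur_s,
                    )
                )
                i += 1
        return SessionResult(trials, np.zeros(1), BasisConfig(), LearnerConfig(),
                             tls, actions=actions)

    def test_step_function_indifference_at_log_midpoint(self):
        durs = [2.0, 2.83, 5.66, 8.0]
        sess = self._session(
            {durs[0]: ["short"] * 4, durs[1]: ["short"] * 4,
             durs[2]: ["long"] * 4, durs[3]: ["long"] * 4}
        )
        res = psychometric(sess)
        np.testing.assert_allclose(res.p_long, [0, 0, 1, 1])
        assert res.indifference_s == pytest.approx(
            np.exp(0.5 * (np.log(2.83) + np.log(5.66))), rel=1e-6
        )

    def test_all_long_has_no_indifference_point(self):
        sess = self._session({2.0: ["long"] * 3, 8.0: ["long"] * 3})
        assert psychometric(sess).indifference_s is None


class TestEventPESummary:
    def test_untrained_model_read_out(self):
        tls = make_pavlovian_task(2.0, 1)
        sess = run_pavlovian_session(tls)
        (row,) = event_pe_summary([(2.0, sess)], k_last=1)
        assert row.reward_delta == pytest.approx(1.0)
        assert row.cue_delta == pytest.approx(0.0)

    def test_k_last_validated(self):
        sess = run_pavlovian_session(make_pavlovian_task(1.0, 2))
        with pytest.raises(ValueError):
            event_pe_summary([(1.0, sess)], k_last=5)
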