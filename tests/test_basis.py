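"""Temporal basis functions: traces, microstimuli, CSC, gain profiles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdtiming.basis import (
    BasisConfig,
    FeatureMap,
    GainProfile,
    assemble_features,
    csc_features,
    gain_vector,
    microstimulus_features,
    trace_strength,
)
from tdtiming.tasks import TrialTimeline

PHI0 = 1.0 / math.sqrt(2 * math.pi)


class TestTraceStrength:
    @pytest.mark.parametrize(
        "t, rho, expected",
        [
            (0, 0.985, 1.0),
            (1, 0.985, 0.985),
            # 0.985**20 frozen from repeated multiplication
            (20, 0.985, 0.7391364333471014),
        ],
    )
    def test_exponential_decay(self, t, rho, expected):
        assert trace_strength(t, rho) == pytest.approx(expected, abs=1e-14)

    def test_absent_stimulus_has_zero_trace(self):
        assert trace_strength(None, 0.985) == 0.0
        assert trace_strength(-3, 0.985) == 0.0

    def test_strictly_decreasing_from_one(self):
        vals = trace_strength(np.arange(200), 0.985)
        assert vals[0] == 1.0
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("rho", [0.0, 1.0, 1.5, -0.1])
    def test_invalid_decay_rejected(self, rho):
        with pytest.raises(ValueError):
            trace_strength(5, rho)


class TestMicrostimuli:
    def test_zero_trace_gives_zero_block(self):
        assert np.all(microstimulus_features(0.0, 50, 0.08) == 0.0)

    def test_receptive_field_center_value(self):
        # at onset (y=1) the feature centered at 1.0 sits at the Gaussian peak
        x = microstimulus_features(1.0, 50, 0.08)
        assert x[-1] == pytest.approx(PHI0, rel=1e-12)

    def test_far_from_center_suppression(self):
        x = microstimulus_features(1.0, 50, 0.08)
        # center 0.5 is 6.25 sigma away: essentially silent
        expected = PHI0 * math.exp(-0.25 / (2 * 0.08**2))
        assert x[24] == pytest.approx(expected, rel=1e-9)
        assert x[24] < 1e-8

    def test_bounded_by_gaussian_peak(self):
        for y in np.linspace(0, 1, 23):
            assert np.all(microstimulus_features(y, 50, 0.08) <= PHI0 + 1e-15)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            microstimulus_features(0.5, 50, 0.0)

    def test_time_course_unimodal_and_late_fields_broader(self):
        # drive each microstimulus by the decaying trace over 2000 steps
        y = trace_strength(np.arange(2000), 0.985)
        D, sigma = 10, 0.08
        courses = np.stack([microstimulus_features(yt, D, sigma) for yt in y])
        fwhm = []
        for d in range(D):
            x = courses[:, d]
            peak = np.argmax(x)
            # rises (weakly) before the peak, falls (weakly) after: unimodal
            assert np.all(np.diff(x[: peak + 1]) >= -1e-15)
            assert np.all(np.diff(x[peak:]) <= 1e-15)
            above = np.flatnonzero(x >= x[peak] / 2)
            fwhm.append(above[-1] - above[0])
        # smaller center d/D => later peak => broader time course
        assert np.all(np.diff(fwhm) < 0)


class TestCSC:
    @pytest.mark.parametrize(
        "t, horizon, hot",
        [(0, 5, 0), (3, 5, 3), (7, 5, None), (None, 5, None)],
    )
    def test_one_hot_by_lag(self, t, horizon, hot):
        x = csc_features(t, horizon)
        assert x.shape == (horizon,)
        if hot is None:
            assert np.all(x == 0)
        else:
            assert x[hot] == 1.0 and x.sum() == 1.0

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            csc_features(0, 0)


class TestGainProfile:
    def test_identity_profile(self):
        g = gain_vector(GainProfile(), 7)
        assert np.all(g == 1.0)

    def test_threshold_rule_with_boundary_center(self):
        # centers {0.25, 0.5, 0.75, 1.0}; centers >= theta count as early
        g = gain_vector(GainProfile(theta=0.5, gain_early=0.5, gain_late=1.0), 4)
        np.testing.assert_allclose(g, [1.0, 0.5, 0.5, 0.5])

    def test_only_latest_center_scaled_at_theta_one(self):
        g = gain_vector(GainProfile(theta=1.0, gain_early=2.0, gain_late=1.0), 2)
        np.testing.assert_allclose(g, [1.0, 2.0])

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            GainProfile(gain_early=-0.1)


def _timeline(duration=60, reward=40):
    return TrialTimeline(
        duration_steps=duration, cue_onsets={"cue": 0}, reward_step=reward
    )


class TestAssembleFeatures:
    def test_before_any_onset_all_zero(self):
        tl = TrialTimeline(duration_steps=30, cue_onsets={"cue": 10})
        cfg = BasisConfig()
        assert np.all(assemble_features(tl, 5, cfg) == 0.0)

    def test_csc_onset_one_hot(self):
        tl = _timeline()
        cfg = BasisConfig(kind="csc", n_features=None)
        x = assemble_features(tl, 0, cfg)
        assert x[0] == 1.0 and x.sum() == 1.0

    def test_composition_of_blocks(self):
        tl = _timeline()
        cfg = BasisConfig()
        t = 45  # after both cue and reward onset
        x = assemble_features(tl, t, cfg)
        cue = microstimulus_features(trace_strength(t, cfg.rho), 50, cfg.sigma)
        rew = microstimulus_features(
            trace_strength(t - tl.reward_step, cfg.rho), 50, cfg.sigma
        )
        np.testing.assert_array_equal(x, np.concatenate([cue, rew]))

    def test_identity_gain_is_bit_identical(self):
        tl = _timeline()
        cfg = BasisConfig()
        gains = {"cue": GainProfile(), "reward": GainProfile()}
        for t in (0, 20, 41, 59):
            np.testing.assert_array_equal(
                assemble_features(tl, t, cfg, gains), assemble_features(tl, t, cfg)
            )

    def test_unknown_stimulus_id_rejected(self):
        with pytest.raises(KeyError):
            assemble_features(_timeline(), 0, BasisConfig(), {"tone": GainProfile()})

    def test_out_of_range_step_rejected(self):
        with pytest.raises(ValueError):
            assemble_features(_timeline(), 60, BasisConfig())


class TestFeatureMap:
    @pytest.mark.parametrize("kind", ["microstimulus", "csc"])
    def test_matches_assemble_features(self, kind):
        tl = _timeline()
        cfg = BasisConfig(kind=kind, n_features=None if kind == "csc" else 50)
        X = FeatureMap(cfg).trial_matrix(tl)
        for t in (0, 1, 39, 40, 41, 59):
            np.testing.assert_array_equal(X[t], assemble_features(tl, t, cfg))

    def test_gains_applied_to_named_block(self):
        tl = _timeline()
        cfg = BasisConfig()
        gains = {"cue": GainProfile(theta=0.0, gain_early=0.5, gain_late=0.5)}
        X = FeatureMap(cfg, gains).trial_matrix(tl)
        X0 = FeatureMap(cfg).trial_matrix(tl)
        np.testing.assert_allclose(X[:, :50], 0.5 * X0[:, :50])
        np.testing.assert_array_equal(X[:, 50:], X0[:, 50:])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    y=st.floats(0.0, 1.0),
    d=st.integers(1, 80),
    sigma=st.floats(0.01, 0.5),
)
def test_microstimulus_block_nonnegative_and_bounded(y, d, sigma):
    x = microstimulus_features(y, d, sigma)
    assert x.shape == (d,)
    assert np.all(x >= 0.0)
    assert np.all(x <= PHI0 + 1e-12)
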