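"""Summaries of simulated sessions: response curves, peak statistics,
psychometric functions and event-locked prediction-error read-outs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .td import SessionResult

__all__ = [
    "ResponseCurve",
    "PeakStats",
    "PsychometricResult",
    "PESummary",
    "response_curve",
    "peak_statistics",
    "psychometric",
    "event_pe_summary",
]


@dataclass
class ResponseCurve:
    """Empirical response frequency per time bin across probe trials."""

    bin_centers_s: np.ndarray
    rate: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.bin_centers_s = np.asarray(self.bin_centers_s, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.bin_centers_s.shape != self.rate.shape:
            raise ValueError("bin centers and rates must have equal length")
        if np.any((self.rate < 0) | (self.rate > 1)):
            raise ValueError("rates must be frequencies in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.bin_centers_s, "rate": self.rate})


@dataclass
class PeakStats:
    """Gaussian summary of a response curve.

    ``peak_time_s``/``spread_s`` are the fitted mean and SD;
    ``fit_quality`` is the R^2 of the Gaussian-plus-baseline fit (set to
    ``nan`` when the fit failed and the smoothed argmax fallback was used).
    ``raw_peak_time_s`` is the argmax of the raw curve.
    """

    peak_time_s: float
    spread_s: float
    fit_quality: float
    amplitude: float = float("nan")
    baseline: float = float("nan")
    raw_peak_time_s: float = float("nan")


@dataclass
class PsychometricResult:
    """p(long) per probe duration and the interpolated indifference point."""

    durations_s: np.ndarray
    p_long: np.ndarray
    indifference_s: Optional[float]
    n_choices: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"duration_s": self.durations_s, "p_long": self.p_long,
             "n_choices": self.n_choices}
        )


@dataclass
class PESummary:
    """Event-locked prediction errors for one cue-reward interval."""

    interval_s: float
    cue_delta: float
    reward_delta: float


def response_curve(
    session: SessionResult,
    bin_s: float = 1.0,
    trial_filter: str = "peak_probe",
) -> ResponseCurve:
    """Per-bin empirical frequency of "respond" across selected trials.

    Bins of width ``bin_s`` cover the probe duration; the rate in a bin is
    the number of sampled "respond" actions divided by the number of
    action steps falling in it.
    """
    if not bin_s > 0:
        raise ValueError("bin_s must be > 0")
    if session.actions is None:
        raise ValueError("session carries no action records")
    trials = [r for r in session.trials if r.trial_type == trial_filter]
    if not trials:
        raise ValueError(f"no trials of type {trial_filter!r} in session")
    i_respond = list(session.actions).index("respond")
    no_action = len(session.actions)
    sps = session.basis.steps_per_second
    dur_steps = max(int(r.step[-1]) + 1 for r in trials)
    bin_steps = bin_s * sps
    n_bins = int(np.ceil(dur_steps / bin_steps))
    responded = np.zeros(n_bins)
    counted = np.zeros(n_bins)
    for rec in trials:
        mask = (rec.action != no_action) & (rec.step >= 0)
        bins = (rec.step[mask] / bin_steps).astype(int)
        np.add.at(counted, bins, 1)
        np.add.at(responded, bins, rec.action[mask] == i_respond)
    with np.errstate(invalid="ignore"):
        rate = np.where(counted > 0, responded / np.maximum(counted, 1), 0.0)
    centers = (np.arange(n_bins) + 0.5) * bin_s
    return ResponseCurve(centers, rate, n_trials=len(trials))


def _gauss(t, amp, mu, sd, base):
    return base + amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)


def peak_statistics(curve: ResponseCurve, smooth_bins: int = 3) -> PeakStats:
    """Gaussian (amplitude, mean, SD, baseline) least-squares summary.

    Falls back to the argmax of a ``smooth_bins``-wide moving average when
    the fit fails; the fallback is flagged by ``fit_quality = nan``.
    """
    t = curve.bin_centers_s
    y = curve.rate
    if len(t) == 0 or not np.any(y > 0):
        raise ValueError("cannot locate a peak on an empty or all-zero curve")
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(y, kernel, mode="same")
    raw_peak = float(t[np.argmax(smoothed)])
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    p0 = [max(y.max() - y.min(), 1e-3), raw_peak, max(span / 6, 1e-2), y.min()]
    try:
        popt, _ = curve_fit(
            _gauss, t, y, p0=p0,
            bounds=([0, t[0] - span, 1e-3, 0], [2, t[-1] + span, 4 * span, 1]),
            maxfev=20000,
        )
        amp, mu, sd, base = popt
        resid = y - _gauss(t, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        return PeakStats(
            peak_time_s=float(mu), spread_s=float(sd), fit_quality=r2,
            amplitude=float(amp), baseline=float(base),
            raw_peak_time_s=raw_peak,
        )
    except RuntimeError:
        return PeakStats(
            peak_time_s=raw_peak, spread_s=float("nan"),
            fit_quality=float("nan"), raw_peak_time_s=raw_peak,
        )


def psychometric(session: SessionResult) -> PsychometricResult:
    """Choice proportions on bisection probes and the indifference point.

    ``p(long)`` is computed per probe duration over trials on which a
    choice was made.  The indifference point is found by linear
    interpolation of p(long) against *log* duration at 0.5 (consistent
    with the geometric-mean regularity of bisection); if the curve never
    crosses 0.5 the indifference point is reported as ``None``.
    """
    if session.actions is None:
        raise ValueError("session carries no action records")
    acts = list(session.actions)
    by_dur: dict = {}
    for rec, tl in zip(session.trials, session.timelines):
        if rec.trial_type != "bisection_probe":
            continue
        chosen = [a for a in rec.action if a < len(acts) and acts[a] in ("short", "long")]
        if tl.probe_duration_s is None:
            continue
        n_long, n_choice = by_dur.get(tl.probe_duration_s, (0, 0))
        if chosen:
            n_choice += 1
            n_long += int(acts[chosen[0]] == "long")
        by_dur[tl.probe_duration_s] = (n_long, n_choice)
    if not by_dur:
        raise ValueError("no bisection probe trials in session")
    durs = np.array(sorted(by_dur))
    n_long = np.array([by_dur[d][0] for d in durs], dtype=float)
    n_choice = np.array([by_dur[d][1] for d in durs], dtype=float)
    with np.errstate(invalid="ignore"):
        p_long = np.where(n_choice > 0, n_long / np.maximum(n_choice, 1), np.nan)
    indiff = _interp_indifference(durs, p_long)
    return PsychometricResult(durs, p_long, indiff, n_choices=n_choice)


def _interp_indifference(durs: np.ndarray, p_long: np.ndarray) -> Optional[float]:
    ok = ~np.isnan(p_long)
    x, p = np.log(durs[ok]), p_long[ok]
    for i in range(len(p) - 1):
        lo, hi = p[i], p[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            frac = (0.5 - lo) / (hi - lo)
            return float(np.exp(x[i] + frac * (x[i + 1] - x[i])))
        if lo == hi == 0.5:
            return float(np.exp(0.5 * (x[i] + x[i + 1])))
    return None


def event_pe_summary(
    sessions: Sequence[tuple],
    k_last: int = 1,
) -> List[PESummary]:
    """Cue- and reward-locked prediction errors per cue-reward interval.

    ``sessions`` is a sequence of ``(interval_s, SessionResult)`` pairs.
    For each session the cue delta (prediction error generated by cue
    onset, i.e. on the transition into the onset state) and the delta at
    the reward step are averaged over the last ``k_last`` trials.
    """
    out = []
    for interval_s, session in sessions:
        if k_last > session.n_trials or k_last < 1:
            raise ValueError("k_last must lie in [1, n_trials]")
        last = session.trials[-k_last:]
        cue = float(np.mean([r.onset_delta(0) for r in last]))
        rew = float(
            np.mean(
                [r.delta_at(r.reward_step) for r in last if r.reward_step is not None]
            )
        ) if any(r.reward_step is not None for r in last) else float("nan")
        out.append(PESummary(interval_s=interval_s, cue_delta=cue, reward_delta=rew))
    return out
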