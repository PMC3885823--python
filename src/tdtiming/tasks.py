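"""Trial-timeline generators for conditioning and interval-timing tasks.

All tasks are trial based: each :class:`TrialTimeline` is a discretized event
schedule (cue onsets, reward time or contingency, duration) and trials are
separated by a long intertrial interval (500 steps by default) during which
stimulus traces decay to nothing; the simulation engines therefore treat
trials as episodes with fresh eligibility traces.

Four generators cover the experiments:

* :func:`make_pavlovian_task` — fixed cue-reward interval conditioning.
* :func:`make_probe_trial` — early-reward / omission / extended-cue probes.
* :func:`make_peak_task` — the peak procedure: reinforced fixed-interval
  trials (first response at or after the criterion time is rewarded)
  randomly interleaved with long unrewarded probe trials.
* :func:`make_bisection_task` — temporal bisection: short/long anchor-cue
  trials with a post-cue choice window, plus unreinforced probes at
  log-spaced intermediate durations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "TrialTimeline",
    "TaskSpec",
    "make_pavlovian_task",
    "make_probe_trial",
    "make_peak_task",
    "make_bisection_task",
]

#: Default intertrial interval, in steps (25 s at 20 steps/s).
DEFAULT_ITI_STEPS = 500

#: Default post-reward window appended to Pavlovian trials, in seconds.
POST_REWARD_WINDOW_S = 2.0

TRIAL_TYPES = (
    "train",
    "probe_early",
    "probe_omission",
    "probe_extended",
    "peak_probe",
    "bisection_probe",
)


@dataclass(frozen=True)
class TrialTimeline:
    """Discretized event schedule for a single trial.

    ``reward_step`` is the scheduled (Pavlovian) reward time, or ``None``
    when no reward is scheduled — either because the trial is a probe or
    because reward is response-contingent (``fi_steps`` set), in which case
    the engine assigns the reward time at run time.
    ``response_window`` restricts action sampling to ``[start, stop)`` steps
    (bisection); when ``None`` actions may be taken at every step.
    """

    duration_steps: int
    cue_onsets: Dict[str, int] = field(default_factory=dict)
    reward_step: Optional[int] = None
    reward_magnitude: float = 1.0
    trial_type: str = "train"
    fi_steps: Optional[int] = None
    response_window: Optional[Tuple[int, int]] = None
    correct_action: Optional[str] = None
    probe_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration_steps < 1:
            raise ValueError("duration_steps must be >= 1")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        for stim, onset in self.cue_onsets.items():
            if not 0 <= onset < self.duration_steps:
                raise ValueError(f"cue {stim!r} onset {onset} outside trial")
        if self.reward_step is not None:
            if not 0 <= self.reward_step < self.duration_steps:
                raise ValueError("reward_step outside trial duration")
            if self.trial_type.startswith(("probe_o", "probe_ex", "peak", "bisection")):
                raise ValueError(f"{self.trial_type} trials cannot carry a reward")
        if self.response_window is not None:
            lo, hi = self.response_window
            if not 0 <= lo < hi <= self.duration_steps:
                raise ValueError("response window outside trial duration")


@dataclass(frozen=True)
class TaskSpec:
    """Generator parameters for a trial sequence (kept for config round-trips)."""

    interval_s: float = 2.0
    iti_steps: int = DEFAULT_ITI_STEPS
    n_trials: int = 100
    probe_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.interval_s > 0:
            raise ValueError("interval_s must be > 0")
        if not 0.0 <= self.probe_fraction <= 1.0:
            raise ValueError("probe_fraction must lie in [0, 1]")


def make_pavlovian_task(
    interval_s: float,
    n_trials: int,
    steps_per_second: int = 20,
    post_reward_s: float = POST_REWARD_WINDOW_S,
    reward_magnitude: float = 1.0,
) -> List[TrialTimeline]:
    """Fixed-interval Pavlovian conditioning trials.

    Each trial presents the cue at step 0 and the reward
    ``round(interval_s * steps_per_second)`` steps later; the trial extends
    ``post_reward_s`` beyond the reward so post-reward prediction errors are
    observable.
    """
    if not interval_s > 0:
        raise ValueError("interval_s must be > 0")
    reward_step = int(round(interval_s * steps_per_second))
    if reward_step == 0:
        raise ValueError("interval rounds to zero steps at this resolution")
    duration = reward_step + int(round(post_reward_s * steps_per_second)) + 1
    trial = TrialTimeline(
        duration_steps=duration,
        cue_onsets={"cue": 0},
        reward_step=reward_step,
        reward_magnitude=reward_magnitude,
    )
    return [trial] * n_trials


def make_probe_trial(
    base: TrialTimeline,
    kind: str,
    shift_s: float = 0.0,
    steps_per_second: int = 20,
    extension_s: float = 2.0,
) -> TrialTimeline:
    """Derive a probe trial from a training trial.

    ``probe_early`` moves the reward ``shift_s`` seconds earlier;
    ``probe_omission`` removes the reward; ``probe_extended`` removes the
    reward and extends the trial by ``extension_s``.
    """
    if base.reward_step is None:
        raise ValueError("base trial has no scheduled reward")
    if kind == "probe_early":
        shift = int(round(shift_s * steps_per_second))
        new_step = base.reward_step - shift
        if new_step < 0:
            raise ValueError("early shift exceeds the trained interval")
        if shift == 0:
            return base
        return replace(base, reward_step=new_step, trial_type="probe_early")
    if kind == "probe_omission":
        return replace(base, reward_step=None, trial_type="probe_omission")
    if kind == "probe_extended":
        ext = int(round(extension_s * steps_per_second))
        return replace(
            base,
            reward_step=None,
            duration_steps=base.duration_steps + ext,
            trial_type="probe_extended",
        )
    raise ValueError(f"unknown probe kind {kind!r}")


def _interleave(train: List[TrialTimeline], probes: List[TrialTimeline], seed):
    rng = np.random.default_rng(seed)
    trials = train + probes
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def make_peak_task(
    fi_s: float,
    n_trials: int,
    probe_fraction: float = 0.25,
    probe_multiple: float = 3.0,
    steps_per_second: int = 20,
    seed: Optional[int] = None,
    reward_magnitude: float = 1.0,
) -> List[TrialTimeline]:
    """Peak-procedure trial sequence.

    Reinforced fixed-interval trials (reward contingent on the first
    "respond" at or after ``fi_s``) are randomly interleaved (seeded) with
    unrewarded probe trials lasting ``probe_multiple`` times the interval.
    """
    if not fi_s > 0:
        raise ValueError("fi_s must be > 0")
    if not 0.0 <= probe_fraction <= 1.0:
        raise ValueError("probe_fraction must lie in [0, 1]")
    fi_steps = int(round(fi_s * steps_per_second))
    if fi_steps == 0:
        raise ValueError("fixed interval rounds to zero steps")
    probe_steps = int(round(probe_multiple * fi_s * steps_per_second))
    n_probe = int(round(probe_fraction * n_trials))
    fi_trial = TrialTimeline(
        duration_steps=probe_steps,  # cap: unanswered FI trials end with the probe span
        cue_onsets={"cue": 0},
        fi_steps=fi_steps,
        reward_magnitude=reward_magnitude,
        trial_type="train",
    )
    probe = TrialTimeline(
        duration_steps=probe_steps,
        cue_onsets={"cue": 0},
        trial_type="peak_probe",
    )
    return _interleave([fi_trial] * (n_trials - n_probe), [probe] * n_probe, seed)


def bisection_probe_durations(short_s: float, long_s: float, n: int) -> np.ndarray:
    """``n`` log-spaced probe durations strictly between the anchors."""
    if not 0 < short_s < long_s:
        raise ValueError("anchors must satisfy 0 < short < long")
    return np.exp(np.linspace(np.log(short_s), np.log(long_s), n + 2))[1:-1]


def make_bisection_task(
    short_s: float,
    long_s: float,
    n_probe_durations: int,
    n_trials: int,
    probe_fraction: float = 0.25,
    choice_window_s: float = 2.0,
    steps_per_second: int = 20,
    seed: Optional[int] = None,
    reward_magnitude: float = 1.0,
) -> List[TrialTimeline]:
    """Temporal-bisection trial sequence.

    Training trials present a short- or long-anchor cue (equally often); a
    choice window opens at cue offset and the anchor-consistent choice is
    rewarded.  Probe trials use log-spaced intermediate durations and are
    never reinforced.
    """
    if not 0 < short_s < long_s:
        raise ValueError("anchors must satisfy 0 < short < long")

    def _trial(dur_s: float, trial_type: str, correct: Optional[str]) -> TrialTimeline:
        dur = int(round(dur_s * steps_per_second))
        window = int(round(choice_window_s * steps_per_second))
        return TrialTimeline(
            duration_steps=dur + window,
            cue_onsets={"cue": 0},
            trial_type=trial_type,
            response_window=(dur, dur + window),
            correct_action=correct,
            reward_magnitude=reward_magnitude,
            probe_duration_s=dur_s if trial_type == "bisection_probe" else None,
        )

    n_probe = int(round(probe_fraction * n_trials)) if n_probe_durations else 0
    n_train = n_trials - n_probe
    train = [_trial(short_s, "train", "short")] * (n_train - n_train // 2) + [
        _trial(long_s, "train", "long")
    ] * (n_train // 2)
    probes: List[TrialTimeline] = []
    if n_probe_durations:
        durs = bisection_probe_durations(short_s, long_s, n_probe_durations)
        for i in range(n_probe):
            probes.append(_trial(float(durs[i % len(durs)]), "bisection_probe", None))
    return _interleave(train, probes, seed)
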