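"""Temporal feature representations for TD models of conditioning and timing.

Two time representations are provided, both triggered by stimulus onsets:

* **CSC** (complete serial compound): a perfect clock.  Every time step
  following stimulus onset is its own one-hot feature, so the value function
  can express arbitrary time courses but generalizes nothing across time.

* **Microstimuli**: each stimulus leaves a memory trace ``y_t`` that is set
  to 1 at onset and decays exponentially (``y_t = rho**t``, default
  ``rho = 0.985`` per step).  A bank of Gaussian temporal receptive fields
  with centers ``d/D`` (``d = 1..D``) reads out the trace,

      x_t(d) = y_t * phi((y_t - d/D) / sigma),

  where ``phi`` is the standard normal density.  Because the trace decays
  toward 0, receptive fields with centers near 1 are active *early* after
  stimulus onset and fields with centers near 0 are active *late*; late
  microstimuli are temporally broader (coarser timing), which is what gives
  the representation its scalar-timing flavour.

Both cues and rewards elicit their own block of features; a trial's feature
vector is the concatenation of the per-stimulus blocks (cue blocks in sorted
stimulus-id order, then the reward block).

Dopamine manipulations are modelled as multiplicative gain profiles on the
microstimulus blocks: features with centers ``d/D >= theta`` (the early,
striatally-represented microstimuli) are scaled by ``gain_early`` and the
rest by ``gain_late``.  ``gain_early < 1`` emulates D2 antagonism / low
striatal dopamine, ``gain_early > 1`` emulates agonists.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "BasisConfig",
    "GainProfile",
    "trace_strength",
    "microstimulus_features",
    "csc_features",
    "gain_vector",
    "assemble_features",
    "FeatureMap",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Sentinel for "the stimulus has not (yet) occurred".
ABSENT = None


@dataclass(frozen=True)
class BasisConfig:
    """Parameters of the temporal feature representation.

    Parameters
    ----------
    kind : {"microstimulus", "csc"}
        Which representation to generate.
    n_features : int or None
        Number of microstimuli per stimulus (``D``), or the CSC horizon in
        steps.  ``None`` is allowed for the CSC and means "use the trial
        duration as the horizon".
    sigma : float
        Width of each microstimulus receptive field on the trace axis.
    rho : float
        Per-step exponential decay of the memory trace, in (0, 1).
    steps_per_second : int
        Temporal discretization; 20 steps are treated as one second.
    """

    kind: str = "microstimulus"
    n_features: Optional[int] = 50
    sigma: float = 0.08
    rho: float = 0.985
    steps_per_second: int = 20

    def __post_init__(self) -> None:
        if self.kind not in ("microstimulus", "csc"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.n_features is None and self.kind != "csc":
            raise ValueError("n_features may be None only for the CSC basis")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (0, 1)")
        if self.steps_per_second < 1:
            raise ValueError("steps_per_second must be >= 1")

    def seconds_to_steps(self, seconds: float) -> int:
        """Convert a duration in seconds to (rounded) integer steps."""
        return int(round(seconds * self.steps_per_second))

    def block_size(self, duration_steps: int) -> int:
        """Per-stimulus feature-block length for a trial of given duration."""
        if self.kind == "csc" and self.n_features is None:
            return int(duration_steps)
        return int(self.n_features)


@dataclass(frozen=True)
class GainProfile:
    """Multiplicative dopamine-manipulation gains on a microstimulus block.

    Features with receptive-field centers ``d/D >= theta`` (the early,
    post-onset microstimuli) are multiplied by ``gain_early``; the remaining
    (late) features by ``gain_late``.  The identity profile leaves the
    representation untouched.
    """

    theta: float = 0.5
    gain_early: float = 1.0
    gain_late: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.gain_early < 0 or self.gain_late < 0:
            raise ValueError("gains must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return self.gain_early == 1.0 and self.gain_late == 1.0


def trace_strength(t_since_onset, rho: float):
    """Memory-trace strength ``rho**t`` a given number of steps after onset.

    ``t_since_onset`` may be a scalar, an array, or the sentinel ``None``
    ("stimulus has not occurred"), which yields 0.  Negative lags (before
    onset) also yield 0.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (0, 1)")
    if t_since_onset is ABSENT:
        return 0.0
    t = np.asarray(t_since_onset, dtype=float)
    out = np.where(t >= 0, np.power(rho, np.clip(t, 0, None)), 0.0)
    return float(out) if out.ndim == 0 else out


def microstimulus_features(y: float, n_features: int, sigma: float) -> np.ndarray:
    """Microstimulus block for trace strength ``y``.

    Returns the length-``n_features`` vector
    ``x(d) = y * phi((y - d/D) / sigma)`` with Gaussian-density receptive
    fields centered at ``d/D`` for ``d = 1..D``.  All entries are in
    ``[0, phi(0) ~= 0.3989]`` and the block is identically zero when the
    trace is zero (stimulus absent).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if not 0.0 <= y <= 1.0:
        raise ValueError("trace strength y must lie in [0, 1]")
    centers = np.arange(1, n_features + 1, dtype=float) / n_features
    z = (y - centers) / sigma
    return y * np.exp(-0.5 * z * z) / _SQRT_2PI


def csc_features(t_since_onset, horizon: int) -> np.ndarray:
    """Complete-serial-compound block: one-hot in time-since-onset.

    Entry ``k`` (0-based) is 1 iff ``t_since_onset == k`` and the lag is
    within the horizon; before onset (negative lag or ``None``) and beyond
    the horizon the block is all-zero.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    out = np.zeros(horizon)
    if t_since_onset is ABSENT:
        return out
    t = int(t_since_onset)
    if 0 <= t < horizon:
        out[t] = 1.0
    return out


def gain_vector(profile: GainProfile, n_features: int) -> np.ndarray:
    """Per-feature gains implementing a dopamine manipulation.

    Receptive-field centers ``d/D >= theta`` count as *early* (the trace
    starts at 1 and decays, so centers near 1 are active soon after onset)
    and receive ``gain_early``; the others receive ``gain_late``.
    """
    centers = np.arange(1, n_features + 1, dtype=float) / n_features
    return np.where(centers >= profile.theta, profile.gain_early, profile.gain_late)


def _stimulus_order(timeline) -> list:
    """Fixed block order: cue ids sorted, then the reward block."""
    return sorted(timeline.cue_onsets) + ["reward"]


def assemble_features(
    timeline,
    t: int,
    config: BasisConfig,
    gains: Optional[Mapping[str, GainProfile]] = None,
) -> np.ndarray:
    """Full feature vector at step ``t`` of a trial.

    Concatenates one block per stimulus (cue blocks in sorted-id order, then
    the reward block), each multiplied entrywise by its gain vector if a
    :class:`GainProfile` is supplied for that stimulus id.  Deterministic
    given its inputs.
    """
    if not 0 <= t < timeline.duration_steps:
        raise ValueError(f"step {t} outside trial duration {timeline.duration_steps}")
    if gains:
        unknown = set(gains) - set(_stimulus_order(timeline))
        if unknown:
            raise KeyError(f"gain profile for unknown stimulus id(s): {sorted(unknown)}")
    size = config.block_size(timeline.duration_steps)
    blocks = []
    for stim in _stimulus_order(timeline):
        onset = timeline.reward_step if stim == "reward" else timeline.cue_onsets[stim]
        lag = ABSENT if onset is None or t < onset else t - onset
        if config.kind == "csc":
            block = csc_features(lag, size)
        else:
            y = trace_strength(lag, config.rho)
            block = microstimulus_features(y, size, config.sigma)
        if gains and stim in gains and not gains[stim].is_identity:
            if config.kind == "csc":
                raise ValueError("gain profiles apply to microstimulus bases only")
            block = block * gain_vector(gains[stim], size)
        blocks.append(block)
    return np.concatenate(blocks)


class FeatureMap:
    """Precomputed per-trial feature matrices for a fixed basis and gains.

    The simulation engines are step loops; recomputing Gaussian receptive
    fields at every step dominates runtime, so this helper builds the
    ``(duration, n_features)`` matrix for a whole trial at once (vectorized
    over steps) and caches cue-only matrices keyed by trial geometry for
    instrumental tasks where the reward time is action-dependent.
    """

    def __init__(
        self,
        config: BasisConfig,
        gains: Optional[Mapping[str, GainProfile]] = None,
    ) -> None:
        self.config = config
        self.gains = dict(gains) if gains else {}
        if self.gains and config.kind == "csc":
            raise ValueError("gain profiles apply to microstimulus bases only")
        self._cue_cache: dict = {}

    # -- layout ----------------------------------------------------------
    def n_features(self, timeline) -> int:
        return len(_stimulus_order(timeline)) * self.config.block_size(
            timeline.duration_steps
        )

    def block_slices(self, timeline) -> dict:
        size = self.config.block_size(timeline.duration_steps)
        return {
            stim: slice(i * size, (i + 1) * size)
            for i, stim in enumerate(_stimulus_order(timeline))
        }

    # -- block generation ------------------------------------------------
    def _block_matrix(self, onset: Optional[int], duration: int, stim: str) -> np.ndarray:
        """(duration, block_size) feature block for one stimulus."""
        cfg = self.config
        size = cfg.block_size(duration)
        out = np.zeros((duration, size))
        if onset is None or onset >= duration:
            return out
        lags = np.arange(duration - onset)
        if cfg.kind == "csc":
            k = lags[lags < size]
            out[onset + k, k] = 1.0
        else:
            y = np.power(cfg.rho, lags)
            centers = np.arange(1, size + 1, dtype=float) / size
            z = (y[:, None] - centers[None, :]) / cfg.sigma
            out[onset:] = y[:, None] * np.exp(-0.5 * z * z) / _SQRT_2PI
            if stim in self.gains and not self.gains[stim].is_identity:
                out[onset:] *= gain_vector(self.gains[stim], size)[None, :]
        return out

    def trial_matrix(self, timeline) -> np.ndarray:
        """Full (duration, n_features) matrix for a fixed-schedule trial."""
        dur = timeline.duration_steps
        cols = []
        for stim in _stimulus_order(timeline):
            onset = (
                timeline.reward_step if stim == "reward" else timeline.cue_onsets[stim]
            )
            cols.append(self._block_matrix(onset, dur, stim))
        return np.hstack(cols)

    def cue_matrix(self, timeline) -> np.ndarray:
        """Like :meth:`trial_matrix` but with the reward block left zero.

        Cached by trial geometry (duration + cue onsets); instrumental tasks
        reuse the same few geometries across thousands of trials.
        """
        key = (timeline.duration_steps, tuple(sorted(timeline.cue_onsets.items())))
        if key not in self._cue_cache:
            dur = timeline.duration_steps
            cols = []
            for stim in _stimulus_order(timeline):
                onset = None if stim == "reward" else timeline.cue_onsets[stim]
                cols.append(self._block_matrix(onset, dur, stim))
            self._cue_cache[key] = np.hstack(cols)
        return self._cue_cache[key]

    def reward_block_rows(self, timeline, onset: int) -> tuple:
        """(slice, matrix) adding a reward block whose onset is ``onset``."""
        dur = timeline.duration_steps
        sl = self.block_slices(timeline)["reward"]
        return sl, self._block_matrix(onset, dur, "reward")
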