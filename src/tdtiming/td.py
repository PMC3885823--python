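"""Linear TD(lambda) critic: value learning and dopamine-like prediction errors.

The critic approximates the discounted return of the current state,
``V(s_t) = E[sum_k gamma^k r_{t+k}]`` (the sum starts at the current reward),
as a linear function of the temporal features, ``V_hat = sum_d w(d) x(d)``.
On every step it computes the prediction error

    delta_t = r_t + gamma * V_hat(s_{t+1}) - V_hat(s_t),

accumulates features into a decaying eligibility trace
``e <- gamma * lambda * e + x_t`` and updates the weights
``w <- w + alpha * delta_t * e`` (online TD(lambda), current weights used for
both value estimates).  ``delta_t`` is the model's stand-in for phasic
dopamine.

Trial structure
---------------
Trials are episodes: eligibility traces start at zero, the value beyond the
last step of a trial is zero, and the long intertrial interval is not
simulated (its features are zero, so no weight changes can occur there).
Each trial is preceded by one synthetic zero-feature *baseline* step,
recorded with step index -1: the prediction error on the transition from
this baseline into the first trial state is the cue-onset dopamine burst
(``gamma * V_hat(onset)``), which otherwise has no step to live on when the
cue starts the trial.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .basis import BasisConfig, FeatureMap, GainProfile
from .tasks import TrialTimeline

__all__ = [
    "LearnerConfig",
    "CriticState",
    "TrialRecord",
    "SessionResult",
    "predict_value",
    "td_error",
    "update_traces",
    "update_weights",
    "run_pavlovian_session",
    "PavlovianTD",
    "PavlovianTDResults",
]


@dataclass(frozen=True)
class LearnerConfig:
    """TD(lambda) hyperparameters: learning rate, discount, trace decay."""

    alpha: float = 0.01
    gamma: float = 0.98
    lam: float = 0.95

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


@dataclass
class CriticState:
    """Value weights and eligibility traces, one entry per feature."""

    weights: np.ndarray
    traces: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.weights.shape != self.traces.shape:
            raise ValueError("weights and traces must have the same shape")

    @classmethod
    def zeros(cls, n_features: int) -> "CriticState":
        return cls(np.zeros(n_features), np.zeros(n_features))


def predict_value(state: CriticState, x: np.ndarray) -> float:
    """Linear value estimate ``sum_d w(d) x(d)``."""
    x = np.asarray(x, dtype=float)
    if x.shape != state.weights.shape:
        raise ValueError(
            f"feature dimension {x.shape} does not match weights {state.weights.shape}"
        )
    return float(state.weights @ x)


def td_error(r: float, v_next: float, v_curr: float, gamma: float) -> float:
    """One-step prediction error ``r + gamma * v_next - v_curr``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return r + gamma * v_next - v_curr


def update_traces(
    state: CriticState, x: np.ndarray, gamma: float, lam: float
) -> CriticState:
    """Decay-and-accumulate eligibility update ``e' = gamma*lam*e + x``."""
    x = np.asarray(x, dtype=float)
    if x.shape != state.traces.shape:
        raise ValueError("feature dimension does not match traces")
    return CriticState(state.weights.copy(), gamma * lam * state.traces + x)


def update_weights(
    state: CriticState, alpha: float, delta: float, traces: np.ndarray
) -> CriticState:
    """Credit-by-eligibility weight update ``w' = w + alpha*delta*e``."""
    if not np.isfinite(delta):
        raise FloatingPointError("non-finite prediction error")
    traces = np.asarray(traces, dtype=float)
    if traces.shape != state.weights.shape:
        raise ValueError("trace dimension does not match weights")
    return CriticState(state.weights + alpha * delta * traces, state.traces.copy())


@dataclass
class TrialRecord:
    """Per-step arrays for one simulated trial.

    ``step`` starts at -1 (the synthetic pre-trial baseline step); the
    record at step t holds the value of state t, the reward collected in
    state t, and ``delta = reward + gamma * value_next - value``.
    """

    trial: int
    trial_type: str
    step: np.ndarray
    value: np.ndarray
    delta: np.ndarray
    reward: np.ndarray
    action: Optional[np.ndarray] = None
    p_respond: Optional[np.ndarray] = None
    reward_step: Optional[int] = None

    def delta_at(self, step: int) -> float:
        """Prediction error recorded at a given step index."""
        idx = int(step) + 1  # records start at step -1
        return float(self.delta[idx])

    def onset_delta(self, onset_step: int = 0) -> float:
        """Prediction error generated by cue onset.

        The burst elicited by a cue lives on the transition *into* the onset
        state, i.e. on the record one step before the onset.
        """
        return self.delta_at(onset_step - 1)


@dataclass
class SessionResult:
    """Full per-step log of a simulated session plus the final learner state."""

    trials: List[TrialRecord]
    weights: np.ndarray
    basis: BasisConfig
    learner: LearnerConfig
    timelines: Sequence[TrialTimeline]
    seed: Optional[int] = None
    preferences: Optional[np.ndarray] = None
    actions: Optional[Sequence[str]] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format log (one row per trial step)."""
        sps = self.basis.steps_per_second
        frames = []
        for rec in self.trials:
            d = {
                "trial": rec.trial,
                "trial_type": rec.trial_type,
                "step": rec.step,
                "time_s": rec.step / sps,
                "value": rec.value,
                "delta": rec.delta,
                "reward": rec.reward,
            }
            if rec.action is not None and self.actions is not None:
                labels = np.asarray(list(self.actions) + [""], dtype=object)
                d["action"] = labels[rec.action]
                d["p_respond"] = rec.p_respond
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)


def _trial_loop(
    X: np.ndarray,
    rewards: np.ndarray,
    w: np.ndarray,
    learner: LearnerConfig,
    learn: bool = True,
) -> tuple:
    """Online TD(lambda) over one trial with a precomputed feature matrix.

    Returns (value, delta) arrays of length ``duration + 1`` whose first
    entry is the pre-trial baseline step.  The terminal value beyond the
    last step is zero.
    """
    gamma, lam, alpha = learner.gamma, learner.lam, learner.alpha
    dur = X.shape[0]
    e = np.zeros_like(w)
    values = np.empty(dur + 1)
    deltas = np.empty(dur + 1)
    # Baseline step: zero features, zero value; its delta is the onset burst.
    v_next = float(w @ X[0])
    values[0] = 0.0
    deltas[0] = gamma * v_next  # r=0, v_curr=0; traces are zero, no update
    for t in range(dur):
        v_t = float(w @ X[t])
        v_tp1 = float(w @ X[t + 1]) if t + 1 < dur else 0.0
        delta = rewards[t] + gamma * v_tp1 - v_t
        values[t + 1] = v_t
        deltas[t + 1] = delta
        if learn:
            e *= gamma * lam
            e += X[t]
            w += (alpha * delta) * e
    return values, deltas


def run_pavlovian_session(
    timelines: Sequence[TrialTimeline],
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    gains: Optional[Mapping[str, GainProfile]] = None,
    weights: Optional[np.ndarray] = None,
    learn: bool = True,
    seed: Optional[int] = None,
) -> SessionResult:
    """Simulate Pavlovian conditioning trials with online TD(lambda).

    The schedule is fully deterministic; ``seed`` is recorded for
    provenance only.  Pass ``weights`` to continue from a trained critic and
    ``learn=False`` to freeze it (probe read-outs).
    """
    basis = basis or BasisConfig()
    learner = learner or LearnerConfig()
    if len(timelines) == 0:
        return SessionResult([], np.zeros(0), basis, learner, timelines, seed)
    fmap = FeatureMap(basis, gains)
    n_feat = fmap.n_features(timelines[0])
    w = np.zeros(n_feat) if weights is None else np.array(weights, dtype=float)
    if w.shape != (n_feat,):
        raise ValueError("weights do not match the feature dimension")
    records = []
    for i, tl in enumerate(timelines):
        if fmap.n_features(tl) != n_feat:
            raise ValueError("all trials in a session must share one feature space")
        X = fmap.trial_matrix(tl)
        rewards = np.zeros(tl.duration_steps)
        if tl.reward_step is not None:
            rewards[tl.reward_step] = tl.reward_magnitude
        values, deltas = _trial_loop(X, rewards, w, learner, learn=learn)
        records.append(
            TrialRecord(
                trial=i,
                trial_type=tl.trial_type,
                step=np.arange(-1, tl.duration_steps),
                value=values,
                delta=deltas,
                reward=np.concatenate(([0.0], rewards)),
                reward_step=tl.reward_step,
            )
        )
    return SessionResult(records, w, basis, learner, timelines, seed)


class PavlovianTD:
    """TD(lambda) critic trained on a Pavlovian trial schedule.

    Model object in the statsmodels style: construction binds the task
    (trial timelines) and configuration; :meth:`fit` runs the learning
    simulation and returns a :class:`PavlovianTDResults`.

    Parameters
    ----------
    timelines : sequence of TrialTimeline
        The trial schedule, e.g. from :func:`tdtiming.tasks.make_pavlovian_task`.
    basis, learner : optional
        Feature representation and TD hyperparameters (defaults: 50
        microstimuli, sigma=0.08, rho=0.985, 20 steps/s; alpha=0.01,
        gamma=0.98, lambda=0.95).
    gains : mapping stimulus-id -> GainProfile, optional
        Dopamine-manipulation gain profiles applied to the features.
    """

    def __init__(
        self,
        timelines: Sequence[TrialTimeline],
        basis: Optional[BasisConfig] = None,
        learner: Optional[LearnerConfig] = None,
        gains: Optional[Mapping[str, GainProfile]] = None,
    ) -> None:
        self.timelines = list(timelines)
        self.basis = basis or BasisConfig()
        self.learner = learner or LearnerConfig()
        self.gains = dict(gains) if gains else {}

    def fit(
        self,
        seed: Optional[int] = None,
        start_weights: Optional[np.ndarray] = None,
    ) -> "PavlovianTDResults":
        session = run_pavlovian_session(
            self.timelines,
            self.basis,
            self.learner,
            gains=self.gains or None,
            weights=start_weights,
            seed=seed,
        )
        return PavlovianTDResults(self, session)


class PavlovianTDResults:
    """Learned critic plus the full training log."""

    def __init__(self, model: PavlovianTD, session: SessionResult) -> None:
        self.model = model
        self.session = session
        self.weights = session.weights

    @property
    def params(self) -> np.ndarray:
        return self.weights

    def value_curve(self, timeline: Optional[TrialTimeline] = None) -> np.ndarray:
        """Learned value V_hat(t) over the steps of a trial (frozen weights)."""
        tl = timeline or self.model.timelines[-1]
        fmap = FeatureMap(self.model.basis, self.model.gains or None)
        return fmap.trial_matrix(tl) @ self.weights

    def probe(
        self,
        timelines: Sequence[TrialTimeline],
        learn: bool = False,
        gains: Optional[Mapping[str, GainProfile]] = None,
    ) -> SessionResult:
        """Run probe trials from the trained weights (frozen by default)."""
        return run_pavlovian_session(
            timelines,
            self.model.basis,
            self.model.learner,
            gains=gains if gains is not None else (self.model.gains or None),
            weights=self.weights.copy(),
            learn=learn,
        )

    def final_trial(self) -> TrialRecord:
        return self.session.trials[-1]

    def to_frame(self) -> pd.DataFrame:
        return self.session.to_frame()

    def summary(self) -> str:
        last = self.final_trial()
        lines = [
            "Pavlovian TD(lambda) critic",
            "===========================",
            f"basis: {self.model.basis.kind}, D={self.model.basis.n_features}, "
            f"sigma={self.model.basis.sigma}, rho={self.model.basis.rho}",
            f"learner: alpha={self.model.learner.alpha}, "
            f"gamma={self.model.learner.gamma}, lambda={self.model.learner.lam}",
            f"trials: {self.session.n_trials}",
            f"final-trial cue-onset delta:  {last.onset_delta():+.4f}",
        ]
        if last.reward_step is not None:
            lines.append(
                f"final-trial reward-time delta: {last.delta_at(last.reward_step):+.4f}"
            )
        return "\n".join(lines)
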