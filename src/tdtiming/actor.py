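"""Softmax actor with prediction-error-modulated policy learning.

The actor turns the critic into a full actor-critic architecture for
instrumental timing tasks.  Action preferences are linear in the same
temporal features the critic uses, ``f(a) = sum_d u(a, d) x(d)``, and
actions are chosen by softmax, ``p(a) ∝ exp{f(a)}``.  After each step the
preference of the *taken* action is moved by the critic's prediction error:

    u(a_t, d) += eta * delta_t * (1 - p(a_t)) * x_t(d).

Rewards are response-contingent: in the peak procedure the first "respond"
at or after the fixed interval triggers reward in the same time step, so
``delta_t`` contains the consequence of ``a_t`` and the update credits the
action that caused it.  With one-hot (tabular) features the update reduces
to the scalar preference rule; with microstimuli it generalizes across
nearby times, which is what produces temporally graded responding.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .basis import BasisConfig, FeatureMap, GainProfile
from .tasks import TrialTimeline
from .td import LearnerConfig, SessionResult, TrialRecord

__all__ = [
    "ActorConfig",
    "PolicyState",
    "action_probabilities",
    "sample_action",
    "update_policy",
    "run_instrumental_session",
    "TimingActorCritic",
    "TimingActorCriticResults",
]


@dataclass(frozen=True)
class ActorConfig:
    """Actor hyperparameters: learning rate and the available action set."""

    eta: float = 0.5
    actions: Tuple[str, ...] = ("respond", "withhold")

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be > 0")
        if len(self.actions) < 2:
            raise ValueError("need at least 2 actions")
        if len(set(self.actions)) != len(self.actions):
            raise ValueError("duplicate action labels")


@dataclass
class PolicyState:
    """Per-action linear preference weights, shape (n_actions, n_features)."""

    preferences: np.ndarray

    def __post_init__(self) -> None:
        self.preferences = np.asarray(self.preferences, dtype=float)
        if self.preferences.ndim != 2:
            raise ValueError("preferences must be 2-D (actions x features)")

    @classmethod
    def zeros(cls, n_actions: int, n_features: int) -> "PolicyState":
        return cls(np.zeros((n_actions, n_features)))


def action_probabilities(policy: PolicyState, x: np.ndarray) -> np.ndarray:
    """Softmax action probabilities from linear preferences.

    Numerically guarded by max-subtraction; invariant to adding a constant
    to every preference.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != policy.preferences.shape[1]:
        raise ValueError("feature dimension does not match preferences")
    f = policy.preferences @ x
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite action preference")
    f = f - f.max()
    p = np.exp(f)
    return p / p.sum()


def sample_action(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw; returns the index of the chosen action."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("invalid probability vector")
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right").clip(0, len(probs) - 1))


def update_policy(
    policy: PolicyState,
    action_taken: int,
    prob_taken: float,
    delta: float,
    x: np.ndarray,
    eta: float,
) -> PolicyState:
    """Preference update for the taken action only (others unchanged)."""
    if not 0.0 < prob_taken <= 1.0:
        raise ValueError("prob_taken must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    if x.shape[0] != policy.preferences.shape[1]:
        raise ValueError("feature dimension does not match preferences")
    prefs = policy.preferences.copy()
    prefs[action_taken] += eta * delta * (1.0 - prob_taken) * x
    return PolicyState(prefs)


def _respond_index(actor: ActorConfig) -> int:
    try:
        return actor.actions.index("respond")
    except ValueError:
        return 0


def run_instrumental_session(
    timelines: Sequence[TrialTimeline],
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    actor: Optional[ActorConfig] = None,
    seed: Optional[int] = None,
    gains: Optional[Mapping[str, GainProfile]] = None,
    weights: Optional[np.ndarray] = None,
    preferences: Optional[np.ndarray] = None,
    learn: bool = True,
) -> SessionResult:
    """Simulate an instrumental (actor-critic) session.

    Per step: assemble features, sample an action, evaluate the trial's
    reinforcement contingency, compute the prediction error, then update
    critic (traces + weights) and actor (taken action's preferences).
    Contingencies:

    * ``fi_steps`` set (peak procedure): the first "respond" at or after
      the interval on a reinforced trial delivers the reward in that step
      and terminates the trial; probe trials never deliver reward.
    * ``response_window`` set (bisection): actions are only sampled inside
      the window; the first non-"withhold" choice terminates the trial and
      is rewarded if it matches ``correct_action`` on a reinforced trial.

    Set ``learn=False`` (with trained ``weights``/``preferences``) to run
    frozen test sessions, e.g. acute dopamine-manipulation probes via
    ``gains``.
    """
    basis = basis or BasisConfig()
    learner = learner or LearnerConfig()
    actor = actor or ActorConfig()
    rng = np.random.default_rng(seed)
    if len(timelines) == 0:
        return SessionResult(
            [], np.zeros(0), basis, learner, timelines, seed,
            preferences=np.zeros((len(actor.actions), 0)), actions=actor.actions,
        )
    fmap = FeatureMap(basis, gains)
    n_feat = fmap.n_features(timelines[0])
    n_act = len(actor.actions)
    w = np.zeros(n_feat) if weights is None else np.array(weights, dtype=float)
    U = (
        np.zeros((n_act, n_feat))
        if preferences is None
        else np.array(preferences, dtype=float)
    )
    if w.shape != (n_feat,) or U.shape != (n_act, n_feat):
        raise ValueError("weights/preferences do not match the feature space")
    i_respond = _respond_index(actor)
    choice_idx = [i for i, a in enumerate(actor.actions) if a != "withhold"]
    gamma, lam, alpha, eta = learner.gamma, learner.lam, learner.alpha, actor.eta
    records: List[TrialRecord] = []

    for i, tl in enumerate(timelines):
        if tl.correct_action is not None and tl.correct_action not in actor.actions:
            raise ValueError(
                f"contingency references unknown action {tl.correct_action!r}"
            )
        dur = tl.duration_steps
        Xc = fmap.cue_matrix(tl)
        reward_sl = fmap.block_slices(tl)["reward"]
        reward_rows = None  # lazily added if a reward is actually delivered
        reinforced = tl.trial_type == "train"
        window = tl.response_window
        e = np.zeros(n_feat)
        steps = np.empty(dur + 1, dtype=int)
        values = np.empty(dur + 1)
        deltas = np.empty(dur + 1)
        rewards = np.zeros(dur + 1)
        acts = np.full(dur + 1, n_act, dtype=int)  # n_act == "no action" code
        p_resp = np.full(dur + 1, np.nan)
        steps[:] = np.arange(-1, dur)

        def x_at(t: int) -> np.ndarray:
            x = Xc[t]
            if reward_rows is not None:
                x = x.copy()
                x[reward_sl] = reward_rows[t]
            return x

        # pre-trial baseline step (zero features): onset burst, no update
        values[0] = 0.0
        deltas[0] = gamma * float(w @ x_at(0))
        terminated = False
        t_end = dur
        for t in range(dur):
            x_t = x_at(t)
            v_t = float(w @ x_t)
            # --- action selection and contingency -----------------------
            a_t = None
            p_t = None
            r_t = 0.0
            may_act = window is None or (window[0] <= t < window[1])
            if may_act:
                p_t = action_probabilities(PolicyState(U), x_t)
                a_t = sample_action(p_t, rng)
                label = actor.actions[a_t]
                if tl.fi_steps is not None and label == "respond" and t >= tl.fi_steps:
                    if reinforced:
                        r_t = tl.reward_magnitude
                        _, rb = fmap.reward_block_rows(tl, t)
                        reward_rows = rb
                    terminated = True
                elif window is not None and label != "withhold":
                    if reinforced and label == tl.correct_action:
                        r_t = tl.reward_magnitude
                    terminated = True
            # --- prediction error --------------------------------------
            if terminated or t + 1 == dur:
                v_tp1 = 0.0
            else:
                v_tp1 = float(w @ x_at(t + 1))
            delta = r_t + gamma * v_tp1 - v_t
            values[t + 1] = v_t
            deltas[t + 1] = delta
            rewards[t + 1] = r_t
            if a_t is not None:
                acts[t + 1] = a_t
                p_resp[t + 1] = p_t[i_respond]
            # --- learning ----------------------------------------------
            if learn:
                e *= gamma * lam
                e += x_t
                w += (alpha * delta) * e
                if a_t is not None:
                    U[a_t] += eta * delta * (1.0 - p_t[a_t]) * x_t
            if terminated:
                t_end = t + 1
                break
        k = t_end + 1
        records.append(
            TrialRecord(
                trial=i,
                trial_type=tl.trial_type,
                step=steps[:k],
                value=values[:k],
                delta=deltas[:k],
                reward=rewards[:k],
                action=acts[:k],
                p_respond=p_resp[:k],
                reward_step=None,
            )
        )
    return SessionResult(
        records, w, basis, learner, timelines, seed,
        preferences=U, actions=actor.actions,
    )


class TimingActorCritic:
    """Actor-critic model of instrumental interval timing.

    Construction binds a trial schedule (peak procedure or bisection, from
    :mod:`tdtiming.tasks`) and the basis/learner/actor configurations;
    :meth:`fit` trains the agent and returns a
    :class:`TimingActorCriticResults` from which response curves,
    peak statistics, psychometric functions and acute dopamine-manipulation
    test sessions can be derived.
    """

    def __init__(
        self,
        timelines: Sequence[TrialTimeline],
        basis: Optional[BasisConfig] = None,
        learner: Optional[LearnerConfig] = None,
        actor: Optional[ActorConfig] = None,
        gains: Optional[Mapping[str, GainProfile]] = None,
    ) -> None:
        self.timelines = list(timelines)
        self.basis = basis or BasisConfig()
        self.learner = learner or LearnerConfig()
        self.actor = actor or ActorConfig()
        self.gains = dict(gains) if gains else {}

    def fit(self, seed: Optional[int] = None) -> "TimingActorCriticResults":
        session = run_instrumental_session(
            self.timelines,
            self.basis,
            self.learner,
            self.actor,
            seed=seed,
            gains=self.gains or None,
        )
        return TimingActorCriticResults(self, session)


class TimingActorCriticResults:
    """Trained actor-critic agent plus the full session log."""

    def __init__(self, model: TimingActorCritic, session: SessionResult) -> None:
        self.model = model
        self.session = session
        self.weights = session.weights
        self.preferences = session.preferences

    def to_frame(self) -> pd.DataFrame:
        return self.session.to_frame()

    def test_session(
        self,
        timelines: Sequence[TrialTimeline],
        seed: Optional[int] = None,
        gains: Optional[Mapping[str, GainProfile]] = None,
    ) -> SessionResult:
        """Frozen-learning test session from the trained agent.

        This is the acute dopamine-manipulation protocol: the agent is
        trained drug-free and then probed with a :class:`GainProfile`
        applied to its features, learning switched off.
        """
        return run_instrumental_session(
            timelines,
            self.model.basis,
            self.model.learner,
            self.model.actor,
            seed=seed,
            gains=gains if gains is not None else (self.model.gains or None),
            weights=self.weights.copy(),
            preferences=self.preferences.copy(),
            learn=False,
        )

    def response_curve(self, bin_s: float = 1.0, trial_type: str = "peak_probe"):
        from .analysis import response_curve

        return response_curve(self.session, bin_s=bin_s, trial_filter=trial_type)

    def peak_statistics(self, bin_s: float = 1.0):
        from .analysis import peak_statistics

        return peak_statistics(self.response_curve(bin_s=bin_s))

    def psychometric(self):
        from .analysis import psychometric

        return psychometric(self.session)

    def summary(self) -> str:
        n_probe = sum(
            1 for r in self.session.trials if r.trial_type.endswith("probe")
        )
        lines = [
            "Actor-critic interval-timing model",
            "==================================",
            f"basis: {self.model.basis.kind}, D={self.model.basis.n_features}, "
            f"sigma={self.model.basis.sigma}, rho={self.model.basis.rho:.6g}",
            f"learner: alpha={self.model.learner.alpha}, gamma={self.model.learner.gamma}, "
            f"lambda={self.model.learner.lam}; actor eta={self.model.actor.eta}",
            f"trials: {self.session.n_trials} ({n_probe} probes)",
        ]
        try:
            stats = self.peak_statistics()
            lines.append(
                f"probe response curve: peak {stats.peak_time_s:.2f} s, "
                f"spread {stats.spread_s:.2f} s (R^2={stats.fit_quality:.3f})"
            )
        except Exception:
            pass
        return "\n".join(lines)
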