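"""High-level experiment recipes.

Each function wires tasks, basis, learner and actor into one of the
package's standard simulations and returns tidy result objects/tables.
These are the units the command-line interface and the reproduction
script call into.

Default parameters follow the conditioning simulation conventions used
throughout: alpha=0.01, gamma=0.98, lambda=0.95, D=50 microstimuli,
sigma=0.08, trace decay rho=0.985, 20 steps per second, 500-step
intertrial intervals, 100 conditioning trials.
"""
from __future__ import annotations

import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .actor import ActorConfig, TimingActorCritic, TimingActorCriticResults
from .analysis import (
    PeakStats,
    PsychometricResult,
    event_pe_summary,
    peak_statistics,
    response_curve,
    psychometric,
)
from .basis import BasisConfig, GainProfile
from .semimarkov import RectifiedPEConfig, interval_scaling_experiment
from .tasks import make_bisection_task, make_pavlovian_task, make_peak_task, make_probe_trial
from .td import LearnerConfig, PavlovianTD

__all__ = [
    "SWEEP_INTERVALS_S",
    "behavioral_rho",
    "interval_sweep",
    "csc_convergence",
    "probe_comparison",
    "peak_experiment",
    "manipulation_experiment",
    "bisection_experiment",
    "rectified_pe_table",
]

#: Cue-reward intervals of the dopamine interval-sweep simulation (doubling
#: series spanning 1-16 s).
SWEEP_INTERVALS_S: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)


def behavioral_rho(interval_s: float, steps_per_second: int = 20) -> float:
    """Trace decay for instrumental timing tasks: half-life at the interval.

    The conditioning default rho=0.985 leaves essentially no memory trace
    at a 20-40 s criterion time, so instrumental experiments scale the
    trace to the task: rho is chosen so the trace has decayed to 1/2 at the
    trained interval.  With the default theta=0.5 gain boundary this also
    places the early/late (striatal/extrastriatal) split at the criterion
    time, and it rescales the whole representation proportionally with the
    interval (a built-in scalar-timing property).
    """
    steps = interval_s * steps_per_second
    return float(0.5 ** (1.0 / steps))


def interval_sweep(
    intervals_s: Sequence[float] = SWEEP_INTERVALS_S,
    n_trials: int = 100,
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    k_last: int = 1,
    keep_sessions: bool = False,
):
    """Cue/reward prediction errors as a function of cue-reward interval.

    Trains an independent microstimulus TD critic per interval (100 trials
    each by default) and reads out the final-trial prediction error at cue
    onset and at the reward time.  Reproduces the pattern that the reward
    response grows, and the cue response shrinks, with the interval.
    """
    basis = basis or BasisConfig()
    learner = learner or LearnerConfig()
    sessions = []
    for T in intervals_s:
        tls = make_pavlovian_task(T, n_trials, steps_per_second=basis.steps_per_second)
        res = PavlovianTD(tls, basis=basis, learner=learner).fit()
        sessions.append((T, res.session))
    rows = event_pe_summary(sessions, k_last=k_last)
    df = pd.DataFrame(
        {
            "interval_s": [r.interval_s for r in rows],
            "cue_delta": [r.cue_delta for r in rows],
            "reward_delta": [r.reward_delta for r in rows],
        }
    )
    if keep_sessions:
        return df, sessions
    return df


def csc_convergence(
    interval_s: float = 2.0,
    n_trials: int = 500,
    alpha: float = 0.1,
    gamma: float = 0.98,
    lam: float = 0.95,
    steps_per_second: int = 20,
) -> Dict[str, float]:
    """Analytic-oracle check: CSC TD on a deterministic chain.

    With a perfect clock and a deterministic cue->reward interval T, TD
    converges to V(t) = gamma**(T - t) * r; returns the sup-norm deviation
    from that closed form over the pre-reward steps and the residual
    prediction error at the reward time.
    """
    tls = make_pavlovian_task(interval_s, n_trials, steps_per_second=steps_per_second)
    basis = BasisConfig(kind="csc", n_features=None, steps_per_second=steps_per_second)
    res = PavlovianTD(
        tls, basis=basis, learner=LearnerConfig(alpha=alpha, gamma=gamma, lam=lam)
    ).fit()
    T = tls[0].reward_step
    values = res.value_curve()[: T + 1]
    analytic = gamma ** (T - np.arange(T + 1)) * tls[0].reward_magnitude
    last = res.final_trial()
    return {
        "interval_s": interval_s,
        "sup_norm": float(np.max(np.abs(values - analytic))),
        "reward_delta": float(last.delta_at(T)),
        "n_trials": n_trials,
    }


def probe_comparison(
    interval_s: float = 2.0,
    n_trials: int = 500,
    early_shift_s: float = 0.5,
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    csc_alpha: float = 0.1,
) -> Dict[str, object]:
    """Early-reward and omission probes: microstimulus vs. CSC critics.

    Trains both representations on the same fixed-interval schedule, then
    probes with (i) reward delivered ``early_shift_s`` early and (ii)
    reward omitted.  Returns the prediction errors at the usual reward
    time plus the full post-interval omission transients, quantifying the
    two classic CSC failures: the microstimulus critic produces a
    negligible error at the usual time after an early reward, and a
    temporally extended, low-amplitude omission dip instead of the CSC's
    punctate one.
    """
    basis = basis or BasisConfig()
    learner = learner or LearnerConfig()
    sps = basis.steps_per_second
    tls = make_pavlovian_task(interval_s, n_trials, steps_per_second=sps)
    T = tls[0].reward_step
    ms = PavlovianTD(tls, basis=basis, learner=learner).fit()
    csc = PavlovianTD(
        tls,
        basis=BasisConfig(kind="csc", n_features=None, steps_per_second=sps),
        learner=LearnerConfig(alpha=csc_alpha, gamma=learner.gamma, lam=learner.lam),
    ).fit()
    early = make_probe_trial(tls[0], "probe_early", shift_s=early_shift_s,
                             steps_per_second=sps)
    omit = make_probe_trial(tls[0], "probe_omission", steps_per_second=sps)
    ms_early = ms.probe([early]).trials[0]
    ms_omit = ms.probe([omit]).trials[0]
    csc_omit = csc.probe([omit]).trials[0]
    post = range(T, omit.duration_steps)
    return {
        "usual_reward_step": T,
        "ms_early_delta_at_usual": ms_early.delta_at(T),
        "ms_omission_deltas": np.array([ms_omit.delta_at(t) for t in post]),
        "csc_omission_delta_at_usual": csc_omit.delta_at(T),
        "csc_omission_deltas": np.array([csc_omit.delta_at(t) for t in post]),
    }


def _peak_model(
    fi_s: float,
    n_trials: int,
    probe_fraction: float,
    seed: Optional[int],
    basis: Optional[BasisConfig],
    learner: Optional[LearnerConfig],
    actor: Optional[ActorConfig],
) -> TimingActorCritic:
    basis = basis or BasisConfig(rho=behavioral_rho(fi_s))
    tls = make_peak_task(
        fi_s,
        n_trials,
        probe_fraction=probe_fraction,
        steps_per_second=basis.steps_per_second,
        seed=seed,
    )
    return TimingActorCritic(tls, basis=basis, learner=learner, actor=actor)


def peak_experiment(
    fi_s: float = 20.0,
    n_trials: int = 2000,
    probe_fraction: float = 0.25,
    seed: int = 0,
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    actor: Optional[ActorConfig] = None,
    bin_s: float = 1.0,
) -> Tuple[TimingActorCriticResults, PeakStats]:
    """Train the actor-critic on the peak procedure and fit the peak.

    Returns the fitted results object and the Gaussian peak statistics of
    the probe-trial response curve.
    """
    model = _peak_model(fi_s, n_trials, probe_fraction, seed, basis, learner, actor)
    res = model.fit(seed=seed + 1)
    return res, res.peak_statistics(bin_s=bin_s)


def manipulation_experiment(
    fi_s: float = 20.0,
    gain_early_values: Sequence[float] = (0.5, 1.0, 2.0),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_trials: int = 2000,
    n_test_probes: int = 150,
    theta: float = 0.5,
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    actor: Optional[ActorConfig] = None,
) -> pd.DataFrame:
    """Acute dopamine manipulations on the trained peak-procedure agent.

    For each seed the agent is trained drug-free, then probed (learning
    frozen) under each early-microstimulus gain: gain < 1 models D2
    antagonism / low striatal dopamine, gain > 1 agonists.  Returns one row
    per (seed, gain) with the fitted peak time of the test response curve.
    """
    rows = []
    for seed in seeds:
        model = _peak_model(fi_s, n_trials, 0.25, seed, basis, learner, actor)
        res = model.fit(seed=seed + 1)
        test_tls = make_peak_task(
            fi_s,
            n_test_probes,
            probe_fraction=1.0,
            steps_per_second=model.basis.steps_per_second,
            seed=seed + 1000,
        )
        for g in gain_early_values:
            gains = (
                None
                if g == 1.0
                else {"cue": GainProfile(theta=theta, gain_early=g)}
            )
            sess = res.test_session(test_tls, seed=seed + 2000, gains=gains)
            stats = peak_statistics(response_curve(sess))
            rows.append(
                {
                    "seed": seed,
                    "gain_early": g,
                    "peak_time_s": stats.peak_time_s,
                    "spread_s": stats.spread_s,
                    "fit_r2": stats.fit_quality,
                }
            )
    return pd.DataFrame(rows)


def bisection_experiment(
    short_s: float = 2.0,
    long_s: float = 8.0,
    n_probe_durations: int = 7,
    n_trials: int = 2000,
    seed: int = 0,
    basis: Optional[BasisConfig] = None,
    learner: Optional[LearnerConfig] = None,
    actor: Optional[ActorConfig] = None,
) -> Tuple[TimingActorCriticResults, PsychometricResult]:
    """Train on temporal bisection and extract the psychometric function.

    The default trace decay follows the behavioral scaling rule with the
    trained interval taken to be the geometric mean of the anchors, so the
    representation spans the anchor range evenly.
    """
    basis = basis or BasisConfig(rho=behavioral_rho(math.sqrt(short_s * long_s)))
    actor = actor or ActorConfig(actions=("short", "long", "withhold"))
    tls = make_bisection_task(
        short_s,
        long_s,
        n_probe_durations,
        n_trials,
        steps_per_second=basis.steps_per_second,
        seed=seed,
    )
    res = TimingActorCritic(tls, basis=basis, learner=learner, actor=actor).fit(
        seed=seed + 1
    )
    return res, res.psychometric()


def rectified_pe_table(
    intervals_s: Sequence[float] = (1.0, 4.0, 16.0),
    cfg: Optional[RectifiedPEConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Interval scaling of rectified scalar-noise prediction errors."""
    cfg = cfg or RectifiedPEConfig(seed=seed)
    if seed is not None and cfg.seed != seed:
        cfg = RectifiedPEConfig(
            weber_k=cfg.weber_k, exponent_p=cfg.exponent_p, floor_c=cfg.floor_c,
            n_samples=cfg.n_samples, seed=seed,
        )
    return interval_scaling_experiment(list(intervals_s), cfg)
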