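# Methods

`tdtiming` simulates a single reinforcement-learning system — a linear
TD(λ) critic with a temporal feature representation, optionally paired
with a softmax actor — and asks it to reproduce two families of phenomena
at once: the timing of phasic dopamine-like prediction errors in Pavlovian
conditioning, and timed instrumental behaviour (peak procedure, temporal
bisection) together with the behavioural effects of dopamine
manipulations. A separate, deliberately minimal module covers the
rectified scalar-noise account of interval-dependent dopamine averages.

## Model

**States and features.** Time is discretized at 20 steps/s (one step =
50 ms). Each stimulus (cue, reward) triggers a feature block at its onset.
Two representations are available:

* *CSC* — one indicator feature per post-onset step: a perfect clock.
* *Microstimuli* — the stimulus leaves a trace `y_t = ρ^t` (default
  ρ = 0.985 per step) read out by `D = 50` Gaussian receptive fields with
  centers `d/D`, `d = 1..D`, and width σ = 0.08:

      x_t(d) = y_t · φ((y_t − d/D)/σ),   φ = standard normal density.

  The printed form of this equation in the source literature is
  typographically ambiguous about the normalizing prefactor; we adopt the
  plain Gaussian density with no 1/σ factor, since any constant scale on
  the features is absorbed by the learning rate. Receptive-field centers
  start at d/D = 1/D (none at zero). Fields centered near 1 are active
  *early* after onset; fields centered near 0 are active *late* and are
  temporally broader — the representation's built-in scalar-timing
  property.

**Critic.** Value is linear in the features, `V̂(s) = Σ_d w(d) x(d)`, and
is the *inclusive* discounted return `V(s_t) = E[Σ_{k≥0} γ^k r_{t+k}]`
(the sum includes the reward collected in the current state). Learning is
online TD(λ):

    δ_t = r_t + γ V̂(s_{t+1}) − V̂(s_t)
    e ← γλ e + x_t            (before the weight update)
    w ← w + α δ_t e

Defaults: α = 0.01, γ = 0.98, λ = 0.95. Under the inclusive convention a
deterministic cue→reward chain has the fixed point `V(t) = γ^(T−t) r`
with δ = 0 everywhere, which the CSC critic attains to < 0.01 sup-norm in
500 trials at α = 0.1 (the convergence-experiment learning rate; the
conditioning default α = 0.01 is kept for phenomenon simulations where
partial training is itself the point).

**Trial structure.** Trials are episodes: eligibility traces start at
zero, the value beyond the final step is zero, and the 500-step
intertrial interval is not simulated explicitly — its features are zero,
so no learning can occur there, and the trace decay makes carry-over
negligible. Every trial is preceded by one synthetic zero-feature
baseline step (recorded at step −1). The prediction error on the
transition from that baseline into the first trial state is the cue-onset
burst (`γV̂(onset)`); analyses read the "cue response" there and the
"reward response" at the reward step. Pavlovian trials extend 2 s past
the reward so that post-reward prediction errors (and hence the negative
weights on early reward microstimuli that underlie the early-reward
result) can form.

**Actor.** Action preferences are linear in the same features,
`f(a) = Σ_d u(a,d) x(d)`, actions are sampled from
`p(a) ∝ exp f(a)`, and only the taken action is updated:

    u(a_t, d) += η δ_t (1 − p(a_t)) x_t(d),   default η = 0.5.

Rewards are delivered in the same 50-ms step as the response that earns
them, so δ_t contains the consequence of a_t and the update credits the
causal action. The tabular form of this rule is recovered for one-hot
features. η = 0.5 was chosen during model development as the smallest
value in {0.1, 0.5, 1.0} at which 2000 peak-procedure trials produce a
response curve with a clearly resolved peak (amplitude ≈ 0.5 over the
0.5 sampling baseline); the fitted peak time is insensitive to η over
that range.

## Tasks

* **Pavlovian conditioning** — cue at step 0, reward at the trained
  interval; probes move the reward earlier, omit it, or extend the cue.
* **Peak procedure** — reinforced trials reward the first "respond" at or
  after the fixed interval (FI); 25% of trials are unrewarded probes of
  3×FI. Unanswered reinforced trials time out at the probe duration.
* **Bisection** — a short- or long-anchor cue (2 s / 8 s by default) is
  followed by a 2-s choice window; the anchor-consistent choice is
  rewarded. Probes at 7 log-spaced intermediate durations are never
  reinforced; p(long) is read from the sampled choices, and the
  indifference point is interpolated at 0.5 in log-duration.

## Trace scaling for behavioural tasks

With ρ = 0.985 at 20 steps/s the memory trace is ≈ 0.002 at a 20-s
criterion: effectively no timing signal at peak-procedure scales (the
conditioning simulations never require one). For instrumental experiments
the package therefore sets the trace *half-life equal to the trained
interval*: ρ = 0.5^(1/(FI·20)), with the anchors' geometric mean playing
the role of the trained interval in bisection. This (i) makes the
representation span the task's range, (ii) rescales it proportionally
with the interval, which is what produces the scalar spread of response
curves (FI-40 spread ≈ 2× FI-20), and (iii) places the trace value 0.5 —
and hence the default early/late gain boundary θ = 0.5 — exactly at the
criterion time, so "early microstimuli" are those covering times up to
the trained interval, the range attributed to the striatum. Conditioning
simulations keep ρ = 0.985.

## Dopamine manipulations

A `GainProfile` multiplies microstimulus features with centers
`d/D ≥ θ` (early) by `gain_early` and the rest by `gain_late`.
`gain_early < 1` models D2 antagonism / low striatal dopamine;
`gain_early > 1` models agonists. Manipulations are applied *acutely*: the
agent is trained drug-free, then probed with the gains in place and
learning frozen, matching drug administration at test in the experimental
literature. (Training to convergence under scaled features would let the
linear weights rescale and absorb the manipulation.) Attenuating the
early features removes the early part of the learned response drive, so
the fitted peak moves later; enhancement moves it earlier. With five
training seeds both directions hold in 5/5 runs (shifts of roughly +1 s
and −0.6 s at FI-20).

## Rectified scalar-noise prediction errors

The semi-Markov account is represented only at the level of its
prediction-error distribution: PE ~ Normal(0, (k·T^p)²) with Weber-like
k = 0.15 and p = 1 (scalar noise), rectified at a floor c = −0.1 in
reward units ("slightly below zero" is not quantified in the source
account; the floor is configurable and reported in outputs). The
closed form E[max(X, c)] = c·Φ(c/σ) + σ·φ(c/σ) serves as the analytic
oracle for the Monte-Carlo means. Belief-state inference, the two-state
ISI/ITI machinery, and the learning rule of the full semi-Markov model
are intentionally out of scope.

## Numerical choices and degenerate inputs

* Weights and preferences initialize at zero (naive prior).
* The eligibility trace incorporates the current state's features before
  its own δ is applied; with λ = 0 the engine is step-for-step identical
  to an independently coded TD(0) reference.
* Gaussian peak fits use `scipy.optimize.curve_fit` with a baseline term
  (the softmax sampling floor of ~0.5 would otherwise bias the mean);
  a smoothed argmax is the documented fallback and is flagged via
  `fit_quality = nan`. Parameter recovery on noise-free synthetic curves
  is better than 5%.
* Zero-trial sessions return empty logs; all-zero response curves and
  empty probe sets raise errors rather than fabricating statistics.
* Seconds-to-steps conversion rounds to the nearest step; intervals that
  round to zero steps are configuration errors.
* A single run seed feeds `numpy.random.SeedSequence`, from which
  independent per-component streams are spawned.

## What the simulations do and do not show

All inputs are generated by the task modules; there is no empirical data
in the loop. Passing tests show that the implemented learning rules
reproduce the qualitative signatures claimed for these model classes
(interval scaling of prediction errors, early-reward/omission
asymmetries, peak timing and scalar spread, geometric-mean bisection,
directional drug effects) under the stated study conditions — not that
the parameter values are quantitatively fitted to any animal's data.
Known limitations: the peak-procedure baseline response rate sits near
the softmax chance level of 0.5 (no response cost is modelled); the
trace-scaling rule is a design choice, not a learned adaptation; and the
actor has no explicit opponent (e.g. serotonergic) channel for negative
prediction errors.

## Problem sizes

Conditioning experiments use 100 trials per interval (interval sweep) or
500 trials (convergence and probe experiments); behavioural experiments
use 2000 training trials, in-training probe read-outs (≈ 500 probes) and
150-probe frozen test sessions per manipulation; the rectified-noise
Monte Carlo uses 10⁵ draws per interval. These sizes were chosen so each
experiment's statistics are stable across seeds while a full reproduction
remains a desk-scale computation.
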