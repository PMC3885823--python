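# tdtiming

Actor-critic TD(λ) simulations of dopamine prediction errors and interval
timing in the basal ganglia.

## What this is for

Phasic dopamine firing behaves like a temporal-difference reward-prediction
error, and the basal ganglia are also central to interval timing — the
perception of durations from seconds to minutes. `tdtiming` is a simulator
for the family of models that explains both with one system: a linear
TD(λ) "critic" over a temporal feature representation, paired with a
softmax "actor" whose action preferences are trained by the critic's
prediction error. It is aimed at computational-neuroscience work that needs
reproducible simulations of conditioning and timing experiments rather
than fits to a particular dataset.

The core objects are:

* **Temporal bases** — the *complete serial compound* (CSC; a perfect
  clock, one feature per post-stimulus time step) and *microstimuli*: a
  decaying memory trace `y_t = ρ^t` read out by `D` Gaussian temporal
  receptive fields, `x_t(d) = y_t φ((y_t − d/D)/σ)`, giving coarser timing
  at longer delays.
* **Critic** — `V̂(s) = Σ_d w(d) x(d)` trained by online TD(λ):
  `δ_t = r_t + γV̂(s_{t+1}) − V̂(s_t)`, `e ← γλe + x_t`, `w ← w + αδ_t e`.
  The prediction error δ is the model's dopamine signal.
* **Actor** — `p(a) ∝ exp{Σ_d u(a,d) x(d)}`, with
  `u(a_t) += ηδ_t(1 − p(a_t)) x_t` for the taken action; this turns value
  learning into timed responding (peak procedure, temporal bisection).
* **Dopamine manipulations** — multiplicative gains on the early
  (striatally represented) microstimuli: gain < 1 emulates D2 antagonism /
  Parkinsonian dopamine depletion (later responding), gain > 1 agonists
  (earlier responding).
* **Rectified scalar-noise prediction errors** — the semi-Markov account
  reduced to its essential claim: PE ~ Normal(0, (kT)²) rectified at a
  floor slightly below zero yields average prediction errors that grow
  with the interval T.

Simulations follow a statsmodels-like pattern: a model object is built
from a trial schedule and configuration, `.fit()` runs the simulation, and
the returned results object carries per-step logs, learned parameters,
summaries and probe/test methods.

## Worked example

Reproduce the interval dependence of dopamine responses in Pavlovian
conditioning — the cue response shrinks and the reward response grows with
the cue-reward interval:

```python
from tdtiming.experiments import interval_sweep

df = interval_sweep(n_trials=100)   # alpha=0.01, gamma=0.98, lambda=0.95,
print(df.to_string(index=False))    # D=50, sigma=0.08, 20 steps/s
```

```
 interval_s  cue_delta  reward_delta
        1.0   0.486991      0.915404
        2.0   0.353486      0.922424
        4.0   0.132598      0.943833
        8.0   0.010576      0.984079
       16.0   0.000229      0.993862
```

`cue_delta` is the prediction error generated by cue onset on the final
trial (temporal discounting plus trace-limited credit make it fall with
the interval); `reward_delta` is the prediction error when the reward
arrives (reward-time predictions get less precise at longer intervals, so
more of the reward stays "surprising"). A perfect-clock CSC critic would
instead predict the reward equally well at every interval.

Instrumental timing with the same machinery:

```python
from tdtiming.experiments import peak_experiment

res, stats = peak_experiment(fi_s=20.0, n_trials=2000, seed=0)
print(res.summary())
```

```
Actor-critic interval-timing model
==================================
basis: microstimulus, D=50, sigma=0.08, rho=0.998269
learner: alpha=0.01, gamma=0.98, lambda=0.95; actor eta=0.5
trials: 2000 (500 probes)
probe response curve: peak 20.39 s, spread 8.19 s (R^2=0.973)
```

Responding on unrewarded probe trials peaks at the trained 20-s interval;
training at 40 s moves the peak to ≈ 41 s with roughly double the spread
(the scalar property of timing).

A command-line interface mirrors the recipes
(`tdtiming sweep|pavlovian|peak|bisection|rectified --seed N --out DIR`,
optionally `--config cfg.yaml`), writing tidy CSV tables and a JSON
manifest for each run.

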