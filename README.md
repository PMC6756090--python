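# advicehgf

Computational modelling of social advice-taking under volatile adviser
intentions, aimed at the precision-imbalance account of persecutory
ideation in early psychosis.

In the paradigm this package simulates, a player predicts the outcome of a
binary lottery while an adviser — who sees a private cue that is valid 80%
of the time — gives advice that is sometimes honest and sometimes
deliberately misleading, with intentions that change over the course of
the game. Doing well requires inferring not just whether the current
advice is accurate, but how trustworthy the adviser is and how quickly
that trustworthiness is changing (volatility).

The package provides:

* **Task simulation** — the volatile advice-taking game (phases of mostly
  helpful / mostly misleading intentions) and a non-intentional card-deck
  control, with deterministic seeding and CSV trial logs.
* **A 3-level binary hierarchical Gaussian filter (HGF)** — trial-by-trial
  beliefs over advice accuracy (x₁), adviser fidelity (x₂) and intention
  volatility (x₃). Each update obeys the precision-weighted
  prediction-error scheme: Δμᵢ ∝ (π̂ᵢ₋₁ / πᵢ) · δᵢ₋₁, with sensory
  precision amplifying and belief precision damping the update. A 2-level
  fixed-volatility variant serves as a baseline.
* **Response models** — a unit-square sigmoid mapping the predicted advice
  accuracy μ̂₁ to the probability of taking the advice, with inverse
  decision noise ζ.
* **Phenotype presets** — `healthy`, `prodromal` (inflated sensory
  precision → high, unstable learning rate) and `delusional` (overly
  precise pessimistic beliefs → reduced volatility estimate, low learning
  rate, "explaining away" of contradictory advice), for contrastive agent
  simulations.
* **Model inversion** — multistart MAP fitting of the 3-level HGF, 2-level
  HGF and a Rescorla–Wagner learner; fixed-effects and random-effects
  (Dirichlet / exceedance-probability) Bayesian model comparison; and
  parameter/model recovery studies.

## Worked example

```python
import advicehgf as a

# the default volatile schedule: 160 trials, six phases alternating
# p(helpful) = 0.9 / 0.1
seq = a.generate_task(a.default_config(seed=42))
print(a.summarize_phases(seq))

# run a healthy observer and simulate its choices
traj, choices, summary = a.simulate_agent(seq, a.make_phenotype("healthy"), seed=42)
print(summary)

# refit the 3-level model to the simulated choices
fit = a.fit_map(choices, seq.inputs, "hgf3", n_starts=4, seed=0)
print(fit.estimates, fit.log_likelihood, fit.bic)
```

Output (abridged):

```
 phase  length  p_helpful  advice_accuracy
     0      30        0.9         0.800000
     1      20        0.1         0.250000
     2      30        0.9         0.766667
     ...
mean_lr2: 1.232
mean_mu3: 0.938
take_rate: 0.519
post_contradiction_update: 0.867

omega = -1.98, zeta = 4.19   (generating preset: omega = -2, zeta = 5)
LL = -31.8, BIC = 73.7
```

The phase table shows realized advice accuracy tracking
`p_helpful·0.8 + (1−p_helpful)·0.2` (0.80 in helpful phases, 0.20 in
misleading ones). The agent summary gives the mean level-2 learning rate,
the mean volatility belief μ₃, the fraction of trials the agent went with
the advice, and the mean belief shift after advice that contradicted the
current expectation. The refit recovers the generating `omega` almost
exactly; `zeta` is recovered more loosely, as expected from 160 binary
choices.

A command-line interface wraps the same functions:

```bash
advicehgf simulate-task --seed 1 --out task.csv
advicehgf simulate-agent --task task.csv --phenotype delusional --seed 1 --out-prefix agent
advicehgf fit --choices merged.csv --model hgf3 --starts 8 --seed 1 --out fit.json
advicehgf recover --model hgf3 --agents 40 --trials 320 --seed 1 --out recovery.json
```

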