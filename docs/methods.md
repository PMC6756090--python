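# Methods

## The task

The simulator emulates a binary lottery game with social advice. On every
trial a lottery outcome is drawn uniformly over two options. An adviser
receives a private cue that matches the outcome with probability
`cue_validity` (default 0.8) and then passes on advice: when the adviser's
intention on that trial is *helpful* the advice repeats the cue, when it is
*misleading* the advice inverts it. Intentions are volatile: the game is
divided into phases, each with its own probability `p_helpful`, and the
intention is resampled independently on every trial within a phase. This
single mechanism covers both stable regimes (`p_helpful` near 0 or 1) and
volatile ones (intermediate probabilities or short phases). Under it, the
long-run advice accuracy in a phase is

    P(advice correct) = p_helpful * v + (1 - p_helpful) * (1 - v),

with `v = cue_validity` — the closed form the generator's tests check.

The default schedule is 160 trials in six phases alternating
`p_helpful ∈ {0.9, 0.1}` with lengths 30/20/30/30/20/30. It is a
configurable stand-in: the point is alternation between mostly-helpful and
mostly-misleading blocks, with block lengths short enough that the
adviser's fidelity never becomes certain. Fitting-scale studies tile this
schedule (320 = 2×, 480 = 3×).

A control variant removes intentionality: advice is correct i.i.d. with
probability `deck_accuracy`, and the intention column records `none`. This
emulates an adviser who draws advice blindly from a pre-arranged deck, so
any hierarchical structure a fitted observer infers there is spurious by
construction.

Outcomes are balanced only in expectation; option labels are abstract
{0, 1}. Payoff bookkeeping, stimulus identity and reaction times are out of
scope.

## The observer: a 3-level binary hierarchical Gaussian filter

The observer infers, from the binary series `u(k)` (1 iff advice matched
the outcome), a hierarchy: advice accuracy (level 1), the adviser's
fidelity tendency `x2` (level 2, logistic-linked to accuracy), and the
log-volatility of intentions `x3` (level 3), which sets the diffusion of
`x2`. Each level's belief is Gaussian `(μ, σ)`; each trial's update is a
prediction error from the level below scaled by a ratio of precisions —
sensory precision (of the predicted input) amplifies, belief precision (of
the current level) damps. The exact update equations implemented are listed
in the `hgf` module docstring; the level-2 learning rate is the posterior
variance `σ2`, which the trajectory exposes as `lr2`.

Parameters, with defaults and roles:

| name | default | role |
|---|---|---|
| `kappa` | 1.0 | coupling of volatility onto fidelity drift; 0 decouples level 3 exactly |
| `omega` | −2.0 | tonic log-volatility at level 2; the main learning-rate dial |
| `theta` | 0.5 (type default) / 0.01–0.15 (presets, fitting) | variance of the volatility random walk |
| `mu2_0, sigma2_0` | 0, 1 | fidelity prior; negative mean = "adviser misleads" prior |
| `mu3_0, sigma3_0` | 1, 1 | volatility prior |

Numerical choices:

* `μ̂1` is clipped to `[1e−8, 1 − 1e−8]` before forming the level-1
  precision, so extreme beliefs cannot produce infinite precision.
* A non-positive level-3 posterior precision raises `FilterRegimeError`
  with the offending trial, rather than clamping: fitting must be able to
  reject pathological parameter regions, and silent clamping would corrupt
  model comparison. A divergent volatility estimate (exponent overflow) is
  treated the same way.
* The regime guard is not hypothetical. The 3-level binary filter becomes
  invalid when the volatility random walk is too loose: with `theta` of
  order 0.5, or `omega` above roughly −1.5 at `kappa = 1`, most volatile
  160-trial realisations hit a non-positive level-3 precision. For this
  reason the presets and the fitting specification keep `theta` in the
  0.01–0.15 range and generating parameters keep `omega ≤ −2`; the large
  `theta` on the `PerceptionParams` type default is harmless for one-step
  examples but should not be used for full runs.

The two-level variant removes level 3 (`σ̂2 = σ2 + exp(ω)`); its level-3
trajectory fields are NaN. It serves as the fixed-volatility baseline in
the comparison space.

## Responses

Beliefs map to the probability of taking the advice through a unit-square
sigmoid, `p_take = μ̂1^ζ / (μ̂1^ζ + (1−μ̂1)^ζ)`, computed in log-odds form
(`expit(ζ·logit μ̂1)`) so large `ζ` cannot overflow. `ζ` is the inverse
decision noise: 1 gives probability matching, ∞ the deterministic argmax.
The response family is deliberately swappable — anything mapping `μ̂1` to
probabilities can replace it in the fitting code — because the belief-to-
action link is the least constrained part of the design. Ties
(`p_take = 0.5`) are resolved by the Bernoulli draw itself.

## Phenotype presets

The presets express the precision-imbalance account of the psychosis
spectrum as parameter displacements from a healthy reference:

* `healthy`: `κ=1, ω=−2, θ=0.01, μ2₀=0, σ2₀=1, μ3₀=1, σ3₀=1, ζ=5`.
* `prodromal`: as healthy with `ω=−1.5`. Raising `ω` inflates the level-2
  variance step and thereby the weight of sensory prediction errors — the
  "increased sensory precision" stage is operationalised through `ω`
  rather than a separate multiplier on the input precision, keeping the
  model inside the standard parameterisation (an explicit precision-scaling
  parameter could be added later). `ω=−1.5` is the largest displacement
  that stays inside the filter's valid regime on volatile schedules.
* `delusional`: `κ=0.5, ω=−4, μ2₀=−1, σ2₀=0.5, μ3₀=0`. Belief
  over-precision is operationalised as tight, pessimistic priors plus low
  `ω/κ`: a reduced volatility estimate, a low tonic learning rate and a
  negative prior on the adviser's fidelity.

The numbers are illustrative fixtures, not clinical calibrations; what the
simulations demonstrate is the *ordering* of summary statistics (learning
rate, volatility estimate, post-contradiction updating), not their scale.
The `post_contradiction_update` summary is the mean `|Δμ2|` on trials whose
input lay on the opposite side of 0.5 from the current prediction — small
values are the "explaining away" signature.

Contrasts are run over fresh task realisations (the seed regenerates the
task), because for a fixed input sequence the trajectory summaries are
deterministic and seed-to-seed dispersion would be vacuous.

## Inversion

Fitting is MAP in unconstrained space: `ω` identity with prior N(−2, 4)
(a zero-centred prior would put half its mass in the invalid/implausible
high-volatility regime), `ζ` and `β` log-transformed with prior N(0, 4),
`α` logit-transformed with prior N(0, 4). The search is Nelder–Mead from
multistart initial points (start 0 at the prior mean, the rest drawn from
the prior), followed by one restart from the winner to refresh a possibly
degenerate simplex. Parameter vectors that break the filter receive a
large soft penalty that decreases with the trial at which the filter
broke, which steers the simplex back towards the valid region while
keeping every valid point strictly preferred; a fit errors out only if no
start ever reaches validity. The recovery studies use six starts: the
likelihood can be bimodal in `ζ` (a chance-level mode near `ζ = 0`
coexists with the true mode), and fewer starts occasionally land every
simplex in the wrong basin. Log evidence is approximated by −BIC/2 —
derivative-free search makes Hessian-based Laplace evidence unreliable at
this scale; the approximation is upgradeable. Random-effects comparison
uses the standard variational Dirichlet scheme over model frequencies with
uniform prior counts of 1; exceedance probabilities are Monte-Carlo
estimates from the fitted Dirichlet (100k draws, seeded).

The comparison space is `hgf3` (free `ω, ζ`; `κ=1, θ=0.15` fixed), `hgf2`
(free `ω, ζ`) and `rw` (free `α, β`; delta rule on advice accuracy, softmax
on the pre-update value). `θ=0.15` for the generating/fitted 3-level model
sits at the top of the stable range: model identifiability demands that the
volatility level actually move — as `θ → 0` the 3-level model degenerates
into the 2-level one and no procedure could tell them apart.

Recovery studies draw generating parameters uniformly from ranges where
each model's distinctive mechanism is expressed in behaviour and the
filter is valid on essentially all realisations: `ω ∈ (−3, −2)` for the
3-level model (the volatility level must actually move), `ω ∈ (−2.25,
−1.5)` for the 2-level model (fixed-volatility learning at rates the
3-level hierarchy cannot sustain without breaking), `ζ ∈ (4, 10)`,
`α ∈ (0.1, 0.7)`, `β ∈ (2, 10)`. A generating draw whose
(parameters, realisation) pair lands in the invalid regime is rejection-
resampled, so the generating population is valid-regime agents by
definition. Parameter recovery uses 40 agents × 320 trials; model
recovery 20 subjects per generating model × 480 trials.

Fixed-effects margins between the 3- and 2-level models are intrinsically
small (expected gaps of a fraction of a nat to a few nats per subject)
because the models genuinely overlap for weakly volatile subjects. The
confusion-matrix diagonal is therefore the fragile quantity: across random
study seeds the 2-level cohort's margin occasionally flips sign, and
cohort-level conclusions should quote the margin, not just the winner.
Doubling the trials per subject grows the expected margin faster than its
noise but does not eliminate flips at realistic sizes.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton of the paradigm — cue
validity, intention volatility, the control condition — but none of its
social surface: no faces, no incentives, no sequential dependency between
the adviser's intentions beyond the phase structure, and no coupling from
the player's compliance back to the adviser's strategy. Passing tests
demonstrate internal consistency and recoverability under the model's own
assumptions; they say nothing about whether real participants behave like
any of these observers, which is an empirical question requiring real
choice data.

Known limitations: the evidence approximation ignores posterior
correlations; only the advice stream is modelled (no parallel hierarchy
for a non-social cue); the alternative account of delusions via asymmetric
weighting of negative advice prediction errors is not implemented; preset
contrasts are qualitative orderings, not effect-size predictions.
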