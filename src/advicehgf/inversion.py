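"""Model inversion: MAP fitting, model comparison, recovery studies.

The model space contains three observer models of advice-taking:

* ``hgf3`` — 3-level HGF (volatility learning) with unit-square sigmoid
  responses; free parameters omega and zeta.
* ``hgf2`` — 2-level HGF with fixed volatility; free omega and zeta.
* ``rw``  — Rescorla–Wagner delta rule on advice accuracy with a softmax on
  the value estimate; free learning rate alpha and inverse temperature beta.

Fitting is maximum-a-posteriori in an unconstrained transformed space
(log for strictly positive parameters, logit for rates, identity for
omega), with independent Gaussian priors in that space, multistart
Nelder–Mead search, and parameter regimes that break the filter assigned a
large soft penalty. Log model evidence is approximated by -BIC/2; cohorts are
compared both fixed-effects (summed log evidence) and random-effects via
the variational Dirichlet scheme over model frequencies, with exceedance
probabilities by Monte-Carlo sampling of the fitted Dirichlet.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special

from .hgf import FilterRegimeError, PerceptionParams, filter_beliefs, filter_beliefs_two_level
from .responses import ChoiceSeries, log_likelihood, unit_square_sigmoid
from .task import default_config, generate_task
from .responses import simulate_choices

__all__ = [
    "FreeParam",
    "ModelSpec",
    "FitResult",
    "ModelComparisonResult",
    "model_spec",
    "MODEL_NAMES",
    "fit_map",
    "rescorla_wagner",
    "compare_models",
    "parameter_recovery",
    "model_recovery",
]

MODEL_NAMES = ("hgf3", "hgf2", "rw")


# --------------------------------------------------------------------------
# Parameter transforms and model specifications
# --------------------------------------------------------------------------

def _identity(x):
    return x


def _logit(p):
    return np.log(p) - np.log1p(-p)


_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    # name -> (native -> transformed, transformed -> native)
    "identity": (_identity, _identity),
    "log": (np.log, np.exp),
    "logit": (_logit, special.expit),
}


@dataclass(frozen=True)
class FreeParam:
    """A free parameter: its transform to unconstrained space and the
    Gaussian prior (mean, variance) in that transformed space."""

    name: str
    transform: str
    prior_mean: float
    prior_var: float = 4.0

    def to_transformed(self, native: float) -> float:
        return float(_TRANSFORMS[self.transform][0](native))

    def to_native(self, transformed: float) -> float:
        return float(_TRANSFORMS[self.transform][1](transformed))


@dataclass(frozen=True)
class ModelSpec:
    """A model in the comparison space: free parameters plus fixed values."""

    name: str
    free: tuple[FreeParam, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def to_native(self, vec: Sequence[float]) -> dict[str, float]:
        return {
            fp.name: fp.to_native(v) for fp, v in zip(self.free, vec, strict=True)
        } | dict(self.fixed)

    def to_transformed(self, native: Mapping[str, float]) -> np.ndarray:
        return np.array([fp.to_transformed(native[fp.name]) for fp in self.free])

    def log_prior(self, vec: Sequence[float]) -> float:
        lp = 0.0
        for fp, v in zip(self.free, vec, strict=True):
            lp += -0.5 * (
                math.log(2 * math.pi * fp.prior_var)
                + (v - fp.prior_mean) ** 2 / fp.prior_var
            )
        return lp

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [rng.normal(fp.prior_mean, math.sqrt(fp.prior_var)) for fp in self.free]
        )


def model_spec(name: str) -> ModelSpec:
    """Build the canonical spec for one of the model-space members."""
    if name == "hgf3":
        return ModelSpec(
            name="hgf3",
            free=(
                FreeParam("omega", "identity", prior_mean=-2.0),
                FreeParam("zeta", "log", prior_mean=0.0),
            ),
            fixed={
                "kappa": 1.0, "theta": 0.15,
                "mu2_0": 0.0, "sigma2_0": 1.0, "mu3_0": 1.0, "sigma3_0": 1.0,
            },
        )
    if name == "hgf2":
        return ModelSpec(
            name="hgf2",
            free=(
                FreeParam("omega", "identity", prior_mean=-2.0),
                FreeParam("zeta", "log", prior_mean=0.0),
            ),
            fixed={"mu2_0": 0.0, "sigma2_0": 1.0},
        )
    if name == "rw":
        return ModelSpec(
            name="rw",
            free=(
                FreeParam("alpha", "logit", prior_mean=0.0),
                FreeParam("beta", "log", prior_mean=0.0),
            ),
        )
    raise KeyError(f"unknown model {name!r}; known: {MODEL_NAMES}")


# --------------------------------------------------------------------------
# Observer models: inputs + native parameters -> per-trial p_take
# --------------------------------------------------------------------------

def rescorla_wagner(
    inputs: Sequence[int], alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-rule value learning of advice accuracy with softmax responses.

    V(k) = V(k-1) + alpha * (u(k) - V(k-1)), V(0) = 0.5;
    p_take(k) = logistic(beta * (Vhat(k) - 0.5)) with Vhat the pre-update
    value (the prediction available at choice time). Returns (V, p_take)
    where V[k] is the post-update value on trial k.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    u = np.asarray(inputs, dtype=np.float64)
    n = len(u)
    V = np.empty(n)
    p_take = np.empty(n)
    v = 0.5
    for k in range(n):
        p_take[k] = special.expit(beta * (v - 0.5))
        v = v + alpha * (u[k] - v)
        V[k] = v
    return V, p_take


def predict_p_take(
    spec_name: str, params: Mapping[str, float], inputs: Sequence[int]
) -> np.ndarray:
    """Per-trial take-advice probability under a named model.

    Raises FilterRegimeError for HGF parameter regimes that break the
    filter; fitting converts that into a large objective penalty.
    """
    if spec_name in ("hgf3", "hgf2"):
        pp = PerceptionParams(
            **{k: v for k, v in params.items() if k != "zeta"}
        )
        run = filter_beliefs if spec_name == "hgf3" else filter_beliefs_two_level
        traj = run(inputs, pp)
        return unit_square_sigmoid(traj.muhat1, params["zeta"])
    if spec_name == "rw":
        _, p_take = rescorla_wagner(inputs, params["alpha"], params["beta"])
        return p_take
    raise KeyError(f"unknown model {spec_name!r}")


# --------------------------------------------------------------------------
# MAP fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Outcome of a (multistart) MAP fit of one model to one subject."""

    model: str
    estimates: dict[str, float]              # native space, free params only
    estimates_transformed: dict[str, float]
    neg_log_joint: float
    log_likelihood: float
    n_trials: int
    aic: float
    bic: float
    converged: bool
    multistart_index: int
    n_function_evals: int

    @property
    def log_evidence(self) -> float:
        """-BIC/2 log-evidence approximation."""
        return -self.bic / 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FitResult":
        return cls(**json.loads(Path(path).read_text()))


class FittingError(RuntimeError):
    """No multistart reached a valid parameter regime."""


#: Objective value assigned to invalid parameter regimes. A soft penalty
#: that shrinks the longer the filter survives steers the simplex towards
#: the valid region; any valid point scores far below it.
_PENALTY = 1e8


def _neg_log_joint(vec, spec: ModelSpec, y: np.ndarray, inputs: np.ndarray) -> float:
    try:
        params = spec.to_native(vec)
    except OverflowError:
        return 2.0 * _PENALTY
    try:
        p_take = predict_p_take(spec.name, params, inputs)
    except FilterRegimeError as e:
        return _PENALTY * (2.0 - e.trial / len(inputs))
    except (OverflowError, FloatingPointError):
        return 2.0 * _PENALTY
    if not np.all(np.isfinite(p_take)):
        return 2.0 * _PENALTY
    ll = log_likelihood(y, p_take)
    return -(ll + spec.log_prior(vec))


def fit_map(
    choices,
    task_inputs: Sequence[int],
    spec: Union[ModelSpec, str],
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Multistart MAP fit of a model to one subject's choices.

    ``choices`` is a ChoiceSeries or 0/1 took-advice array aligned with the
    binary ``task_inputs`` (advice correctness). Initial points are drawn
    from the prior with a seeded generator; the best (lowest) negative
    log-joint across starts wins, ties broken by lowest start index.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    y = choices.took_advice if isinstance(choices, ChoiceSeries) else np.asarray(choices)
    u = np.asarray(task_inputs)
    if len(y) != len(u):
        raise ValueError(f"length mismatch: {len(y)} choices vs {len(u)} inputs")
    if n_starts < 1:
        raise ValueError("need at least one start")
    n = len(y)
    k = spec.n_free

    if k == 0:
        p_take = predict_p_take(spec.name, dict(spec.fixed), u)
        ll = log_likelihood(y, p_take)
        return FitResult(
            model=spec.name, estimates={}, estimates_transformed={},
            neg_log_joint=-ll, log_likelihood=ll, n_trials=n,
            aic=-2 * ll, bic=-2 * ll, converged=True,
            multistart_index=0, n_function_evals=1,
        )

    rng = np.random.default_rng(seed)
    best = None
    prior_mean = np.array([fp.prior_mean for fp in spec.free])
    for i in range(n_starts):
        # first start at the prior mean (always a valid regime), the rest
        # drawn from the prior
        x0 = prior_mean if i == 0 else spec.sample_prior(rng)
        with np.errstate(invalid="ignore"):  # simplex may hold inf objectives
            res = optimize.minimize(
                _neg_log_joint, x0, args=(spec, y, u), method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600},
            )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best[1].fun:
            best = (i, res)
    if best is None or best[1].fun >= _PENALTY:
        raise FittingError(
            f"all {n_starts} starts failed for model {spec.name!r} "
            f"(n={n} trials); no start reached a valid parameter regime"
        )
    i, res = best
    # restart once from the winner: a fresh simplex escapes the degenerate
    # simplexes Nelder-Mead is prone to
    with np.errstate(invalid="ignore"):
        polish = optimize.minimize(
            _neg_log_joint, res.x, args=(spec, y, u), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
        )
    if np.isfinite(polish.fun) and polish.fun <= res.fun:
        polish.nfev += res.nfev
        res = polish
    vec = np.asarray(res.x, dtype=float)
    ll = log_likelihood(y, predict_p_take(spec.name, spec.to_native(vec), u))
    native = {fp.name: fp.to_native(v) for fp, v in zip(spec.free, vec)}
    return FitResult(
        model=spec.name,
        estimates=native,
        estimates_transformed={fp.name: float(v) for fp, v in zip(spec.free, vec)},
        neg_log_joint=float(res.fun),
        log_likelihood=float(ll),
        n_trials=n,
        aic=float(2 * k - 2 * ll),
        bic=float(k * math.log(n) - 2 * ll),
        converged=bool(res.success),
        multistart_index=int(i),
        n_function_evals=int(res.nfev),
    )


# --------------------------------------------------------------------------
# Bayesian model selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparisonResult:
    """Fixed- and random-effects comparison of a cohort of fits.

    ``log_evidence`` is subjects x models (-BIC/2 per cell);
    ``exceedance`` holds the probability that each model is the most
    frequent in the population under the fitted Dirichlet.
    """

    models: tuple[str, ...]
    log_evidence: np.ndarray
    fixed_effects: dict[str, float]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray

    @property
    def fixed_effects_winner(self) -> str:
        return max(self.fixed_effects, key=self.fixed_effects.get)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "log_evidence": self.log_evidence.tolist(),
            "fixed_effects": self.fixed_effects,
            "fixed_effects_winner": self.fixed_effects_winner,
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance": self.exceedance.tolist(),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def compare_models(
    fits: Sequence[Mapping[str, FitResult]],
    seed: int = 0,
    n_samples: int = 100_000,
    alpha0: float = 1.0,
) -> ModelComparisonResult:
    """Compare a model space across subjects.

    ``fits`` has one mapping per subject, model name -> FitResult; every
    subject must have a fit for every model. Log evidence per cell is the
    -BIC/2 approximation. Random effects follow the variational Dirichlet
    scheme over model frequencies with uniform prior counts ``alpha0``;
    exceedance probabilities are estimated by sampling the fitted
    Dirichlet with a seeded generator.
    """
    if len(fits) == 0:
        raise ValueError("no fits supplied")
    models = tuple(sorted(fits[0]))
    for i, row in enumerate(fits):
        if set(row) != set(models):
            raise ValueError(f"subject {i} is missing fits for some models")
    L = np.array([[row[m].log_evidence for m in models] for row in fits])
    n_subj, n_models = L.shape

    fixed = {m: float(L[:, j].sum()) for j, m in enumerate(models)}

    # variational Dirichlet update over model frequencies
    alpha = np.full(n_models, alpha0, dtype=float)
    for _ in range(200):
        logu = L + special.digamma(alpha) - special.digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-10:
            alpha = alpha_new
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceedance = np.bincount(winners, minlength=n_models) / n_samples

    return ModelComparisonResult(
        models=models,
        log_evidence=L,
        fixed_effects=fixed,
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=exceedance,
    )


# --------------------------------------------------------------------------
# Recovery studies
# --------------------------------------------------------------------------

def default_sampler(spec: ModelSpec) -> Callable[[np.random.Generator], dict]:
    """Sampler of generating parameters over a plausible native range.

    Ranges are chosen so that each model's distinctive mechanism is
    expressed in behaviour: the 3-level model's omega stays in the regime
    where the volatility level actually moves (and the filter is valid),
    while the fixed-volatility 2-level model may learn faster — rates the
    3-level hierarchy cannot sustain.
    """
    ranges = {
        "omega": (-3.0, -2.0) if spec.name == "hgf3" else (-2.25, -1.5),
        "zeta": (4.0, 10.0),
        "alpha": (0.1, 0.7),
        "beta": (2.0, 10.0),
    }

    def sample(rng: np.random.Generator) -> dict:
        return {
            fp.name: float(rng.uniform(*ranges[fp.name])) for fp in spec.free
        }

    return sample


def _simulate_subject(
    spec: ModelSpec, params: dict, n_trials: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one subject: a fresh task realisation plus model choices."""
    n_reps = max(1, round(n_trials / 160))
    cfg = default_config(seed=seed, n_reps=n_reps)
    seq = generate_task(cfg)
    u = seq.inputs[:n_trials]
    p_take = predict_p_take(spec.name, dict(params) | dict(spec.fixed), u)
    choices = simulate_choices(p_take, seed=seed + 1)
    return u, choices.took_advice


def _draw_valid_subject(
    spec: ModelSpec,
    sampler: Callable[[np.random.Generator], dict],
    n_trials: int,
    seed: int,
    max_attempts: int = 50,
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Draw generating parameters and a task realisation in the filter's
    valid regime.

    The generating population is defined as valid-regime agents: a
    (parameters, realisation) pair on which the filter degenerates is
    redrawn, up to ``max_attempts`` times.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        true = sampler(rng)
        try:
            u, y = _simulate_subject(spec, true, n_trials,
                                     seed=seed + 1_000_003 * attempt)
        except FilterRegimeError:
            continue
        return true, u, y
    raise FittingError(
        f"could not draw a valid generating agent for {spec.name!r} in "
        f"{max_attempts} attempts"
    )


def parameter_recovery(
    model: Union[ModelSpec, str],
    sampler: Callable[[np.random.Generator], dict] | None = None,
    n_agents: int = 40,
    n_trials: int = 320,
    seed: int = 0,
    n_starts: int = 6,
) -> pd.DataFrame:
    """Simulate-and-refit study: per-parameter correlation, bias, RMSE.

    Each agent gets its own task realisation, generating parameters drawn
    from ``sampler`` (default: uniform over a plausible native range), and
    a MAP refit. Returns a per-parameter report; correlations are NaN when
    n_agents < 2. A ``pairs`` attribute on the frame carries the per-agent
    true/recovered values.
    """
    if isinstance(model, str):
        model = model_spec(model)
    sampler = sampler or default_sampler(model)
    seeds = np.random.SeedSequence(seed).generate_state(n_agents) % (2**30)

    records = []
    for a in range(n_agents):
        true, u, y = _draw_valid_subject(model, sampler, n_trials,
                                         seed=int(seeds[a]))
        fit = fit_map(y, u, model, n_starts=n_starts, seed=int(seeds[a]) + 7)
        for fp in model.free:
            records.append(
                {
                    "agent": a, "param": fp.name,
                    "true": true[fp.name], "recovered": fit.estimates[fp.name],
                }
            )
    pairs = pd.DataFrame(records)

    rows = []
    for name, g in pairs.groupby("param", sort=False):
        err = g["recovered"] - g["true"]
        corr = (
            float(np.corrcoef(g["true"], g["recovered"])[0, 1])
            if len(g) >= 2
            else float("nan")
        )
        rows.append(
            {
                "param": name,
                "n_agents": len(g),
                "correlation": corr,
                "bias": float(err.mean()),
                "median_abs_bias": float(err.abs().median()),
                "rmse": float(np.sqrt((err**2).mean())),
            }
        )
    report = pd.DataFrame(rows).set_index("param")
    report.attrs["pairs"] = pairs
    return report


def model_recovery(
    n_per_model: int = 20,
    n_trials: int = 480,
    seed: int = 0,
    n_starts: int = 6,
    models: Sequence[str] = MODEL_NAMES,
) -> pd.DataFrame:
    """Confusion matrix of fixed-effects model selection.

    For each generating model, ``n_per_model`` synthetic subjects are
    simulated and every candidate model is fitted to each; the cohort's
    fixed-effects (summed -BIC/2) winner fills the confusion matrix cell.
    Rows: generating model; columns: candidate; entries: summed log
    evidence; the frame's ``winner`` attribute maps generator -> selected.
    """
    specs = {m: model_spec(m) for m in models}
    seeds = np.random.SeedSequence(seed).generate_state(len(models) * n_per_model)
    seeds = (seeds % (2**30)).reshape(len(models), n_per_model)

    matrix = pd.DataFrame(0.0, index=list(models), columns=list(models))
    winners: dict[str, str] = {}
    for gi, gen in enumerate(models):
        gen_spec = specs[gen]
        sampler = default_sampler(gen_spec)
        fits = []
        for a in range(n_per_model):
            _, u, y = _draw_valid_subject(gen_spec, sampler, n_trials,
                                          seed=int(seeds[gi, a]))
            fits.append(
                {
                    m: fit_map(y, u, specs[m], n_starts=n_starts,
                               seed=int(seeds[gi, a]) + 13)
                    for m in models
                }
            )
        cmp = compare_models(fits, seed=seed)
        for m in models:
            matrix.loc[gen, m] = cmp.fixed_effects[m]
        winners[gen] = cmp.fixed_effects_winner
    matrix.attrs["winner"] = winners
    return matrix
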