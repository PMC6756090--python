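"""Belief-to-decision mapping: choice probabilities and simulated choices.

The response model maps the predicted advice accuracy muhat1 on each trial
to the probability of going with the advice through a unit-square sigmoid

    p_take = muhat1**zeta / (muhat1**zeta + (1 - muhat1)**zeta)

where zeta > 0 is the inverse decision noise: zeta = 1 reproduces
probability matching (p_take = muhat1), zeta -> infinity approaches a
deterministic argmax on the belief. The functional form is swappable: any
callable (muhat1, params) -> p_take can stand in for
:func:`choice_probabilities` throughout the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .hgf import BeliefTrajectory

__all__ = [
    "ResponseParams",
    "ChoiceSeries",
    "choice_probabilities",
    "simulate_choices",
    "log_likelihood",
]


@dataclass(frozen=True)
class ResponseParams:
    """Response parameters: zeta is the inverse decision noise (> 0)."""

    zeta: float = 1.0

    def __post_init__(self) -> None:
        if not self.zeta > 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")


@dataclass(frozen=True)
class ChoiceSeries:
    """Per-trial take-advice decisions and their probabilities."""

    took_advice: np.ndarray
    p_take: np.ndarray

    def __len__(self) -> int:
        return len(self.took_advice)


def unit_square_sigmoid(muhat1: np.ndarray, zeta: float) -> np.ndarray:
    m = np.asarray(muhat1, dtype=np.float64)
    # m**z / (m**z + (1-m)**z) == expit(z * logit(m)), which cannot under-
    # or overflow for large zeta
    logit_m = np.log(m) - np.log1p(-m)
    return special.expit(zeta * logit_m)


def choice_probabilities(
    traj: BeliefTrajectory, params: ResponseParams
) -> np.ndarray:
    """Per-trial probability of taking the advice."""
    return unit_square_sigmoid(traj.muhat1, params.zeta)


def simulate_choices(p_take: Sequence[float], seed: int = 0) -> ChoiceSeries:
    """Draw seeded Bernoulli choices from per-trial take probabilities."""
    p = np.asarray(p_take, dtype=np.float64)
    rng = np.random.default_rng(seed)
    took = (rng.random(len(p)) < p).astype(np.int64)
    return ChoiceSeries(took_advice=took, p_take=p)


def log_likelihood(choices, p_take) -> float:
    """Total Bernoulli log-likelihood of choices under take probabilities.

    ``choices`` may be a ChoiceSeries or a 0/1 array aligned with p_take.
    """
    y = choices.took_advice if isinstance(choices, ChoiceSeries) else choices
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p_take, dtype=np.float64)
    if len(y) != len(p):
        raise ValueError(
            f"length mismatch: {len(y)} choices vs {len(p)} probabilities"
        )
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
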