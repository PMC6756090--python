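"""Three-level binary hierarchical Gaussian filter (HGF).

The observer infers a hierarchy of hidden states from a binary input series
``u`` (1 iff the advice matched the lottery outcome):

* level 1 — accuracy of the current advice (``x1``, binary);
* level 2 — the adviser's fidelity, i.e. tendency to give helpful advice
  (``x2``, a continuous tendency mapped to probability via the logistic);
* level 3 — the volatility of the adviser's intentions (``x3``), which sets
  how quickly fidelity is allowed to drift.

Beliefs are Gaussian, summarised by mean ``mu`` and variance ``sigma``
(precision ``pi = 1/sigma``); hatted quantities are predictions before the
trial's input is observed. Each belief update is a prediction error from the
level below weighted by a ratio of precisions — sensory precision in the
numerator amplifies updates, belief precision in the denominator damps them.

Update equations per trial k (previous-trial posteriors on the right):

    muhat1 = logistic(mu2)            pihat1 = 1 / (muhat1 (1 - muhat1))
    delta1 = u - muhat1
    sigmahat2 = sigma2 + exp(kappa mu3 + omega)      pihat2 = 1/sigmahat2
    pi2 = pihat2 + muhat1 (1 - muhat1)               sigma2' = 1/pi2
    mu2' = mu2 + sigma2' delta1
    delta2 = (sigma2' + (mu2' - mu2)^2) / sigmahat2 - 1
    w2 = exp(kappa mu3 + omega) / sigmahat2
    pihat3 = 1 / (sigma3 + theta)
    pi3 = pihat3 + (kappa^2 / 2) w2 (w2 + (2 w2 - 1) delta2)
    sigma3' = 1/pi3
    mu3' = mu3 + sigma3' (kappa/2) w2 delta2

The level-2 posterior variance ``sigma2'`` doubles as the effective learning
rate on the level-1 prediction error; it equals the precision ratio
``pihat1-weighted`` form of the generic precision-weighted update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PerceptionParams",
    "BeliefTrajectory",
    "FilterRegimeError",
    "filter_beliefs",
    "filter_beliefs_two_level",
    "precision_ratio",
]

#: Clipping bound on the level-1 prediction, for numerical stability of
#: pihat1 at extreme beliefs.
MUHAT1_EPS = 1e-8


class FilterRegimeError(ValueError):
    """Raised when a parameter regime produces a non-positive precision.

    Attributes
    ----------
    trial:
        1-based index of the trial at which the update became invalid.
    """

    def __init__(self, message: str, trial: int):
        super().__init__(message)
        self.trial = trial


@dataclass(frozen=True)
class PerceptionParams:
    """Perceptual parameters of the 3-level binary HGF.

    Parameters
    ----------
    kappa:
        Coupling strength of volatility (level 3) onto fidelity drift
        (level 2); >= 0. kappa = 0 decouples the levels exactly.
    omega:
        Tonic log-volatility at level 2; higher omega means a larger
        variance step per trial and hence a higher learning rate.
    theta:
        Variance of the volatility random walk at level 3; > 0.
    mu2_0, sigma2_0:
        Prior mean / variance of fidelity. mu2_0 < 0 encodes a prior that
        the adviser tends to mislead.
    mu3_0, sigma3_0:
        Prior mean / variance of log-volatility.
    """

    kappa: float = 1.0
    omega: float = -2.0
    theta: float = 0.5
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        for name in ("theta", "sigma2_0", "sigma3_0"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")


#: Column order of trajectory exports.
TRAJECTORY_COLUMNS = (
    "muhat1",
    "pihat1",
    "delta1",
    "mu2",
    "sigma2",
    "pi2",
    "pihat2",
    "sigmahat2",
    "delta2",
    "mu3",
    "sigma3",
    "pi3",
    "pihat3",
    "lr2",
)


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial predictions and posteriors of the filter.

    All arrays have one entry per trial (1-based trial k stored at index
    k-1). Posterior arrays at "trial 0" are the priors, available via
    ``params``. ``lr2`` is the effective level-2 learning rate, i.e. the
    posterior variance sigma2 after the update.
    """

    params: PerceptionParams
    inputs: np.ndarray
    muhat1: np.ndarray
    pihat1: np.ndarray
    delta1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    pi2: np.ndarray
    pihat2: np.ndarray
    sigmahat2: np.ndarray
    delta2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    pi3: np.ndarray
    pihat3: np.ndarray
    lr2: np.ndarray

    def __len__(self) -> int:
        return len(self.inputs)

    def to_frame(self) -> pd.DataFrame:
        data = {"trial": np.arange(1, len(self) + 1), "u": self.inputs}
        for c in TRAJECTORY_COLUMNS:
            data[c] = getattr(self, c)
        return pd.DataFrame(data)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def mu2_prev(self) -> np.ndarray:
        """Level-2 posterior mean before each trial's update (prior first)."""
        return np.concatenate([[self.params.mu2_0], self.mu2[:-1]])

    def mu3_prev(self) -> np.ndarray:
        return np.concatenate([[self.params.mu3_0], self.mu3[:-1]])


def _validate_inputs(inputs) -> np.ndarray:
    u = np.asarray(inputs)
    if u.size == 0:
        raise ValueError("input series is empty")
    if not np.isin(u, (0, 1)).all():
        raise ValueError("inputs must be binary (0/1)")
    return u.astype(np.float64).ravel()


def _logistic(x: float) -> float:
    # numerically safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def filter_beliefs(
    inputs: Sequence[int], params: PerceptionParams
) -> BeliefTrajectory:
    """Run the 3-level binary HGF over a binary input series.

    Raises
    ------
    FilterRegimeError
        If the level-3 precision becomes non-positive at some trial; the
        offending (1-based) trial is carried on the exception.
    ValueError
        For non-binary or empty inputs.
    """
    u = _validate_inputs(inputs)
    n = len(u)
    p = params
    out = {c: np.empty(n) for c in TRAJECTORY_COLUMNS}

    mu2, sigma2 = p.mu2_0, p.sigma2_0
    mu3, sigma3 = p.mu3_0, p.sigma3_0
    kappa, omega, theta = p.kappa, p.omega, p.theta

    for k in range(n):
        muhat1 = _logistic(mu2)
        muhat1 = min(max(muhat1, MUHAT1_EPS), 1.0 - MUHAT1_EPS)
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
        delta1 = u[k] - muhat1

        expo = kappa * mu3 + omega
        if expo > 700.0:  # exp would overflow: diverged volatility estimate
            raise FilterRegimeError(
                f"volatility estimate diverged (exponent {expo:.3g}) at trial "
                f"{k + 1}; parameter regime invalid",
                trial=k + 1,
            )
        vol = math.exp(expo)
        sigmahat2 = sigma2 + vol
        pihat2 = 1.0 / sigmahat2
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        sigma2_new = 1.0 / pi2
        mu2_new = mu2 + sigma2_new * delta1

        delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1.0
        w2 = vol / sigmahat2
        pihat3 = 1.0 / (sigma3 + theta)
        pi3 = pihat3 + (kappa**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0:
            raise FilterRegimeError(
                f"level-3 precision became non-positive ({pi3:.3g}) at trial "
                f"{k + 1}; parameter regime invalid",
                trial=k + 1,
            )
        sigma3_new = 1.0 / pi3
        mu3_new = mu3 + sigma3_new * (kappa / 2.0) * w2 * delta2

        out["muhat1"][k] = muhat1
        out["pihat1"][k] = pihat1
        out["delta1"][k] = delta1
        out["sigmahat2"][k] = sigmahat2
        out["pihat2"][k] = pihat2
        out["pi2"][k] = pi2
        out["sigma2"][k] = sigma2_new
        out["mu2"][k] = mu2_new
        out["lr2"][k] = sigma2_new
        out["delta2"][k] = delta2
        out["pihat3"][k] = pihat3
        out["pi3"][k] = pi3
        out["sigma3"][k] = sigma3_new
        out["mu3"][k] = mu3_new

        mu2, sigma2 = mu2_new, sigma2_new
        mu3, sigma3 = mu3_new, sigma3_new

    return BeliefTrajectory(params=p, inputs=u.astype(np.int64), **out)


def filter_beliefs_two_level(
    inputs: Sequence[int], params: PerceptionParams
) -> BeliefTrajectory:
    """Two-level (fixed-volatility) variant: level 3 removed.

    The level-2 variance step is a constant exp(omega); kappa and the
    level-3 priors are ignored. Level-3 fields in the returned trajectory
    are NaN (delta2 is still computed from level-2 quantities).
    """
    u = _validate_inputs(inputs)
    n = len(u)
    p = params
    out = {c: np.empty(n) for c in TRAJECTORY_COLUMNS}
    for c in ("mu3", "sigma3", "pi3", "pihat3"):
        out[c].fill(np.nan)

    mu2, sigma2 = p.mu2_0, p.sigma2_0
    vol = math.exp(p.omega)

    for k in range(n):
        muhat1 = _logistic(mu2)
        muhat1 = min(max(muhat1, MUHAT1_EPS), 1.0 - MUHAT1_EPS)
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
        delta1 = u[k] - muhat1

        sigmahat2 = sigma2 + vol
        pihat2 = 1.0 / sigmahat2
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        sigma2_new = 1.0 / pi2
        mu2_new = mu2 + sigma2_new * delta1
        delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1.0

        out["muhat1"][k] = muhat1
        out["pihat1"][k] = pihat1
        out["delta1"][k] = delta1
        out["sigmahat2"][k] = sigmahat2
        out["pihat2"][k] = pihat2
        out["pi2"][k] = pi2
        out["sigma2"][k] = sigma2_new
        out["mu2"][k] = mu2_new
        out["lr2"][k] = sigma2_new
        out["delta2"][k] = delta2

        mu2, sigma2 = mu2_new, sigma2_new

    return BeliefTrajectory(params=p, inputs=u.astype(np.int64), **out)


def precision_ratio(traj: BeliefTrajectory) -> np.ndarray:
    """Per-trial sensory-to-belief precision ratio pihat1 / pi2 at level 2.

    This is the ratio that scales the level-1 prediction error in the
    level-2 belief update; strictly positive by construction.
    """
    return traj.pihat1 / traj.pi2
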