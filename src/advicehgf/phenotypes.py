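"""Phenotype presets and contrastive agent simulations.

The sensory-vs-belief precision imbalance hypothesis for the psychosis
spectrum is expressed as three named agent presets:

* ``healthy`` — reference parameters; balanced precision weighting.
* ``prodromal`` — elevated tonic log-volatility omega, which inflates the
  level-2 variance step and hence the weight of sensory prediction errors
  on fidelity beliefs (the "increased sensory precision" stage): a high,
  unstable learning rate.
* ``delusional`` — consolidated, overly precise beliefs: low omega and
  kappa and a tight fidelity prior (small sigma2_0) suppress updating, a
  low volatility prior (mu3_0) encodes a rigid model of the adviser, and a
  negative fidelity prior mean (mu2_0 < 0) encodes the expectation that the
  adviser intends to mislead. Contradictory advice is "explained away".

Preset numbers are illustrative fixtures chosen to demonstrate the
qualitative predictions; they are not clinically calibrated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hgf import BeliefTrajectory, PerceptionParams, filter_beliefs
from .responses import (
    ChoiceSeries,
    ResponseParams,
    choice_probabilities,
    simulate_choices,
)
from .task import TaskConfig, TrialSequence, generate_task

__all__ = [
    "PhenotypePreset",
    "AgentSummary",
    "make_phenotype",
    "simulate_agent",
    "summarize_agent",
    "contrast_phenotypes",
    "PHENOTYPE_NAMES",
]

PHENOTYPE_NAMES = ("healthy", "prodromal", "delusional")


@dataclass(frozen=True)
class PhenotypePreset:
    name: str
    perception: PerceptionParams
    response: ResponseParams
    description: str


_PRESETS = {
    "healthy": PhenotypePreset(
        name="healthy",
        perception=PerceptionParams(
            kappa=1.0, omega=-2.0, theta=0.01,
            mu2_0=0.0, sigma2_0=1.0, mu3_0=1.0, sigma3_0=1.0,
        ),
        response=ResponseParams(zeta=5.0),
        description="Reference agent with balanced precision weighting.",
    ),
    "prodromal": PhenotypePreset(
        name="prodromal",
        perception=PerceptionParams(
            kappa=1.0, omega=-1.5, theta=0.01,
            mu2_0=0.0, sigma2_0=1.0, mu3_0=1.0, sigma3_0=1.0,
        ),
        response=ResponseParams(zeta=5.0),
        description=(
            "Elevated omega inflates the sensory-precision weighting of "
            "prediction errors: a high, unstable learning rate."
        ),
    ),
    "delusional": PhenotypePreset(
        name="delusional",
        perception=PerceptionParams(
            kappa=0.5, omega=-4.0, theta=0.01,
            mu2_0=-1.0, sigma2_0=0.5, mu3_0=0.0, sigma3_0=1.0,
        ),
        response=ResponseParams(zeta=5.0),
        description=(
            "Overly precise beliefs: reduced volatility estimate, low tonic "
            "learning rate and a negative prior on the adviser's fidelity."
        ),
    ),
}


def make_phenotype(name: str) -> PhenotypePreset:
    """Return the named preset; raises KeyError for unknown names."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown phenotype {name!r}; known: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class AgentSummary:
    """Scalar summaries of one simulated agent run.

    ``post_contradiction_update`` is the mean |change in mu2| on trials
    whose input contradicted the current belief (advice accuracy u on the
    opposite side of 0.5 from the prediction muhat1) — the behavioural
    signature of "explaining away" when small.
    """

    mean_lr2: float
    final_mu3: float
    mean_mu3: float
    take_rate: float
    mean_abs_delta1: float
    post_contradiction_update: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_agent(traj: BeliefTrajectory, choices: ChoiceSeries) -> AgentSummary:
    """Pure function of (trajectory, choices) -> summary statistics."""
    dmu2 = traj.mu2 - traj.mu2_prev()
    contradiction = (traj.inputs - 0.5) * (traj.muhat1 - 0.5) < 0
    post = float(np.abs(dmu2[contradiction]).mean()) if contradiction.any() else 0.0
    return AgentSummary(
        mean_lr2=float(traj.lr2.mean()),
        final_mu3=float(traj.mu3[-1]),
        mean_mu3=float(traj.mu3.mean()),
        take_rate=float(choices.took_advice.mean()),
        mean_abs_delta1=float(np.abs(traj.delta1).mean()),
        post_contradiction_update=post,
    )


def simulate_agent(
    seq: TrialSequence, preset: PhenotypePreset, seed: int = 0
) -> tuple[BeliefTrajectory, ChoiceSeries, AgentSummary]:
    """Full pipeline task -> filter -> choices -> summary for one agent."""
    traj = filter_beliefs(seq.inputs, preset.perception)
    p_take = choice_probabilities(traj, preset.response)
    choices = simulate_choices(p_take, seed=seed)
    return traj, choices, summarize_agent(traj, choices)


def contrast_phenotypes(
    config: TaskConfig,
    presets: Sequence[PhenotypePreset],
    n_seeds: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Contrast presets across task realisations.

    For each of ``n_seeds`` seeds a fresh task is generated from ``config``
    (the seed replaces ``config.seed``) and every preset is simulated on the
    same realisation. Returns one row per (seed, preset) with the
    AgentSummary fields; aggregate with ``groupby("phenotype")``.
    """
    if len(presets) < 2:
        raise ValueError("need at least two presets to contrast")
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    rows = []
    for s in seeds:
        cfg = TaskConfig(**{**config.to_dict(), "seed": int(s)})
        seq = generate_task(cfg)
        for preset in presets:
            _, _, summary = simulate_agent(seq, preset, seed=int(s))
            rows.append({"seed": int(s), "phenotype": preset.name, **summary.to_dict()})
    return pd.DataFrame(rows)
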