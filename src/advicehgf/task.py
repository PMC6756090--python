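"""Synthetic volatile advice-taking task.

A player predicts the outcome of a binary lottery. An adviser receives a
private cue that matches the true outcome with fixed probability
(``cue_validity``, 0.8 by default) and passes on advice that either follows
the cue (helpful intention) or inverts it (misleading intention). The
adviser's intention is volatile: the probability of being helpful changes
between phases of the game. A non-intentional control variant replaces the
adviser with a "card deck" whose advice is correct i.i.d. with a fixed
probability, removing intentionality while preserving advice statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "TaskConfig",
    "TrialRecord",
    "TrialSequence",
    "ConfigurationError",
    "generate_task",
    "summarize_phases",
    "default_schedule",
    "default_config",
]

#: CSV column order for trial logs.
TRIAL_LOG_COLUMNS = (
    "trial",
    "outcome",
    "intention",
    "private_cue",
    "advice",
    "advice_correct",
)


class ConfigurationError(ValueError):
    """Raised for an invalid task configuration."""


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class Phase:
    """A contiguous block of trials with a fixed helpful-intention rate."""

    length: int
    p_helpful: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ConfigurationError(f"phase length must be >= 0, got {self.length}")
        _check_probability("p_helpful", self.p_helpful)


def default_schedule() -> tuple[Phase, ...]:
    """Default volatile schedule: 160 trials, six phases alternating
    mostly-helpful (p=0.9) and mostly-misleading (p=0.1) intentions."""
    lengths = (30, 20, 30, 30, 20, 30)
    ps = (0.9, 0.1, 0.9, 0.1, 0.9, 0.1)
    return tuple(Phase(n, p) for n, p in zip(lengths, ps))


@dataclass(frozen=True)
class TaskConfig:
    """Full specification of a task run.

    Parameters
    ----------
    n_trials:
        Total number of trials; must equal the sum of phase lengths.
    cue_validity:
        Probability that the adviser's private cue matches the lottery
        outcome (default 0.8).
    phases:
        Ordered phases, each with a length and a helpful-intention
        probability. Intention is resampled independently on every trial
        within a phase.
    control_mode:
        If True, run the non-intentional card-deck control: advice is
        correct i.i.d. with probability ``deck_accuracy`` and intention is
        recorded as ``"none"``.
    deck_accuracy:
        Probability of correct advice in control mode.
    seed:
        Seed for the task's random number generator. Identical
        (config, seed) pairs produce bitwise-identical trial logs.
    """

    n_trials: int
    phases: tuple[Phase, ...] = field(default_factory=default_schedule)
    cue_validity: float = 0.8
    control_mode: bool = False
    deck_accuracy: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigurationError(f"n_trials must be positive, got {self.n_trials}")
        phases = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phases
        )
        object.__setattr__(self, "phases", phases)
        _check_probability("cue_validity", self.cue_validity)
        _check_probability("deck_accuracy", self.deck_accuracy)
        total = sum(p.length for p in phases)
        if total != self.n_trials:
            raise ConfigurationError(
                f"phase lengths sum to {total}, expected n_trials={self.n_trials}"
            )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "cue_validity": self.cue_validity,
            "phases": [[p.length, p.p_helpful] for p in self.phases],
            "control_mode": self.control_mode,
            "deck_accuracy": self.deck_accuracy,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        d["phases"] = tuple(Phase(int(n), float(p)) for n, p in d["phases"])
        return cls(**d)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TaskConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_config(seed: int = 0, n_reps: int = 1, **kwargs) -> TaskConfig:
    """Default 160-trial volatile task; ``n_reps`` tiles the schedule
    (n_reps=2 gives the 320-trial variant used for fitting studies)."""
    phases = default_schedule() * n_reps
    n = sum(p.length for p in phases)
    return TaskConfig(n_trials=n, phases=phases, seed=seed, **kwargs)


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the advice-taking task."""

    trial_index: int  # 1-based
    outcome: int
    intention: str  # {"helpful", "misleading", "none"}
    private_cue: int
    advice: int
    advice_correct: int


@dataclass(frozen=True)
class TrialSequence:
    """A generated task: config plus per-trial arrays.

    Arrays are aligned, length ``config.n_trials``; ``phase_index`` maps each
    trial to its phase (0-based).
    """

    config: TaskConfig
    outcome: np.ndarray
    intention: np.ndarray
    private_cue: np.ndarray
    advice: np.ndarray
    advice_correct: np.ndarray
    phase_index: np.ndarray

    def __len__(self) -> int:
        return len(self.outcome)

    @property
    def records(self) -> list[TrialRecord]:
        return [
            TrialRecord(
                trial_index=k + 1,
                outcome=int(self.outcome[k]),
                intention=str(self.intention[k]),
                private_cue=int(self.private_cue[k]),
                advice=int(self.advice[k]),
                advice_correct=int(self.advice_correct[k]),
            )
            for k in range(len(self))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "outcome": self.outcome,
                "intention": self.intention,
                "private_cue": self.private_cue,
                "advice": self.advice,
                "advice_correct": self.advice_correct,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def inputs(self) -> np.ndarray:
        """Observer input series u: 1 iff advice matched the outcome."""
        return self.advice_correct.astype(np.int64)


def generate_task(config: TaskConfig) -> TrialSequence:
    """Generate a task sequence from a config.

    On each trial the lottery outcome is Bernoulli(0.5) over {0, 1} and the
    private cue equals the outcome with probability ``cue_validity``. The
    intention is helpful with the phase's ``p_helpful`` (resampled every
    trial), and the advice follows the cue when helpful, inverts it when
    misleading. In control mode the advice is correct i.i.d. with
    probability ``deck_accuracy`` and no intention or private cue exists
    (the cue column simply mirrors the advice).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    outcome = rng.integers(0, 2, size=n)

    phase_index = np.repeat(
        np.arange(len(config.phases)), [p.length for p in config.phases]
    )

    if config.control_mode:
        advice_correct = (rng.random(n) < config.deck_accuracy).astype(np.int64)
        advice = np.where(advice_correct == 1, outcome, 1 - outcome)
        intention = np.full(n, "none", dtype=object)
        private_cue = advice.copy()
    else:
        cue_hit = rng.random(n) < config.cue_validity
        private_cue = np.where(cue_hit, outcome, 1 - outcome)
        p_helpful = np.array([p.p_helpful for p in config.phases])[phase_index]
        helpful = rng.random(n) < p_helpful
        advice = np.where(helpful, private_cue, 1 - private_cue)
        intention = np.where(helpful, "helpful", "misleading").astype(object)
        advice_correct = (advice == outcome).astype(np.int64)

    return TrialSequence(
        config=config,
        outcome=outcome.astype(np.int64),
        intention=np.asarray(intention, dtype=object),
        private_cue=np.asarray(private_cue, dtype=np.int64),
        advice=np.asarray(advice, dtype=np.int64),
        advice_correct=advice_correct,
        phase_index=phase_index,
    )


def summarize_phases(seq: TrialSequence) -> pd.DataFrame:
    """Per-phase realized advice accuracy.

    Returns one row per non-empty phase with columns ``phase`` (0-based),
    ``length``, ``p_helpful`` and ``advice_accuracy`` (mean advice_correct).
    """
    if len(seq) == 0:
        raise ValueError("empty trial sequence")
    rows = []
    for i, phase in enumerate(seq.config.phases):
        mask = seq.phase_index == i
        if not mask.any():
            continue  # vacuous phase
        rows.append(
            {
                "phase": i,
                "length": int(mask.sum()),
                "p_helpful": phase.p_helpful,
                "advice_accuracy": float(seq.advice_correct[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
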