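"""Synthetic participants: softmax-noisy strategy agents over full schedules.

Agents are static ideal observers corrupted by softmax choice noise: on
each categorisation trial the chosen category is sampled from the softmax
(at the agent's temperature) of the generating model's prediction vector.
Feedback affects nothing but metadata — the models do not learn. The
module also provides the model-recovery experiment (simulate every roster
model, refit the full roster, tabulate the confusion of generating versus
selected model) and simple mapping-task agents whose expected accuracies
anchor the mapping analytics (chance 1/16, single-dimension attender 1/4).

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
spawns, so cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ParticipantDataset, select_best, softmax_choice_probs
from .models import (
    ModelSpec,
    PredictionContext,
    get_model,
    model_roster,
    prediction_matrix,
)
from .task import GRID_SIZE, MappingTrial, TrialSchedule, build_schedule

RECOVERY_TEMPERATURES = (0.05, 0.2, 0.35, 0.5)


@dataclass(frozen=True)
class AgentSpec:
    """A generating strategy model plus its softmax temperature and seed."""

    generating_model: str
    beta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        get_model(self.generating_model)  # validates the name


@dataclass
class RecoveryResult:
    """Generating-model x selected-model confusion, one matrix per beta."""

    confusion: dict[float, pd.DataFrame]
    n_per_model: int
    transfer_kind: str

    def recovery_rate(self, beta: float) -> pd.Series:
        """Diagonal fraction per generating model at one temperature."""
        mat = self.confusion[beta]
        diag = pd.Series(np.diag(mat.loc[mat.index, mat.index]), index=mat.index)
        return diag / mat.sum(axis=1)


def simulate_participant(agent: AgentSpec, schedule: TrialSchedule,
                         participant_id: str | None = None) -> ParticipantDataset:
    """Sample one synthetic participant's choices over a schedule."""
    trials = schedule.quadruplet_trials
    context = PredictionContext(schedule.trained_rotations)
    spec = get_model(agent.generating_model)
    probs = softmax_choice_probs(
        prediction_matrix(spec, context, trials), agent.beta
    )
    rng = np.random.default_rng(agent.seed)
    u = rng.random(len(trials))
    choices = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return ParticipantDataset(
        participant_id or f"{agent.generating_model}_b{agent.beta:g}_s{agent.seed}",
        trials,
        choices,
        context,
        meta={
            "generating_model": agent.generating_model,
            "beta": agent.beta,
            "seed": agent.seed,
            "experiment_id": schedule.experiment_id,
        },
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(models, beta: float, n_per_model: int, experiment_id: str,
                    seed: int = 0) -> list[ParticipantDataset]:
    """Independent seeded agents, ``n_per_model`` per generating model.

    Each agent receives its own pseudo-randomised schedule, mirroring the
    per-participant randomisation of the experiments.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    names = [m.name if isinstance(m, ModelSpec) else m for m in models]
    seeds = _spawn_seeds(seed, 2 * len(names) * n_per_model)
    out = []
    k = 0
    for name in names:
        for rep in range(n_per_model):
            schedule = build_schedule(experiment_id, seeds[k])
            agent = AgentSpec(name, beta, seeds[k + 1])
            k += 2
            out.append(simulate_participant(
                agent, schedule, participant_id=f"{name}_{rep:03d}"))
    return out


def run_model_recovery(experiment_id: str = "1a",
                       temperatures=RECOVERY_TEMPERATURES,
                       n_per_model: int = 100,
                       seed: int = 0,
                       transfer_kind: str = "near") -> RecoveryResult:
    """Simulate every roster model, refit the roster, tabulate confusion."""
    temperatures = tuple(temperatures)
    if any(b <= 0 for b in temperatures):
        raise ValueError("temperatures must be positive")
    names = [m.name for m in model_roster(transfer_kind)]
    confusion = {}
    for b_idx, beta in enumerate(temperatures):
        mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
        cohort = simulate_cohort(names, beta, n_per_model, experiment_id,
                                 seed=seed * 7919 + b_idx)
        for ds in cohort:
            sel = select_best(ds, transfer_kind)
            mat.loc[ds.meta["generating_model"], sel.best_model] += 1
        confusion[beta] = mat
    return RecoveryResult(confusion, n_per_model, transfer_kind)


# ---------------------------------------------------------------------------
# mapping-task agents
# ---------------------------------------------------------------------------

MAPPING_AGENT_KINDS = ("random", "one_dimension", "perfect")


def expected_mapping_accuracy(kind: str) -> float:
    """Exact expected accuracy: chance 1/16, one dimension 1/4, perfect 1."""
    return {"random": 1.0 / 16.0, "one_dimension": 0.25, "perfect": 1.0}[kind]


def simulate_mapping_agent(kind: str, trials: list[MappingTrial],
                           seed: int = 0) -> float:
    """Proportion correct of a mapping agent over a block list.

    ``random`` guesses uniformly over the 16 cells; ``one_dimension``
    attends one dimension (chosen once per agent), answers its level
    correctly and guesses the other uniformly; ``perfect`` is always right.
    """
    if kind not in MAPPING_AGENT_KINDS:
        raise ValueError(f"unknown mapping agent kind {kind!r}")
    if not trials:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed)
    if kind == "perfect":
        return 1.0
    n_correct = 0
    attended = int(rng.integers(2))  # fixed per agent
    for t in trials:
        if kind == "random":
            resp = (int(rng.integers(GRID_SIZE)), int(rng.integers(GRID_SIZE)))
        else:
            guess = int(rng.integers(GRID_SIZE))
            resp = ((t.target_cell[0], guess) if attended == 0
                    else (guess, t.target_cell[1]))
        n_correct += resp == tuple(t.target_cell)
    return n_correct / len(trials)
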