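"""Ideal-observer strategy models for quadruplet categorisation.

Each model assigns a probability vector over the three categories to any
trial. The roster comprises:

* ``R`` — responds uniformly at random (the null model, no parameters).
* ``Rp`` — the "non-generaliser": responds with the true category on
  feedback-trained trials and uniformly on transfer trials.
* ``1Di_u``/``1Dj_u`` — track the *unsigned* level pattern (e.g. ABAB vs
  ABBA) on a single dimension; a pattern and its A<->B swap are identified.
* ``1Di_s``/``1Dj_s`` — track the *signed* pattern on one dimension.
* ``2D`` — matches the full transition-vector sequence against every
  rotation of the three category templates (rotation- and
  translation-invariant by construction).
* ``1Dij_u``, ``1Dji_u``, ``1Dij_s``, ``1Dji_s`` — far-transfer variants of
  the 1D models that re-map dimensions between manifolds (e.g. ``1Dij_u``
  tracks unsigned patterns on ``i`` during training but reads the far
  manifold's ``j`` dimension as if it were ``i``).

1D models are *idealised on the training distribution*: the mapping from
pattern to category posterior is derived by enumerating every category x
trained-rotation x anchor exemplar, weighting exemplars equally. Patterns
never seen in training yield a uniform prediction. All models are static
(memoryless ideal observers, not learners).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .task import (
    N_CATEGORIES,
    ROTATIONS,
    QuadrupletTrial,
    canonical_templates,
    enumerate_quadruplets,
    pattern_of,
    rotate_template,
)

NEAR_MODELS = ("R", "Rp", "1Di_u", "1Dj_u", "1Di_s", "1Dj_s", "2D")
FAR_EXTRA_MODELS = ("1Dij_u", "1Dji_u", "1Dij_s", "1Dji_s")
TRAINING_PHASES = ("pretraining", "training")

_UNIFORM = np.full(N_CATEGORIES, 1.0 / N_CATEGORIES)


@dataclass(frozen=True)
class PredictionContext:
    """The training distribution a model is idealised on."""

    trained_rotations: tuple[int, ...] = (0,)
    transfer_kind: str = "near"

    def __post_init__(self) -> None:
        if not self.trained_rotations:
            raise ValueError("trained_rotations must be non-empty")
        if any(r not in ROTATIONS for r in self.trained_rotations):
            raise ValueError("rotations must be multiples of 90 in [0, 270]")
        if self.transfer_kind not in ("near", "far"):
            raise ValueError("transfer_kind must be 'near' or 'far'")


@dataclass(frozen=True)
class ModelSpec:
    """Name, family and dimension bookkeeping for one strategy model."""

    name: str
    family: str  # random | 1D | 2D
    tracked_dimension: str | None = None
    signed: bool = False
    far_dimension: str | None = None  # dimension read on far-transfer trials

    @property
    def n_params(self) -> int:
        """k = 0 for the parameter-free random model, 1 (temperature) otherwise."""
        return 0 if self.name == "R" else 1


_SPECS = {
    "R": ModelSpec("R", "random"),
    "Rp": ModelSpec("Rp", "random"),
    "1Di_u": ModelSpec("1Di_u", "1D", "i", False, "i"),
    "1Dj_u": ModelSpec("1Dj_u", "1D", "j", False, "j"),
    "1Di_s": ModelSpec("1Di_s", "1D", "i", True, "i"),
    "1Dj_s": ModelSpec("1Dj_s", "1D", "j", True, "j"),
    "2D": ModelSpec("2D", "2D"),
    "1Dij_u": ModelSpec("1Dij_u", "1D", "i", False, "j"),
    "1Dji_u": ModelSpec("1Dji_u", "1D", "j", False, "i"),
    "1Dij_s": ModelSpec("1Dij_s", "1D", "i", True, "j"),
    "1Dji_s": ModelSpec("1Dji_s", "1D", "j", True, "i"),
}


def get_model(name: str) -> ModelSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}") from None


def model_roster(transfer_kind: str = "near") -> list[ModelSpec]:
    """Seven models for near transfer, eleven for far transfer."""
    if transfer_kind == "near":
        return [_SPECS[n] for n in NEAR_MODELS]
    if transfer_kind == "far":
        return [_SPECS[n] for n in NEAR_MODELS + FAR_EXTRA_MODELS]
    raise ValueError("transfer_kind must be 'near' or 'far'")


@lru_cache(maxsize=None)
def _ideal_mapping(dimension: str, signed: bool, trained_rotations: tuple[int, ...]):
    """Pattern -> category-posterior over the trained distribution."""
    counts: dict[str, np.ndarray] = {}
    for trial in enumerate_quadruplets(trained_rotations):
        token = pattern_of(trial, dimension, signed=signed)
        counts.setdefault(token, np.zeros(N_CATEGORIES))[trial.category] += 1.0
    return {tok: c / c.sum() for tok, c in counts.items()}


def derive_ideal_mapping(model: ModelSpec, context: PredictionContext) -> dict:
    """The 1D model's pattern -> prediction-vector lookup table."""
    if model.family != "1D":
        raise ValueError("ideal mappings are defined for 1D models only")
    mapping = _ideal_mapping(model.tracked_dimension, model.signed,
                             tuple(context.trained_rotations))
    return {tok: vec.copy() for tok, vec in mapping.items()}


@lru_cache(maxsize=None)
def _rotated_template_index():
    """(vector sequence) -> category, over all 3 categories x 4 rotations."""
    index = {}
    for template in canonical_templates():
        for rot in ROTATIONS:
            key = rotate_template(template, rot).vectors
            if key in index:  # pragma: no cover - ruled out by design
                raise RuntimeError("rotated templates are not pairwise distinct")
            index[key] = template.category
    return index


def _trial_vectors(trial: QuadrupletTrial) -> tuple[tuple[int, int], ...]:
    return tuple(
        (b[0] - a[0], b[1] - a[1])
        for a, b in zip(trial.positions[:-1], trial.positions[1:])
    )


def predict(model: ModelSpec, context: PredictionContext,
            trial: QuadrupletTrial) -> np.ndarray:
    """Probability the model assigns to each category for one trial."""
    if model.name == "R":
        return _UNIFORM.copy()
    if model.name == "Rp":
        if trial.phase in TRAINING_PHASES:
            out = np.zeros(N_CATEGORIES)
            out[trial.category] = 1.0
            return out
        return _UNIFORM.copy()
    if model.family == "2D":
        category = _rotated_template_index().get(_trial_vectors(trial))
        if category is None:
            raise ValueError("quadruplet matches no rotated category template")
        out = np.zeros(N_CATEGORIES)
        out[category] = 1.0
        return out
    # 1D models: read the tracked dimension, re-mapped on far-transfer trials
    dim = model.far_dimension if trial.transformation.far_transfer else model.tracked_dimension
    token = pattern_of(trial, dim, signed=model.signed)
    mapping = _ideal_mapping(model.tracked_dimension, model.signed,
                             tuple(context.trained_rotations))
    return mapping.get(token, _UNIFORM).copy()


def prediction_matrix(model: ModelSpec, context: PredictionContext,
                      trials) -> np.ndarray:
    """Stack ``predict`` over a trial list -> (T, 3) array."""
    return np.array([predict(model, context, t) for t in trials])


def training_accuracy(model: ModelSpec, context: PredictionContext) -> float:
    """Expected proportion correct over the uniform training distribution.

    Responses are argmax with ties broken uniformly, over all categories x
    trained rotations x nine anchors.
    """
    trials = enumerate_quadruplets(context.trained_rotations, phase="training")
    total = 0.0
    for trial in trials:
        p = predict(model, context, trial)
        winners = np.flatnonzero(p >= p.max() - 1e-12)
        if trial.category in winners:
            total += 1.0 / len(winners)
    return total / len(trials)


def expected_response_matrix(model: ModelSpec, context: PredictionContext,
                             transformation) -> np.ndarray:
    """3x3 matrix P(response | true category) for one transformation.

    Averages the model's prediction vectors over the nine anchors; this is
    the idealised (probability-matching) response matrix behind the
    model-prediction panels.
    """
    from .task import ANCHORS, realise_quadruplet

    phase = ("far_transfer" if transformation.far_transfer else
             ("training" if transformation.rotation in context.trained_rotations
              else "near_transfer"))
    out = np.zeros((N_CATEGORIES, N_CATEGORIES))
    for c in range(N_CATEGORIES):
        for a in ANCHORS:
            trial = realise_quadruplet(c, transformation, a, phase=phase,
                                       feedback=phase == "training")
            out[c] += predict(model, context, trial)
    return out / len(ANCHORS)


def prediction_table(context: PredictionContext, transfer_kind: str = "near"):
    """Audit dump: model x trial prediction vectors as a tidy DataFrame."""
    import pandas as pd
    from .task import ALL_TRANSFORMATIONS, ANCHORS, realise_quadruplet

    rows = []
    for model in model_roster(transfer_kind):
        for tf in ALL_TRANSFORMATIONS:
            phase = ("far_transfer" if tf.far_transfer else
                     ("training" if tf.rotation in context.trained_rotations
                      else "near_transfer"))
            for c in range(N_CATEGORIES):
                for a in ANCHORS:
                    trial = realise_quadruplet(c, tf, a, phase=phase,
                                               feedback=phase == "training")
                    p = predict(model, context, trial)
                    rows.append({
                        "model": model.name, "category": c,
                        "rotation_deg": tf.rotation,
                        "far_transfer": int(tf.far_transfer),
                        "anchor_i": a[0], "anchor_j": a[1],
                        "p0": p[0], "p1": p[1], "p2": p[2],
                    })
    return pd.DataFrame(rows)
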