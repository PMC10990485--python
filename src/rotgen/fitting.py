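"""Softmax choice likelihood, temperature fitting and BIC model selection.

A strategy model's category posterior ``p(c | Q, M)`` is converted into
choice probabilities through a softmax with temperature ``beta``::

    P(choice = c) = exp(p_c / beta) / sum_k exp(p_k / beta)

Larger ``beta`` means noisier choices (beta = 0.5 is a high-noise regime).
The single free parameter ``beta`` is fitted by exhaustive search over 200
linearly spaced values on the inclusive interval [0.01, 0.5]; ties go to
the smallest grid value. Model comparison uses the Bayesian information
criterion ``BIC = k ln(T) - 2 ln(L)`` with ``k = 0`` for the random model
``R`` and ``k = 1`` otherwise.

The core fit is exposed as the sklearn-style estimator
:class:`SoftmaxChoiceModel`; module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .models import (
    ModelSpec,
    PredictionContext,
    get_model,
    model_roster,
    prediction_matrix,
)
from .task import QuadrupletTrial

BETA_GRID = np.linspace(0.01, 0.5, 200)
FIT_PHASES = {
    "near": ("training", "near_transfer"),
    "far": ("training", "far_transfer"),
}


@dataclass
class ParticipantDataset:
    """Ordered choice records of one participant."""

    participant_id: str
    trials: list[QuadrupletTrial]
    choices: np.ndarray
    context: PredictionContext
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        if len(self.trials) != len(self.choices):
            raise ValueError("one choice per trial is required")
        if self.n_trials and not np.all((self.choices >= 0) & (self.choices <= 2)):
            raise ValueError("choices must be in {0, 1, 2}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, phases) -> "ParticipantDataset":
        keep = [k for k, t in enumerate(self.trials) if t.phase in phases]
        return ParticipantDataset(
            self.participant_id,
            [self.trials[k] for k in keep],
            self.choices[keep],
            self.context,
            dict(self.meta),
        )


@dataclass(frozen=True)
class FitResult:
    """Per participant x model: fitted temperature, max log-likelihood, BIC."""

    model: str
    beta_hat: float | None
    max_log_likelihood: float
    bic: float
    n_trials: int


@dataclass
class SelectionResult:
    """All per-model fits for one participant plus the BIC-best model."""

    participant_id: str
    transfer_kind: str
    fits: dict[str, FitResult]
    best_model: str

    def log_likelihood(self, model: str) -> float:
        return self.fits[model].max_log_likelihood


def softmax_choice_probs(p_matrix: np.ndarray, beta: float) -> np.ndarray:
    """Row-wise softmax of prediction vectors at temperature ``beta``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = np.asarray(p_matrix, dtype=float) / beta
    z -= z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def response_probability(p_vec, beta: float, chosen: int) -> float:
    """Softmax probability of one chosen category given a prediction vector."""
    return float(softmax_choice_probs(np.asarray(p_vec)[None, :], beta)[0, chosen])


def _grid_log_likelihoods(p_matrix: np.ndarray, choices: np.ndarray,
                          grid: np.ndarray) -> np.ndarray:
    """ln L at every grid temperature, vectorised: shape (len(grid),)."""
    # (G, T, 3): prediction vectors scaled by each candidate temperature
    z = p_matrix[None, :, :] / grid[:, None, None]
    lse = logsumexp(z, axis=2)
    chosen = z[:, np.arange(len(choices)), choices]
    return (chosen - lse).sum(axis=1)


class SoftmaxChoiceModel(BaseEstimator):
    """Sklearn-style estimator fitting one strategy model to choice data.

    Parameters
    ----------
    model : str
        Strategy model name (e.g. ``"2D"``, ``"1Di_u"``, ``"R"``).
    trained_rotations : tuple of int
        Rotations present in the feedback training set the ideal observer
        is idealised on ({0} for Exp. 1, {0, 90} for Exp. 2-4).
    beta_min, beta_max, n_beta : float, float, int
        The temperature search grid (inclusive endpoints).

    Attributes
    ----------
    beta_ : float or None
        Fitted temperature (``None`` for the parameter-free ``R`` model).
    log_likelihood_ : float
        Maximised log-likelihood.
    bic_ : float
        ``k ln(T) - 2 log_likelihood_``.
    n_trials_ : int
    """

    def __init__(self, model: str = "2D", trained_rotations=(0,),
                 beta_min: float = 0.01, beta_max: float = 0.5,
                 n_beta: int = 200):
        self.model = model
        self.trained_rotations = trained_rotations
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.n_beta = n_beta

    def _grid(self) -> np.ndarray:
        return np.linspace(self.beta_min, self.beta_max, self.n_beta)

    def _context(self) -> PredictionContext:
        return PredictionContext(tuple(self.trained_rotations))

    def fit(self, X, y):
        """Fit the temperature to trials ``X`` and chosen categories ``y``."""
        trials = list(X)
        choices = np.asarray(y, dtype=int)
        if len(trials) == 0:
            raise ValueError("cannot fit on an empty dataset")
        if len(trials) != len(choices):
            raise ValueError("X and y must have equal length")
        spec = get_model(self.model)
        p_matrix = prediction_matrix(spec, self._context(), trials)
        n = len(trials)
        if spec.n_params == 0:
            # uniform predictions: likelihood independent of temperature
            self.beta_ = None
            self.log_likelihood_ = float(n * np.log(1.0 / 3.0))
        else:
            grid = self._grid()
            lls = _grid_log_likelihoods(p_matrix, choices, grid)
            best = int(np.argmax(lls))  # first maximum -> smallest beta
            self.beta_ = float(grid[best])
            self.log_likelihood_ = float(lls[best])
        self.k_ = spec.n_params
        self.n_trials_ = n
        self.bic_ = float(self.k_ * np.log(n) - 2.0 * self.log_likelihood_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Choice probabilities at the fitted temperature."""
        spec = get_model(self.model)
        p_matrix = prediction_matrix(spec, self._context(), list(X))
        if self.beta_ is None:
            return np.full_like(p_matrix, 1.0 / 3.0)
        return softmax_choice_probs(p_matrix, self.beta_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y) -> float:
        """Mean per-trial log-likelihood at the fitted temperature."""
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        return float(np.mean(np.log(probs[np.arange(len(y)), y])))


def log_likelihood(model, dataset: ParticipantDataset, beta: float) -> float:
    """Summed log-likelihood of a dataset under one model at fixed beta."""
    if dataset.n_trials == 0:
        raise ValueError("empty dataset")
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    p_matrix = prediction_matrix(spec, dataset.context, dataset.trials)
    probs = softmax_choice_probs(p_matrix, beta)
    return float(np.log(probs[np.arange(dataset.n_trials), dataset.choices]).sum())


def fit_model(model, dataset: ParticipantDataset) -> FitResult:
    """Grid-fit one model to one participant's dataset."""
    name = model.name if isinstance(model, ModelSpec) else model
    est = SoftmaxChoiceModel(
        model=name, trained_rotations=dataset.context.trained_rotations
    ).fit(dataset.trials, dataset.choices)
    return FitResult(name, est.beta_, est.log_likelihood_, est.bic_, est.n_trials_)


def select_best(dataset: ParticipantDataset,
                transfer_kind: str = "near") -> SelectionResult:
    """Fit the roster on training + requested transfer trials; best = min BIC."""
    if transfer_kind not in FIT_PHASES:
        raise ValueError("transfer_kind must be 'near' or 'far'")
    sub = dataset.subset(FIT_PHASES[transfer_kind])
    if sub.n_trials == 0:
        raise ValueError(
            f"dataset has no trials in phases {FIT_PHASES[transfer_kind]}"
        )
    fits = {m.name: fit_model(m, sub) for m in model_roster(transfer_kind)}
    best = min(fits.values(), key=lambda f: f.bic).model
    return SelectionResult(dataset.participant_id, transfer_kind, fits, best)


def crossval_split(dataset: ParticipantDataset):
    """Split by 0-based trial-position parity: (even half, odd half).

    Models are fitted on the even half; held-out response matrices use the
    odd half.
    """
    if dataset.n_trials < 2:
        raise ValueError("need at least two trials to split")
    even = [k for k in range(dataset.n_trials) if k % 2 == 0]
    odd = [k for k in range(dataset.n_trials) if k % 2 == 1]

    def _take(idx):
        return ParticipantDataset(
            dataset.participant_id,
            [dataset.trials[k] for k in idx],
            dataset.choices[idx],
            dataset.context,
            dict(dataset.meta),
        )

    return _take(even), _take(odd)


def response_matrix(trials, choices, transformation) -> np.ndarray:
    """Row-normalised 3x3 confusion P(response | true category).

    Restricted to trials carrying ``transformation``; rows with no trials
    are left as zeros.
    """
    counts = np.zeros((3, 3))
    for t, c in zip(trials, np.asarray(choices, dtype=int)):
        if t.transformation == transformation:
            counts[t.category, c] += 1.0
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
    return out


def fits_to_frame(selections) -> pd.DataFrame:
    """Tidy participant x model fit table (beta, lnL, BIC, best flag)."""
    rows = []
    for sel in selections:
        for name, f in sel.fits.items():
            rows.append({
                "participant_id": sel.participant_id,
                "transfer_kind": sel.transfer_kind,
                "model": name,
                "beta_hat": np.nan if f.beta_hat is None else f.beta_hat,
                "log_likelihood": f.max_log_likelihood,
                "bic": f.bic,
                "n_trials": f.n_trials,
                "best": int(name == sel.best_model),
            })
    return pd.DataFrame(rows)
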