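"""Dual-learning-rate Q-learning likelihood core.

Value learning follows a temporal-difference rule with separate learning
rates for positive and negative prediction errors,

    Q_s(t+1) = Q_s(t) + alpha_G [r(t) - Q_s(t)]_+ + alpha_L [r(t) - Q_s(t)]_-,

applied to the chosen symbol only, and choices follow the softmax rule

    P(left) = exp(beta Q_left) / (exp(beta Q_left) + exp(beta Q_right)),

with inverse temperature beta.  The single-rate variant constrains
alpha_G = alpha_L.  All heavy loops are numba-compiled; the public
functions accept the trial tables produced by the cohort simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "AgentParams",
    "ModelVariant",
    "initialize_q",
    "update_q",
    "choice_probability",
    "sequence_loglik",
    "DatasetArrays",
    "dataset_arrays",
    "loglik_from_arrays",
]

DEFAULT_Q_INIT = 0.5


@dataclass(frozen=True)
class AgentParams:
    """Natural-scale Q-learning parameters for one subject-in-condition dataset."""

    alpha_gain: float
    alpha_loss: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_gain <= 1.0:
            raise ValueError("alpha_gain must lie in [0, 1]")
        if not 0.0 <= self.alpha_loss <= 1.0:
            raise ValueError("alpha_loss must lie in [0, 1]")
        if not (np.isfinite(self.beta) and self.beta >= 0.0):
            raise ValueError("beta must be finite and non-negative")


class ModelVariant(str, Enum):
    """dual_rate: separate gain/loss learning rates; single_rate: alpha_G = alpha_L."""

    DUAL_RATE = "dual_rate"
    SINGLE_RATE = "single_rate"


def initialize_q(symbols, init: float = DEFAULT_Q_INIT) -> dict[str, float]:
    """Fresh Q-table with every symbol at the configured initial value."""
    symbols = list(symbols)
    if len(set(symbols)) != len(symbols):
        raise ValueError("symbols must be distinct")
    return {s: float(init) for s in symbols}


def update_q(q: float, reward: float, alpha_gain: float, alpha_loss: float) -> float:
    """One value update: positive prediction errors scaled by alpha_gain, negative by alpha_loss."""
    if not 0.0 <= alpha_gain <= 1.0 or not 0.0 <= alpha_loss <= 1.0:
        raise ValueError("learning rates must lie in [0, 1]")
    pe = reward - q
    return q + alpha_gain * max(pe, 0.0) + alpha_loss * min(pe, 0.0)


def choice_probability(q_left: float, q_right: float, beta: float):
    """Softmax probability of choosing the left option; stable for large beta."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    from scipy.special import expit

    return expit(beta * (np.asarray(q_left, dtype=float) - np.asarray(q_right, dtype=float)))


@njit(cache=True)
def _loglik_kernel(chosen, unchosen, reward, n_symbols, a_gain, a_loss, beta, q_init):  # pragma: no cover
    q = np.full(n_symbols, q_init)
    n = chosen.size
    out = np.empty(n)
    for t in range(n):
        c = chosen[t]
        d = beta * (q[c] - q[unchosen[t]])
        if d < -30.0:
            out[t] = d
        else:
            out[t] = -np.log1p(np.exp(-d))
        pe = reward[t] - q[c]
        if pe > 0.0:
            q[c] += a_gain * pe
        else:
            q[c] += a_loss * pe
    return out


@njit(cache=True)
def _final_q_kernel(chosen, reward, n_symbols, a_gain, a_loss, q_init):  # pragma: no cover
    q = np.full(n_symbols, q_init)
    for t in range(chosen.size):
        c = chosen[t]
        pe = reward[t] - q[c]
        if pe > 0.0:
            q[c] += a_gain * pe
        else:
            q[c] += a_loss * pe
    return q


@dataclass
class DatasetArrays:
    """Integer-encoded learning trials for one dataset, ready for the numba kernels.

    Missed trials are dropped on construction: they contribute no likelihood
    term and trigger no value update.
    """

    chosen: np.ndarray
    unchosen: np.ndarray
    reward: np.ndarray
    n_symbols: int

    @property
    def n_trials(self) -> int:
        return int(self.chosen.size)


def dataset_arrays(trials: pd.DataFrame, symbols=("A", "B", "C", "D", "E", "F")) -> DatasetArrays:
    """Encode one dataset's learning-phase trials for likelihood evaluation.

    Trials must be sorted by ``trial_index``; only learning-phase rows carry
    feedback, so test-phase rows are excluded.
    """
    learn = trials[trials["phase"] == "learning"]
    idx = learn["trial_index"].to_numpy()
    if idx.size > 1 and np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be strictly ordered by trial_index")
    if "missed" in learn.columns:
        learn = learn[learn["missed"] == 0]
    code = {s: i for i, s in enumerate(symbols)}
    chosen = learn["choice"].map(code)
    if chosen.isna().any():
        raise ValueError("choice contains symbols outside the configured set")
    chosen = chosen.to_numpy(dtype=np.int64)
    if {"left_symbol", "right_symbol"} <= set(learn.columns):
        left = learn["left_symbol"].map(code).to_numpy(dtype=np.int64)
        right = learn["right_symbol"].map(code).to_numpy(dtype=np.int64)
        unchosen = np.where(chosen == left, right, left)
    elif len(learn) == 0:
        unchosen = np.empty(0, dtype=np.int64)
    else:
        # single-character symbol labels: the unchosen option is the other pair member
        unchosen = learn.apply(lambda r: code[r["pair"].replace(r["choice"], "", 1)],
                               axis=1).to_numpy(dtype=np.int64)
    reward = learn["reward"].to_numpy(dtype=np.float64)
    return DatasetArrays(chosen=chosen, unchosen=unchosen, reward=reward, n_symbols=len(symbols))


def loglik_from_arrays(data: DatasetArrays, alpha_gain: float, alpha_loss: float, beta: float,
                       q_init: float = DEFAULT_Q_INIT) -> np.ndarray:
    """Per-trial choice log-likelihood vector for pre-encoded trials."""
    return _loglik_kernel(data.chosen, data.unchosen, data.reward, data.n_symbols,
                          float(alpha_gain), float(alpha_loss), float(beta), float(q_init))


def sequence_loglik(trials: pd.DataFrame, params: AgentParams,
                    variant: ModelVariant = ModelVariant.DUAL_RATE,
                    q_init: float = DEFAULT_Q_INIT,
                    symbols=("A", "B", "C", "D", "E", "F")) -> np.ndarray:
    """Per-trial log-likelihoods of the observed learning-phase choices.

    Q-values evolve only on non-missed learning trials; the sum of the
    returned vector is the log joint choice likelihood of the dataset.
    Under ``single_rate`` the loss rate is tied to ``alpha_gain``.
    """
    variant = ModelVariant(variant)
    a_loss = params.alpha_gain if variant is ModelVariant.SINGLE_RATE else params.alpha_loss
    data = dataset_arrays(trials, symbols=symbols)
    return loglik_from_arrays(data, params.alpha_gain, a_loss, params.beta, q_init=q_init)


def final_q_values(data: DatasetArrays, alpha_gain: float, alpha_loss: float,
                   q_init: float = DEFAULT_Q_INIT) -> np.ndarray:
    """Q-table after replaying all learning trials (used to predict test-phase choices)."""
    return _final_q_kernel(data.chosen, data.reward, data.n_symbols,
                           float(alpha_gain), float(alpha_loss), float(q_init))
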