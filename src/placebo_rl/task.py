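"""Probabilistic selection task: structure, schedules and reward draws.

The task presents pairs of symbols whose members are probabilistically
associated with a monetary reward (A 80% vs B 20%, C 70% vs D 30%,
E 60% vs F 40%).  A learning phase delivers trial-wise feedback over six
blocks of 20 repetitions per trained pair; a subsequent test phase probes
all 15 pairwise combinations of the six symbols 12 times each, without
feedback.  Left/right placement is exactly counterbalanced per pair (per
block in the learning phase).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "enumerate_test_pairs",
    "generate_learning_schedule",
    "generate_test_schedule",
    "sample_reward",
    "better_symbol",
]

SCHEDULE_COLUMNS = ["phase", "block", "trial_index", "pair", "left_symbol", "right_symbol"]


def _default_reward_prob() -> dict[str, float]:
    return {"A": 0.80, "B": 0.20, "C": 0.70, "D": 0.30, "E": 0.60, "F": 0.40}


def _default_pairs() -> list[tuple[str, str]]:
    return [("A", "B"), ("C", "D"), ("E", "F")]


@dataclass
class TaskConfig:
    """Task structure and payoff parameters.

    Defaults encode the standard monetary probabilistic selection task:
    six symbols in three trained pairs with 80/20, 70/30 and 60/40 reward
    contingencies, six learning blocks of 20 repetitions per pair, and a
    test phase of 12 repetitions of each of the 15 possible pairs.
    """

    symbols: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    reward_prob: dict[str, float] = field(default_factory=_default_reward_prob)
    trained_pairs: list[tuple[str, str]] = field(default_factory=_default_pairs)
    blocks: int = 6
    reps_per_pair_per_block: int = 20
    test_reps_per_pair: int = 12
    response_window: float = 1.7  # seconds
    reward_magnitude: float = 0.01  # currency units per rewarded trial

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("symbols must be distinct")
        for s in self.symbols:
            p = self.reward_prob.get(s)
            if p is None:
                raise ValueError(f"no reward probability for symbol {s!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability for {s!r} outside [0, 1]")
        seen: set[str] = set()
        for a, b in self.trained_pairs:
            if a in seen or b in seen or a == b:
                raise ValueError("trained pairs must be disjoint in symbols")
            seen |= {a, b}
            if not np.isclose(self.reward_prob[a] + self.reward_prob[b], 1.0):
                raise ValueError(f"pair {a}{b}: reward probabilities must sum to 1")
        if self.reps_per_pair_per_block % 2 != 0:
            raise ValueError("reps_per_pair_per_block must be even for exact left/right counterbalancing")
        if self.test_reps_per_pair % 2 != 0:
            raise ValueError("test_reps_per_pair must be even for exact left/right counterbalancing")
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")

    def pair_name(self, pair: tuple[str, str]) -> str:
        return "".join(pair)

    def better_symbol(self, pair: tuple[str, str]) -> str:
        return better_symbol(pair, self.reward_prob)


def better_symbol(pair: tuple[str, str], reward_prob: dict[str, float]) -> str:
    """The objectively correct choice: the pair member with the higher reward probability."""
    a, b = pair
    return a if reward_prob[a] >= reward_prob[b] else b


def enumerate_test_pairs(symbols) -> list[tuple[str, str]]:
    """All unordered symbol pairs in canonical (lexicographic) order.

    Six symbols give the 15 combinations probed in the test phase; removing
    the three trained pairs leaves the 12 novel pairings.
    """
    symbols = list(symbols)
    if len(set(symbols)) != len(symbols):
        raise ValueError("symbols must be distinct")
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(symbols), 2)]


def _orientations(pair: tuple[str, str], reps: int) -> list[tuple[str, str]]:
    """Exactly reps presentations of a pair, half in each left/right orientation."""
    half = reps // 2
    return [pair] * half + [(pair[1], pair[0])] * half


def generate_learning_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Seeded learning-phase schedule.

    Each block contains ``reps_per_pair_per_block`` presentations of every
    trained pair, shuffled within the block, with left/right orientation
    exactly counterbalanced per pair per block.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for block in range(config.blocks):
        presentations: list[tuple[str, str]] = []
        for pair in config.trained_pairs:
            presentations.extend(_orientations(pair, config.reps_per_pair_per_block))
        order = rng.permutation(len(presentations))
        for k in order:
            left, right = presentations[k]
            pair = tuple(sorted((left, right)))
            rows.append(("learning", block, trial, "".join(pair), left, right))
            trial += 1
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def generate_test_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Seeded test-phase schedule: every pair ``test_reps_per_pair`` times, no feedback.

    All 15 combinations appear (3 trained + 12 novel for the default six
    symbols), each orientation exactly half the time, in random order.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    presentations: list[tuple[str, str]] = []
    for pair in enumerate_test_pairs(config.symbols):
        presentations.extend(_orientations(pair, config.test_reps_per_pair))
    order = rng.permutation(len(presentations))
    rows = []
    for trial, k in enumerate(order):
        left, right = presentations[k]
        pair = tuple(sorted((left, right)))
        rows.append(("test", 0, trial, "".join(pair), left, right))
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def sample_reward(chosen_symbol: str, config: TaskConfig, rng: np.random.Generator) -> int:
    """Bernoulli reward draw for the chosen symbol (advances the generator)."""
    try:
        p = config.reward_prob[chosen_symbol]
    except KeyError as err:
        raise ValueError(f"unknown symbol {chosen_symbol!r}") from err
    return int(rng.random() < p)
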