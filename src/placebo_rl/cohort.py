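"""Synthetic study generator.

Emulates a three-session within-subject placebo study on the monetary
probabilistic selection task: a hierarchical population of dual-rate
Q-learning agents whose transformed parameters are shifted by condition
fixed effects (baseline, low-uncertainty LU, high-uncertainty HU),
log-normal reaction times, categorical subjective reports, and 0-10
arousal ratings.

Group-level defaults: the gain learning rate is centred at the emulated
cohort's fitted group mean (0.07), and the condition effects delta on the
transformed scales are the fitted fixed effects (gains LU +0.83, HU +1.17;
losses LU -0.74, HU -0.86; noise LU -0.02, HU +0.05).  The loss-rate
centre (0.20) and the inverse-temperature centre (1/0.21, i.e. the
temperature reading of the reported noise parameter) are generator
choices: under the plain inverse-temperature softmax the literal fitted
values produce near-chance choices and an inverted condition ordering,
whereas these centres reproduce the empirical 70-85% accuracy range and
the observed HU > LU > baseline direction.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .qlearning import AgentParams, DEFAULT_Q_INIT
from .posterior import to_natural, to_unconstrained
from .task import TaskConfig, generate_learning_schedule, generate_test_schedule

__all__ = [
    "PARAMETERS",
    "CONDITIONS",
    "GroupTruth",
    "RTCoefs",
    "AccuracyCoefs",
    "ArousalCoefs",
    "SUBJECTIVE_PROFILES",
    "sample_population",
    "simulate_agent",
    "simulate_study",
    "simulate_performance",
    "simulate_subjective",
    "simulate_arousal",
]

PARAMETERS = ("alpha_gain", "alpha_loss", "beta")
CONDITIONS = ("baseline", "LU", "HU")
PLACEBO_CONDITIONS = ("LU", "HU")
RESPONSE_CATEGORIES = ("decline", "neutral", "improve")

TRIAL_COLUMNS = ["subject_id", "condition", "phase", "block", "trial_index",
                 "pair", "choice", "correct", "reward", "rt", "missed"]


def _default_delta() -> dict[tuple[str, str], float]:
    return {
        ("alpha_gain", "LU"): 0.83,
        ("alpha_gain", "HU"): 1.17,
        ("alpha_loss", "LU"): -0.74,
        ("alpha_loss", "HU"): -0.86,
        ("beta", "LU"): -0.02,
        ("beta", "HU"): 0.05,
    }


@dataclass
class GroupTruth:
    """Group-level generative parameters on the transformed (logit/log) scales."""

    mu_alpha_gain: float = float(to_unconstrained(0.07, "logit"))
    mu_alpha_loss: float = float(to_unconstrained(0.20, "logit"))
    mu_log_beta: float = float(-np.log(0.21))
    sigma_alpha_gain: float = 0.4
    sigma_alpha_loss: float = 0.4
    sigma_log_beta: float = 0.25
    delta: dict[tuple[str, str], float] = field(default_factory=_default_delta)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for s in (self.sigma_alpha_gain, self.sigma_alpha_loss, self.sigma_log_beta):
            if s < 0:
                raise ValueError("group SDs must be non-negative")
        expected = {(p, c) for p in PARAMETERS for c in PLACEBO_CONDITIONS}
        if set(self.delta) != expected:
            raise ValueError("delta must cover exactly the six (parameter, condition) pairs")

    def mu(self, param: str) -> float:
        return {"alpha_gain": self.mu_alpha_gain, "alpha_loss": self.mu_alpha_loss,
                "beta": self.mu_log_beta}[param]

    def sigma(self, param: str) -> float:
        return {"alpha_gain": self.sigma_alpha_gain, "alpha_loss": self.sigma_alpha_loss,
                "beta": self.sigma_log_beta}[param]

    def offset(self, param: str, condition: str) -> float:
        return 0.0 if condition == "baseline" else self.delta[(param, condition)]

    def zero_effect(self) -> "GroupTruth":
        return replace(self, delta={k: 0.0 for k in self.delta})


@dataclass
class RTCoefs:
    """Generative log-RT model: mirrors the analysis model so recovery is testable.

    log rt = intercept + b_trial * (trial/20) + b_pair * pair + condition effect
             + subject offset + Normal(0, noise_sd).
    Defaults are the fitted RT regression coefficients of the emulated study;
    the two SDs are generator choices.
    """

    intercept: float = -0.077
    b_trial: float = -0.043
    b_pair: float = 0.023
    b_LU: float = -0.116
    b_HU: float = -0.145
    subject_sd: float = 0.10
    noise_sd: float = 0.15

    def condition_effect(self, condition: str) -> float:
        return {"baseline": 0.0, "LU": self.b_LU, "HU": self.b_HU}[condition]


@dataclass
class AccuracyCoefs:
    """Generative hierarchical-logistic accuracy model (for regression recovery).

    logit P(correct) = intercept_subject + b_trial * (trial/20) + b_pair * pair
                       + condition effect.  Defaults follow the emulated study's
    fitted accuracy regression; subject_sd is a generator choice.
    """

    intercept: float = 1.673
    b_trial: float = 0.144
    b_pair: float = -0.497
    b_LU: float = 0.217
    b_HU: float = 0.435
    subject_sd: float = 0.5

    def condition_effect(self, condition: str) -> float:
        return {"baseline": 0.0, "LU": self.b_LU, "HU": self.b_HU}[condition]


@dataclass
class ArousalCoefs:
    """Generative arousal-rating model (0-10 Likert, before/after each session)."""

    intercept: float = 7.22
    b_after: float = -0.91
    b_LU: float = -0.32
    b_HU: float = -0.18
    b_LU_after: float = 0.10
    b_HU_after: float = -0.11
    subject_sd: float = 1.0
    noise_sd: float = 1.0


#: Category probabilities (decline, neutral, improve) per (condition, question),
#: the estimated response profiles of the emulated study.
SUBJECTIVE_PROFILES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("LU", "anticipated"): (0.07, 0.34, 0.59),
    ("HU", "anticipated"): (0.10, 0.34, 0.56),
    ("LU", "experienced"): (0.03, 0.56, 0.41),
    ("HU", "experienced"): (0.26, 0.52, 0.22),
}


def sample_population(truth: GroupTruth, n_subjects: int, condition: str,
                      seed, tie_rates: bool = False) -> list[AgentParams]:
    """Draw natural-scale agent parameters for one condition's datasets.

    Transformed parameters are Normal(mu + delta_condition, sigma); alphas map
    back through the inverse logit and beta through the exponential.  With
    ``tie_rates`` the loss rate is set equal to the gain rate draw, producing
    data whose true generating process is the single-rate model.
    """
    truth.validate()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        natural = {}
        for param in PARAMETERS:
            z = rng.normal(truth.mu(param) + truth.offset(param, condition),
                           truth.sigma(param))
            kind = "log" if param == "beta" else "logit"
            natural[param] = float(to_natural(z, kind))
        if tie_rates:
            natural["alpha_loss"] = natural["alpha_gain"]
        out.append(AgentParams(**natural))
    return out


@njit(cache=True)
def _agent_kernel(left, right, is_learning, probs, a_g, a_l, beta, q_init,
                  u_choice, u_reward):  # pragma: no cover
    n = left.size
    choice = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=np.int64)
    q = np.full(probs.size, q_init)
    for t in range(n):
        d = beta * (q[left[t]] - q[right[t]])
        if d < -30.0:
            p_left = 0.0
        elif d > 30.0:
            p_left = 1.0
        else:
            p_left = 1.0 / (1.0 + np.exp(-d))
        c = left[t] if u_choice[t] < p_left else right[t]
        choice[t] = c
        if is_learning[t]:
            r = 1 if u_reward[t] < probs[c] else 0
            reward[t] = r
            pe = r - q[c]
            if pe > 0.0:
                q[c] += a_g * pe
            else:
                q[c] += a_l * pe
        else:
            reward[t] = -1  # no feedback in the test phase
    return choice, reward


def simulate_agent(params: AgentParams, schedule: pd.DataFrame, config: TaskConfig,
                   seed, rt_coefs: RTCoefs | None = None,
                   rt_offset: float = 0.0, condition: str = "baseline",
                   miss_rate: float = 0.0, q_init: float = DEFAULT_Q_INIT) -> pd.DataFrame:
    """Simulate one dataset (one subject in one condition) over a schedule.

    Learning trials: softmax choice on current Q-values, Bernoulli reward for
    the chosen symbol, dual-rate value update.  Test trials: softmax choice
    with frozen Q-values and no feedback.  RTs are log-normal with trial,
    pair and condition effects; missed trials (rate ``miss_rate``) carry no
    choice, reward or RT and trigger no update.
    """
    rt_coefs = rt_coefs or RTCoefs()
    rng = np.random.default_rng(seed)
    symbols = list(config.symbols)
    code = {s: i for i, s in enumerate(symbols)}
    probs = np.array([config.reward_prob[s] for s in symbols])
    left = schedule["left_symbol"].map(code).to_numpy(dtype=np.int64)
    right = schedule["right_symbol"].map(code).to_numpy(dtype=np.int64)
    is_learning = (schedule["phase"] == "learning").to_numpy()
    choice_idx, reward = _agent_kernel(
        left, right, is_learning, probs,
        params.alpha_gain, params.alpha_loss, params.beta, q_init,
        rng.random(left.size), rng.random(left.size))

    pair_number = _pair_numbers(schedule["pair"], config)
    trial_in_phase = schedule.groupby("phase", sort=False).cumcount().to_numpy()
    log_rt = (rt_coefs.intercept
              + rt_coefs.b_trial * trial_in_phase / 20.0
              + rt_coefs.b_pair * pair_number
              + rt_coefs.condition_effect(condition)
              + rt_offset
              + rng.normal(0.0, rt_coefs.noise_sd, left.size))
    rt = np.clip(np.exp(log_rt), 0.15, config.response_window)

    missed = rng.random(left.size) < miss_rate
    chosen = np.array(symbols, dtype=object)[choice_idx]
    other_idx = np.where(choice_idx == left, right, left)
    correct = (probs[choice_idx] > probs[other_idx]).astype(int)

    out = pd.DataFrame({
        "phase": schedule["phase"].to_numpy(),
        "block": schedule["block"].to_numpy(),
        "trial_index": schedule["trial_index"].to_numpy(),
        "pair": schedule["pair"].to_numpy(),
        "choice": chosen,
        "correct": correct,
        "reward": np.where(is_learning, reward, -1),
        "rt": np.round(rt, 6),
        "missed": missed.astype(int),
    })
    # missed trials carry no observable response; feedback exists only in learning
    out.loc[out["missed"] == 1, ["choice"]] = ""
    out.loc[out["missed"] == 1, ["correct"]] = -1
    out.loc[out["missed"] == 1, "rt"] = np.nan
    out.loc[(out["missed"] == 1) | (~is_learning), "reward"] = -1
    return out


def _pair_numbers(pairs: pd.Series, config: TaskConfig) -> np.ndarray:
    """Numeric pair coding 1-3 for trained pairs; novel test pairs get the middle code."""
    trained = {config.pair_name(p): i + 1 for i, p in enumerate(config.trained_pairs)}
    return pairs.map(lambda p: trained.get(p, 2)).to_numpy(dtype=float)


def simulate_study(truth: GroupTruth, rt_truth: RTCoefs | None = None,
                   n_subjects: int = 29, seed: int = 0,
                   config: TaskConfig | None = None,
                   conditions=CONDITIONS, miss_rate: float = 0.0,
                   q_init: float = DEFAULT_Q_INIT, tie_rates: bool = False) -> pd.DataFrame:
    """Simulate a complete study: ``n_subjects`` agents in each condition.

    Subject-level RL parameters are drawn independently for every
    subject-by-condition dataset; baseline uses zero condition offsets.
    Fresh schedules (new stimuli orders) are generated per dataset.  RT
    subject offsets are shared across a subject's sessions, mirroring the
    varying-intercept analysis model.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a hierarchical analysis")
    truth.validate()
    rt_truth = rt_truth or RTCoefs()
    config = config or TaskConfig()
    root = np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(root.spawn(1)[0])
    rt_offsets = subj_rng.normal(0.0, rt_truth.subject_sd, n_subjects)

    frames = []
    for condition in conditions:
        cond_seq = root.spawn(1)[0]
        agents = sample_population(truth, n_subjects, condition, cond_seq, tie_rates=tie_rates)
        for i, params in enumerate(agents):
            s_learn, s_test, s_agent = root.spawn(3)
            learn = generate_learning_schedule(config, s_learn)
            test = generate_test_schedule(config, s_test)
            schedule = pd.concat([learn, test], ignore_index=True)
            rec = simulate_agent(params, schedule, config, s_agent,
                                 rt_coefs=rt_truth, rt_offset=rt_offsets[i],
                                 condition=condition, miss_rate=miss_rate,
                                 q_init=q_init)
            rec.insert(0, "condition", condition)
            rec.insert(0, "subject_id", i + 1)
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_performance(acc_truth: AccuracyCoefs | None = None,
                         rt_truth: RTCoefs | None = None,
                         n_subjects: int = 29, seed: int = 0,
                         config: TaskConfig | None = None) -> pd.DataFrame:
    """Learning-phase data drawn directly from the regression models.

    Used for regression-recovery checks: accuracy is Bernoulli under the
    hierarchical logistic model and RT log-normal under the linear model,
    with the same predictors the analysis fits (trial/20, numeric pair,
    condition dummies, subject-varying intercepts).
    """
    acc_truth = acc_truth or AccuracyCoefs()
    rt_truth = rt_truth or RTCoefs()
    config = config or TaskConfig()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    acc_offsets = rng.normal(0.0, acc_truth.subject_sd, n_subjects)
    rt_offsets = rng.normal(0.0, rt_truth.subject_sd, n_subjects)
    from scipy.special import expit

    frames = []
    for condition in CONDITIONS:
        for i in range(n_subjects):
            sched = generate_learning_schedule(config, root.spawn(1)[0])
            pair_number = _pair_numbers(sched["pair"], config)
            t20 = sched["trial_index"].to_numpy() / 20.0
            eta = (acc_truth.intercept + acc_offsets[i]
                   + acc_truth.b_trial * t20 + acc_truth.b_pair * pair_number
                   + acc_truth.condition_effect(condition))
            correct = (rng.random(len(sched)) < expit(eta)).astype(int)
            log_rt = (rt_truth.intercept + rt_offsets[i]
                      + rt_truth.b_trial * t20 + rt_truth.b_pair * pair_number
                      + rt_truth.condition_effect(condition)
                      + rng.normal(0.0, rt_truth.noise_sd, len(sched)))
            rec = pd.DataFrame({
                "subject_id": i + 1, "condition": condition,
                "phase": "learning", "block": sched["block"],
                "trial_index": sched["trial_index"], "pair": sched["pair"],
                "choice": "", "correct": correct, "reward": -1,
                "rt": np.round(np.exp(log_rt), 6), "missed": 0,
            })
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_subjective(prob_profiles: dict[tuple[str, str], tuple] | None = None,
                        n_subjects: int = 29, seed: int = 0) -> pd.DataFrame:
    """Categorical anticipated/experienced reports per subject and placebo condition."""
    prob_profiles = prob_profiles or SUBJECTIVE_PROFILES
    rng = np.random.default_rng(seed)
    rows = []
    for (condition, question), p in prob_profiles.items():
        p = np.asarray(p, dtype=float)
        if p.shape != (3,) or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"profile for {(condition, question)} must be a 3-vector summing to 1")
        draws = rng.choice(3, size=n_subjects, p=p)
        for i, k in enumerate(draws):
            rows.append((i + 1, condition, question, RESPONSE_CATEGORIES[k]))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "question", "response"])


def simulate_arousal(coefs: ArousalCoefs | None = None, n_subjects: int = 29,
                     seed: int = 0) -> pd.DataFrame:
    """Before/after arousal ratings per session, rounded and clipped to the 0-10 scale."""
    coefs = coefs or ArousalCoefs()
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, coefs.subject_sd, n_subjects)
    rows = []
    for condition in CONDITIONS:
        is_lu = condition == "LU"
        is_hu = condition == "HU"
        for i in range(n_subjects):
            for time in ("before", "after"):
                after = time == "after"
                mean = (coefs.intercept + offsets[i]
                        + coefs.b_after * after
                        + coefs.b_LU * is_lu + coefs.b_HU * is_hu
                        + coefs.b_LU_after * (is_lu and after)
                        + coefs.b_HU_after * (is_hu and after))
                rating = int(np.clip(np.round(mean + rng.normal(0.0, coefs.noise_sd)), 0, 10))
                rows.append((i + 1, condition, time, rating))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "time", "rating"])
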