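"""Behavioral regression analyses.

Four Bayesian analyses accompany the reinforcement-learning fit:

* accuracy: hierarchical logistic regression on learning-phase correctness
  with trial (in steps of 20), numeric pair (1-3), condition dummies
  (baseline reference), and subject-varying intercepts;
* reaction time: the same predictor set on log-transformed RTs (normal
  likelihood), reflecting the log-normal shape of RT distributions;
* subjective reports: softmax (multinomial) regression of the
  decline/neutral/improve responses on condition (HU indicator), question
  (experienced indicator) and their interaction, with "neutral" fixed as
  the reference category;
* arousal: hierarchical linear regression of the 0-10 ratings on
  condition, before/after time and their interaction.

Posteriors use wide (effectively flat) priors and are approximated by the
posterior mode with a Gaussian (Laplace) curvature approximation — for
these generalized linear models at the study's sample sizes the posterior
is close to Gaussian, so summaries agree with full MCMC to well within
reporting precision.  The hierarchical logistic and linear fits stand on
statsmodels (Bayesian mixed GLM / linear mixed model); the softmax
regression is fit directly by penalized maximum a posteriori with an
analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .posterior import hdi as _hdi

__all__ = [
    "CoefSummary",
    "RegressionResult",
    "SoftmaxCoefMatrix",
    "fit_accuracy_model",
    "fit_rt_model",
    "fit_subjective_softmax",
    "fit_arousal_model",
    "category_probabilities",
]

RESPONSE_CATEGORIES = ("decline", "neutral", "improve")
SOFTMAX_PREDICTORS = ("intercept", "condition", "question", "condition_x_question")


@dataclass
class CoefSummary:
    name: str
    mean: float
    sd: float
    hdi_low: float
    hdi_high: float


@dataclass
class RegressionResult:
    """Posterior summaries for one regression model."""

    model: str
    n_obs: int
    coefficients: dict[str, CoefSummary]
    group_intercept_mean: float | None = None
    group_intercept_sd: float | None = None
    flags: list[str] = field(default_factory=list)
    draws: dict[str, np.ndarray] | None = None

    def coef(self, name: str) -> CoefSummary:
        return self.coefficients[name]

    def covers(self, name: str, value: float) -> bool:
        c = self.coefficients[name]
        return c.hdi_low <= value <= c.hdi_high

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.coefficients.values()])


def _prepare_learning(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials[(trials["phase"] == "learning")].copy()
    if "missed" in df.columns:
        df = df[df["missed"] == 0]
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    pair_codes = {p: i + 1 for i, p in enumerate(sorted(df["pair"].unique()))}
    df["pair_num"] = df["pair"].map(pair_codes).astype(float)
    df["trial_s"] = df["trial_index"].astype(float) / 20.0
    df["cond_LU"] = (df["condition"] == "LU").astype(float)
    df["cond_HU"] = (df["condition"] == "HU").astype(float)
    return df


def _summaries(names, means, sds, mass: float, rng: np.random.Generator,
               n_draws: int = 4000) -> tuple[dict[str, CoefSummary], dict[str, np.ndarray]]:
    coefs, draws = {}, {}
    for name, m, s in zip(names, means, sds):
        d = rng.normal(m, s, n_draws)
        lo, hi = _hdi(d, mass)
        coefs[name] = CoefSummary(name=name, mean=float(m), sd=float(s),
                                  hdi_low=lo, hdi_high=hi)
        draws[name] = d
    return coefs, draws


def fit_accuracy_model(trials: pd.DataFrame, mass: float = 0.95,
                       seed: int = 0) -> RegressionResult:
    """Hierarchical logistic regression of learning-phase accuracy."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = _prepare_learning(trials)
    df = df[df["correct"].isin([0, 1])]
    fe_names = ["intercept", "trial", "pair", "condition_LU", "condition_HU"]
    if df["correct"].nunique() < 2:
        # degenerate outcome: the likelihood is maximized at infinity
        nan = float("nan")
        coefs = {n: CoefSummary(n, nan, nan, nan, nan) for n in fe_names}
        return RegressionResult(model="accuracy_logistic", n_obs=len(df),
                                coefficients=coefs, flags=["separation"])
    flags = []

    model = BinomialBayesMixedGLM.from_formula(
        "correct ~ trial_s + pair_num + cond_LU + cond_HU",
        {"subject": "0 + C(subject_id)"}, df, vcp_p=3.0, fe_p=15.0)
    fit = model.fit_map()
    fe_mean = np.asarray(fit.fe_mean)
    fe_sd = np.asarray(fit.fe_sd)
    if np.any(np.abs(fe_mean) > 12.0) or not np.all(np.isfinite(fe_sd)):
        flags.append("separation")
    rng = np.random.default_rng(seed)
    coefs, draws = _summaries(fe_names, fe_mean, fe_sd, mass, rng)
    group_sd = float(np.exp(fit.vcp_mean[0]))
    return RegressionResult(model="accuracy_logistic", n_obs=len(df), coefficients=coefs,
                            group_intercept_mean=float(fe_mean[0]), group_intercept_sd=group_sd,
                            flags=flags, draws=draws)


def fit_rt_model(trials: pd.DataFrame, mass: float = 0.95, seed: int = 0) -> RegressionResult:
    """Hierarchical normal regression of log reaction times."""
    import statsmodels.formula.api as smf

    df = _prepare_learning(trials)
    n_bad = int(((df["rt"] <= 0) | df["rt"].isna()).sum())
    flags = [f"dropped_nonpositive_rt:{n_bad}"] if n_bad else []
    df = df[df["rt"] > 0].copy()
    df["log_rt"] = np.log(df["rt"])

    model = smf.mixedlm("log_rt ~ trial_s + pair_num + cond_LU + cond_HU",
                        df, groups=df["subject_id"])
    fit = model.fit(reml=True)
    if not fit.converged:
        flags.append("non_converged")
    fe_names = ["intercept", "trial", "pair", "condition_LU", "condition_HU"]
    means = np.asarray(fit.fe_params)
    sds = np.asarray(fit.bse[: len(means)])
    rng = np.random.default_rng(seed)
    coefs, draws = _summaries(fe_names, means, sds, mass, rng)
    group_sd = float(np.sqrt(fit.cov_re.iloc[0, 0]))
    return RegressionResult(model="rt_lognormal", n_obs=len(df), coefficients=coefs,
                            group_intercept_mean=float(means[0]), group_intercept_sd=group_sd,
                            flags=flags, draws=draws)


def fit_arousal_model(records: pd.DataFrame, mass: float = 0.95, seed: int = 0) -> RegressionResult:
    """Hierarchical linear regression of arousal ratings on condition x time."""
    import statsmodels.formula.api as smf

    df = records.copy()
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    df["after"] = (df["time"] == "after").astype(float)
    df["cond_LU"] = (df["condition"] == "LU").astype(float)
    df["cond_HU"] = (df["condition"] == "HU").astype(float)
    df["LU_after"] = df["cond_LU"] * df["after"]
    df["HU_after"] = df["cond_HU"] * df["after"]

    model = smf.mixedlm("rating ~ after + cond_LU + cond_HU + LU_after + HU_after",
                        df, groups=df["subject_id"])
    fit = model.fit(reml=True)
    flags = [] if fit.converged else ["non_converged"]
    fe_names = ["intercept", "after", "condition_LU", "condition_HU",
                "condition_LU_x_after", "condition_HU_x_after"]
    means = np.asarray(fit.fe_params)
    sds = np.asarray(fit.bse[: len(means)])
    rng = np.random.default_rng(seed)
    coefs, draws = _summaries(fe_names, means, sds, mass, rng)
    group_sd = float(np.sqrt(fit.cov_re.iloc[0, 0]))
    return RegressionResult(model="arousal_linear", n_obs=len(df), coefficients=coefs,
                            group_intercept_mean=float(means[0]), group_intercept_sd=group_sd,
                            flags=flags, draws=draws)


# ---------------------------------------------------------------------------
# softmax (multinomial) regression for the subjective reports

@dataclass
class SoftmaxCoefMatrix:
    """4 x 3 coefficient matrix (predictors x categories); neutral fixed at zero.

    Rows: intercept, condition (HU indicator), question (experienced
    indicator), their interaction.  Columns: decline, neutral, improve.
    """

    mean: np.ndarray
    coefficients: dict[str, CoefSummary]
    draws: np.ndarray  # (n_draws, 4, 2) free columns (decline, improve)
    n_obs: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mean.shape != (4, 3) or not np.allclose(self.mean[:, 1], 0.0):
            raise ValueError("coefficient matrix must be 4x3 with a zero neutral column")


def _softmax_design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cond = (records["condition"] == "HU").astype(float).to_numpy()
    quest = (records["question"] == "experienced").astype(float).to_numpy()
    x = np.column_stack([np.ones(len(records)), cond, quest, cond * quest])
    cat = {c: i for i, c in enumerate(RESPONSE_CATEGORIES)}
    y = records["response"].map(cat)
    if y.isna().any():
        raise ValueError("responses must be coded decline/neutral/improve")
    return x, y.to_numpy(dtype=int)


def _softmax_neg_logpost(b_free: np.ndarray, x: np.ndarray, y: np.ndarray,
                         prior_sd: float) -> tuple[float, np.ndarray]:
    b = b_free.reshape(4, 2)
    scores = np.zeros((x.shape[0], 3))
    scores[:, 0] = x @ b[:, 0]
    scores[:, 2] = x @ b[:, 1]
    lse = logsumexp(scores, axis=1)
    nll = float(np.sum(lse - scores[np.arange(len(y)), y]))
    p = np.exp(scores - lse[:, None])
    resid = p.copy()
    resid[np.arange(len(y)), y] -= 1.0
    nll += float(np.sum(b_free ** 2) / (2 * prior_sd ** 2))
    # gradient in the same row-major (4, 2) layout as b_free
    g = np.column_stack([x.T @ resid[:, 0], x.T @ resid[:, 2]]).reshape(-1)
    g += b_free / prior_sd ** 2
    return nll, g


def fit_subjective_softmax(records: pd.DataFrame, mass: float = 0.95,
                           prior_sd: float = 5.0, seed: int = 0,
                           n_draws: int = 4000) -> SoftmaxCoefMatrix:
    """Softmax regression of categorical subjective reports.

    MAP estimate under independent Normal(0, prior_sd) priors on the free
    coefficients, with a Laplace approximation for the posterior draws.  A
    category that never occurs stays identified through the prior and is
    flagged rather than failing.
    """
    x, y = _softmax_design(records)
    flags = []
    observed = set(y)
    if observed != {0, 1, 2}:
        missing = [RESPONSE_CATEGORIES[k] for k in {0, 1, 2} - observed]
        flags.append("unobserved_category:" + ",".join(missing))

    from scipy.optimize import minimize

    res = minimize(_softmax_neg_logpost, np.zeros(8), args=(x, y, prior_sd),
                   jac=True, method="BFGS")
    if not res.success:
        flags.append("optimizer:" + str(res.message))
    b_map = res.x

    # finite-difference Hessian of the analytic gradient
    eps = 1e-5
    hess = np.empty((8, 8))
    for k in range(8):
        e = np.zeros(8)
        e[k] = eps
        _, gp = _softmax_neg_logpost(b_map + e, x, y, prior_sd)
        _, gm = _softmax_neg_logpost(b_map - e, x, y, prior_sd)
        hess[:, k] = (gp - gm) / (2 * eps)
    hess = 0.5 * (hess + hess.T)
    cov = np.linalg.inv(hess)

    rng = np.random.default_rng(seed)
    free_draws = rng.multivariate_normal(b_map, cov, size=n_draws).reshape(n_draws, 4, 2)

    mean = np.zeros((4, 3))
    b = b_map.reshape(4, 2)
    mean[:, 0] = b[:, 0]
    mean[:, 2] = b[:, 1]
    coefs = {}
    for r, pred in enumerate(SOFTMAX_PREDICTORS):
        for c, cat in ((0, "decline"), (1, "improve")):
            d = free_draws[:, r, c]
            lo, hi = _hdi(d, mass)
            coefs[f"{pred}:{RESPONSE_CATEGORIES[2 * c]}"] = CoefSummary(
                name=f"{pred}:{RESPONSE_CATEGORIES[2 * c]}", mean=float(d.mean()),
                sd=float(d.std(ddof=1)), hdi_low=lo, hdi_high=hi)
    return SoftmaxCoefMatrix(mean=mean, coefficients=coefs, draws=free_draws,
                             n_obs=len(y), flags=flags)


def category_probabilities(coefs: np.ndarray | SoftmaxCoefMatrix, condition: str,
                           question: str) -> np.ndarray:
    """(p_decline, p_neutral, p_improve) for one condition/question cell."""
    m = coefs.mean if isinstance(coefs, SoftmaxCoefMatrix) else np.asarray(coefs, dtype=float)
    if m.shape != (4, 3):
        raise ValueError("coefficient matrix must be 4x3")
    hu = 1.0 if condition == "HU" else 0.0
    exp_q = 1.0 if question == "experienced" else 0.0
    xvec = np.array([1.0, hu, exp_q, hu * exp_q])
    scores = xvec @ m
    p = np.exp(scores - logsumexp(scores))
    return p / p.sum()


def category_probability_draws(coefs: SoftmaxCoefMatrix, condition: str,
                               question: str) -> np.ndarray:
    """Posterior draws of the category-probability 3-vector for one cell."""
    hu = 1.0 if condition == "HU" else 0.0
    exp_q = 1.0 if question == "experienced" else 0.0
    xvec = np.array([1.0, hu, exp_q, hu * exp_q])
    scores = np.zeros((coefs.draws.shape[0], 3))
    scores[:, 0] = coefs.draws[:, :, 0] @ xvec
    scores[:, 2] = coefs.draws[:, :, 1] @ xvec
    p = np.exp(scores - logsumexp(scores, axis=1)[:, None])
    return p
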