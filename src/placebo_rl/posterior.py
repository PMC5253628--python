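"""Posterior summaries and diagnostics: links, HDI, R-hat, WAIC, model comparison.

These are the generic pieces shared by the hierarchical reinforcement-learning
fit and the behavioral regressions.  Learning rates live on the logit scale
and the inverse temperature on the log scale; condition effects are additive
on those transformed scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "to_unconstrained",
    "to_natural",
    "hdi",
    "rhat",
    "waic",
    "WaicResult",
    "compare_models",
    "ModelComparison",
    "exceedance_probability",
    "effect_on_original_scale",
    "PosteriorSummary",
]

STRONG_WAIC_DIFFERENCE = 10.0


# ---------------------------------------------------------------------------
# link functions

def to_unconstrained(value, kind: str):
    """Map natural-scale parameters to the unconstrained sampling scale.

    kind="logit" for rates in (0, 1); kind="log" for positive parameters.
    Boundary values map to infinities and are rejected.
    """
    value = np.asarray(value, dtype=float)
    if kind == "logit":
        if np.any(value <= 0.0) or np.any(value >= 1.0):
            raise ValueError("logit link requires values strictly inside (0, 1)")
        return _logit(value)
    if kind == "log":
        if np.any(value <= 0.0):
            raise ValueError("log link requires strictly positive values")
        return np.log(value)
    raise ValueError(f"unknown link kind {kind!r}")


def to_natural(value, kind: str):
    """Inverse of :func:`to_unconstrained`."""
    value = np.asarray(value, dtype=float)
    if kind == "logit":
        return expit(value)
    if kind == "log":
        return np.exp(value)
    raise ValueError(f"unknown link kind {kind!r}")


# ---------------------------------------------------------------------------
# interval and diagnostic statistics

def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval holding ``mass``.

    Computed by an exhaustive scan over sorted samples (the interval contains
    ceil(mass * n) of them), which is exact for unimodal posteriors.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    n_in = int(np.ceil(mass * n))
    if n_in >= n:
        return float(x[0]), float(x[-1])
    widths = x[n_in - 1:] - x[: n - n_in + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + n_in - 1])


def rhat(chains, split: bool = True) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (n_chains, n_draws) array.  With ``split=True`` each
    chain is halved first (the modern default, sensitive to trends); with
    ``split=False`` this is the classic formula
    sqrt(((n-1)/n * W + B/n) / W).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    n = x.shape[1]
    within = x.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        raise ValueError("zero within-chain variance: R-hat undefined")
    b = n * x.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass
class WaicResult:
    """Watanabe-Akaike information criterion on the deviance scale."""

    waic: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-observation -2*(lppd_i - p_i)
    n_points: int


def waic(loglik_draws) -> WaicResult:
    """WAIC from a (draws, observations) matrix of pointwise log-likelihoods.

    lppd_i = log mean_d exp(ll_di); the effective-parameter penalty is the
    pointwise posterior variance of the log-likelihood; the criterion is
    reported on the deviance scale, waic = -2 * (lppd - p_waic).
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.ndim == 1:
        ll = ll[:, None]
    ndraws, npoints = ll.shape
    lppd_i = _log_mean_exp(ll, axis=0)
    if ndraws < 2:
        import warnings

        warnings.warn("WAIC penalty is zero with a single posterior draw", stacklevel=2)
        p_i = np.zeros(npoints)
    else:
        p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(
        waic=float(-2.0 * (lppd - p_waic)),
        lppd=lppd,
        p_waic=p_waic,
        pointwise=-2.0 * (lppd_i - p_i),
        n_points=npoints,
    )


def _log_mean_exp(a: np.ndarray, axis: int) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis) - np.log(a.shape[axis])


@dataclass
class ModelComparison:
    delta: float  # waic_a - waic_b; negative favors model a (lower deviance)
    preferred: str
    strong: bool


def compare_models(waic_a: WaicResult, waic_b: WaicResult,
                   label_a: str = "A", label_b: str = "B") -> ModelComparison:
    """Compare two WAIC results computed on identical observations.

    A difference larger than 10 on the deviance scale counts as strong
    evidence for the lower-WAIC model.
    """
    if waic_a.n_points != waic_b.n_points:
        raise ValueError("WAICs computed on different numbers of observations")
    delta = waic_a.waic - waic_b.waic
    preferred = label_a if delta <= 0 else label_b
    return ModelComparison(delta=float(delta), preferred=preferred,
                           strong=abs(delta) > STRONG_WAIC_DIFFERENCE)


def exceedance_probability(draws_a, draws_b) -> float:
    """Posterior probability P(A > B) from matched draws."""
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("draw vectors must have equal length")
    return float(np.mean(a > b))


def effect_on_original_scale(mu_draws, delta_draws, kind: str) -> np.ndarray:
    """Condition effect back-transformed to the natural scale at the group mean.

    Per matched draw: inv_link(mu + delta) - inv_link(mu).
    """
    mu = np.asarray(mu_draws, dtype=float)
    delta = np.asarray(delta_draws, dtype=float)
    return to_natural(mu + delta, kind) - to_natural(mu, kind)


@dataclass
class PosteriorSummary:
    """One parameter's posterior summary row."""

    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    rhat: float
    ess: float

    def __post_init__(self) -> None:
        if self.hdi_low > self.hdi_high:
            raise ValueError("HDI lower bound exceeds upper bound")


def effective_sample_size(chains) -> float:
    """Bulk effective sample size (autocorrelation-corrected draw count)."""
    import arviz as az

    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return float(az.ess(x))
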