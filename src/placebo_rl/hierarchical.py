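"""Hierarchical Bayesian estimation of the Q-learning model.

Every subject-by-condition dataset i has its own natural-scale parameters
(alpha_G, alpha_L, beta, or a single alpha for the single-rate variant).
On the transformed scales (logit for learning rates, log for the inverse
temperature) they are exchangeable draws

    theta_ip ~ Normal(mu_p + delta_p_LU * LU_i + delta_p_HU * HU_i, sigma_p),

so the placebo conditions act as additive fixed effects on the transformed
parameters.  Mildly informative priors: Normal(0, 5) on group means and
condition effects, half-Normal(0, 2.5) on group SDs.

Sampling uses a blocked MCMC scheme designed for this posterior's
structure: per-dataset parameters are conditionally independent given the
group level and are updated with adaptive random-walk Metropolis steps on
the transformed scale; group means and condition effects are jointly
conjugate given the transformed dataset parameters and are drawn exactly
(Gibbs); group SDs are updated by slice sampling.  Chains are seeded
deterministically and non-converged fits are returned flagged, never
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import posterior as post
from .qlearning import DEFAULT_Q_INIT, DatasetArrays, ModelVariant, dataset_arrays, loglik_from_arrays

__all__ = [
    "Priors",
    "McmcConfig",
    "REDUCED_PROFILE",
    "FULL_PROFILE",
    "HierarchicalModel",
    "PosteriorDraws",
    "pointwise_loglik",
]

_PARAM_SPECS = {
    ModelVariant.DUAL_RATE: (("alpha_gain", "logit"), ("alpha_loss", "logit"), ("beta", "log")),
    ModelVariant.SINGLE_RATE: (("alpha", "logit"), ("beta", "log")),
}
# transformed-scale centres used only to initialise chains
_INIT_CENTRE = {"logit": -1.5, "log": 1.0}


@dataclass
class Priors:
    """Prior scales for the group-level parameters (transformed scales)."""

    mean_scale: float = 5.0
    delta_scale: float = 5.0
    sigma_scale: float = 2.5


@dataclass
class McmcConfig:
    """Sampler settings.  The full profile matches the emulated analysis
    (8 chains, 1000 warm-up and 1000 kept draws each, no thinning); the
    reduced profile keeps recovery studies fast."""

    n_chains: int = 8
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2 or self.n_draws < 1:
            raise ValueError("need at least 2 chains and 1 draw")


FULL_PROFILE = McmcConfig()
REDUCED_PROFILE = McmcConfig(n_chains=2, n_warmup=500, n_draws=500)


def _norm_logpdf(x, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


@dataclass
class PosteriorDraws:
    """MCMC output: per-parameter arrays indexed (chain, draw).

    Group-level scalars are stored on the transformed scales under their
    registry names (``mu_*``, ``sigma_*``, ``delta_*_LU/HU``); dataset-level
    parameters are stored on the natural scale as (chain, draw, dataset)
    arrays under ``<param>_i``.
    """

    draws: dict[str, np.ndarray]
    dataset_index: pd.DataFrame
    variant: ModelVariant
    config: McmcConfig
    worst_rhat: float = np.nan
    converged: bool = False

    def get(self, name: str) -> np.ndarray:
        """Flattened draws (chains stacked) for one registered parameter."""
        x = self.draws[name]
        return x.reshape(-1, *x.shape[2:])

    @property
    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def rhat(self, name: str) -> float:
        return post.rhat(self.draws[name])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws of the group-level scalars (chain, draw, one column each)."""
        names = self.scalar_names
        n_chains, n_draws = self.draws[names[0]].shape
        out = {"chain": np.repeat(np.arange(n_chains), n_draws),
               "draw": np.tile(np.arange(n_draws), n_chains)}
        for name in names:
            out[name] = self.draws[name].ravel()
        return pd.DataFrame(out)

    def summary(self, names=None, mass: float = 0.95) -> pd.DataFrame:
        names = names or self.scalar_names
        rows = []
        for name in names:
            x = self.draws[name]
            lo, hi = post.hdi(x.ravel(), mass)
            rows.append(post.PosteriorSummary(
                name=name, mean=float(x.mean()), hdi_low=lo, hdi_high=hi,
                rhat=post.rhat(x), ess=post.effective_sample_size(x)))
        return pd.DataFrame([r.__dict__ for r in rows])


class HierarchicalModel:
    """Joint posterior over group and dataset-level Q-learning parameters."""

    def __init__(self, study: pd.DataFrame, variant: ModelVariant = ModelVariant.DUAL_RATE,
                 priors: Priors | None = None, q_init: float = DEFAULT_Q_INIT,
                 symbols=("A", "B", "C", "D", "E", "F")):
        self.variant = ModelVariant(variant)
        self.priors = priors or Priors()
        self.q_init = float(q_init)
        self.symbols = tuple(symbols)
        self.param_specs = _PARAM_SPECS[self.variant]

        datasets: list[DatasetArrays] = []
        index_rows = []
        lu, hu = [], []
        for (subject, condition), g in study.groupby(["subject_id", "condition"], sort=True):
            datasets.append(dataset_arrays(g.sort_values("trial_index"), symbols=self.symbols))
            index_rows.append((subject, condition))
            lu.append(1.0 if condition == "LU" else 0.0)
            hu.append(1.0 if condition == "HU" else 0.0)
        if len(datasets) < 2:
            raise ValueError("hierarchical model requires at least 2 datasets")
        self.datasets = datasets
        self.dataset_index = pd.DataFrame(index_rows, columns=["subject_id", "condition"])
        self.design = np.column_stack([np.ones(len(datasets)), np.array(lu), np.array(hu)])

    # -- parameter bookkeeping -------------------------------------------------
    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_params(self) -> int:
        return len(self.param_specs)

    def _natural(self, theta_row: np.ndarray) -> tuple[float, float, float]:
        """Transformed dataset parameters -> (alpha_gain, alpha_loss, beta)."""
        if self.variant is ModelVariant.DUAL_RATE:
            ag = post.to_natural(theta_row[0], "logit")
            al = post.to_natural(theta_row[1], "logit")
            b = post.to_natural(theta_row[2], "log")
        else:
            ag = al = post.to_natural(theta_row[0], "logit")
            b = post.to_natural(theta_row[1], "log")
        return float(ag), float(al), float(b)

    def dataset_loglik(self, i: int, theta_row: np.ndarray) -> float:
        ag, al, b = self._natural(theta_row)
        return float(loglik_from_arrays(self.datasets[i], ag, al, b, q_init=self.q_init).sum())

    # -- joint density (oracle-testable) --------------------------------------
    def log_density(self, point: dict) -> float:
        """Joint log density at a parameter point.

        ``point`` holds ``mu``, ``sigma``, ``delta`` arrays of shape
        (n_params,), (n_params,), (n_params, 2) on the transformed scales and
        ``theta`` of shape (n_datasets, n_params).  Group-prior, hierarchy and
        likelihood terms are summed exactly as the sampler sees them.
        """
        mu = np.asarray(point["mu"], dtype=float)
        sigma = np.asarray(point["sigma"], dtype=float)
        delta = np.asarray(point["delta"], dtype=float)
        theta = np.asarray(point["theta"], dtype=float)
        if np.any(sigma <= 0):
            return -np.inf
        pr = self.priors
        ld = float(np.sum(_norm_logpdf(mu, pr.mean_scale)))
        ld += float(np.sum(_norm_logpdf(delta, pr.delta_scale)))
        # half-Normal(0, s) density on sigma
        ld += float(np.sum(0.5 * np.log(2.0 / np.pi) - np.log(pr.sigma_scale)
                           - 0.5 * (sigma / pr.sigma_scale) ** 2))
        means = self.design @ np.column_stack([mu, delta[:, 0], delta[:, 1]]).T
        ld += float(np.sum(_norm_logpdf(theta - means, sigma[None, :])))
        for i in range(self.n_datasets):
            ld += self.dataset_loglik(i, theta[i])
        return ld

    # -- sampling --------------------------------------------------------------
    def fit(self, config: McmcConfig | None = None) -> PosteriorDraws:
        """Sample the joint posterior; returns draws with convergence flags."""
        config = config or REDUCED_PROFILE
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        stores = [self._run_chain(np.random.default_rng(s), config) for s in seeds]

        draws: dict[str, np.ndarray] = {}
        for key in stores[0]:
            draws[key] = np.stack([s[key] for s in stores], axis=0)
        result = PosteriorDraws(draws=draws, dataset_index=self.dataset_index,
                                variant=self.variant, config=config)
        rhats = [post.rhat(draws[k]) for k in result.scalar_names]
        result.worst_rhat = float(np.nanmax(rhats))
        result.converged = bool(result.worst_rhat < config.rhat_threshold)
        return result

    def _init_state(self, rng: np.random.Generator):
        p = self.n_params
        mu = np.array([_INIT_CENTRE[kind] for _, kind in self.param_specs]) + rng.normal(0, 0.5, p)
        sigma = np.abs(rng.normal(0, 0.3, p)) + 0.2
        delta = rng.normal(0, 0.2, (p, 2))
        means = self.design @ np.column_stack([mu, delta[:, 0], delta[:, 1]]).T
        theta = means + rng.normal(0, 0.2, (self.n_datasets, p)) * sigma[None, :]
        return mu, sigma, delta, theta

    def _run_chain(self, rng: np.random.Generator, config: McmcConfig) -> dict[str, np.ndarray]:
        pr = self.priors
        n_d, p = self.n_datasets, self.n_params
        mu, sigma, delta, theta = self._init_state(rng)
        ll = np.array([self.dataset_loglik(i, theta[i]) for i in range(n_d)])
        log_step = np.full(n_d, np.log(0.15))

        n_keep = config.n_draws // config.thin
        store: dict[str, np.ndarray] = {}
        for j, (name, _) in enumerate(self.param_specs):
            store[f"mu_{name}"] = np.empty(n_keep)
            store[f"sigma_{name}"] = np.empty(n_keep)
            store[f"delta_{name}_LU"] = np.empty(n_keep)
            store[f"delta_{name}_HU"] = np.empty(n_keep)
            store[f"{name}_i"] = np.empty((n_keep, n_d))

        prior_prec = np.diag([1.0 / pr.mean_scale ** 2, 1.0 / pr.delta_scale ** 2,
                              1.0 / pr.delta_scale ** 2])
        x = self.design
        xtx = x.T @ x
        kept = 0
        total = config.n_warmup + config.n_draws
        for sweep in range(total):
            warming = sweep < config.n_warmup
            means = x @ np.column_stack([mu, delta[:, 0], delta[:, 1]]).T

            # 1) adaptive random-walk Metropolis on each dataset's parameters
            steps = np.exp(log_step)
            noise = rng.normal(size=(n_d, p))
            log_u = np.log(rng.random(n_d))
            for i in range(n_d):
                prop = theta[i] + steps[i] * noise[i]
                ll_prop = self.dataset_loglik(i, prop)
                log_acc = (ll_prop - ll[i]
                           - 0.5 * np.sum(((prop - means[i]) / sigma) ** 2)
                           + 0.5 * np.sum(((theta[i] - means[i]) / sigma) ** 2))
                if log_u[i] < log_acc:
                    theta[i] = prop
                    ll[i] = ll_prop
                if warming:
                    acc = min(1.0, np.exp(min(log_acc, 0.0)))
                    log_step[i] += (acc - 0.30) / (1.0 + sweep) ** 0.6

            # 2) exact Gibbs draw of (mu_p, delta_p_LU, delta_p_HU)
            for j in range(p):
                prec = xtx / sigma[j] ** 2 + prior_prec
                rhs = x.T @ theta[:, j] / sigma[j] ** 2
                chol = np.linalg.cholesky(prec)
                mean_vec = np.linalg.solve(prec, rhs)
                z = rng.normal(size=3)
                draw = mean_vec + np.linalg.solve(chol.T, z)
                mu[j], delta[j, 0], delta[j, 1] = draw

            # 3) slice sampling of each group SD on the log scale
            means = x @ np.column_stack([mu, delta[:, 0], delta[:, 1]]).T
            for j in range(p):
                resid2 = float(np.sum((theta[:, j] - means[:, j]) ** 2))

                def logf(ls: float) -> float:
                    s = np.exp(ls)
                    return (-n_d * ls - resid2 / (2.0 * s * s)
                            - 0.5 * (s / pr.sigma_scale) ** 2 + ls)

                sigma[j] = np.exp(_slice_sample(logf, np.log(sigma[j]), rng))

            if not warming and (sweep - config.n_warmup) % config.thin == 0 and kept < n_keep:
                for j, (name, kind) in enumerate(self.param_specs):
                    store[f"mu_{name}"][kept] = mu[j]
                    store[f"sigma_{name}"][kept] = sigma[j]
                    store[f"delta_{name}_LU"][kept] = delta[j, 0]
                    store[f"delta_{name}_HU"][kept] = delta[j, 1]
                    store[f"{name}_i"][kept] = post.to_natural(theta[:, j], kind)
                kept += 1
        return store


def _slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    y = logf(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x1 = lo + (hi - lo) * rng.random()
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def pointwise_loglik(model: HierarchicalModel, draws: PosteriorDraws,
                     thin: int = 1) -> np.ndarray:
    """(draws, trials) matrix of per-trial log-likelihoods for WAIC.

    Columns concatenate every dataset's non-missed learning trials in the
    model's dataset order; rows are posterior draws (chains stacked, thinned
    by ``thin``).
    """
    if model.variant is ModelVariant.DUAL_RATE:
        nat = [draws.get("alpha_gain_i")[::thin], draws.get("alpha_loss_i")[::thin],
               draws.get("beta_i")[::thin]]
    else:
        a = draws.get("alpha_i")[::thin]
        nat = [a, a, draws.get("beta_i")[::thin]]
    n_draws = nat[0].shape[0]
    n_trials = sum(d.n_trials for d in model.datasets)
    out = np.empty((n_draws, n_trials))
    for d in range(n_draws):
        col = 0
        for i, data in enumerate(model.datasets):
            ll = loglik_from_arrays(data, nat[0][d, i], nat[1][d, i], nat[2][d, i],
                                    q_init=model.q_init)
            out[d, col: col + data.n_trials] = ll
            col += data.n_trials
    return out
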