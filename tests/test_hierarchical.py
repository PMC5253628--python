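"""Hierarchical model: joint density oracle, sampler correctness, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm, norm

from placebo_rl.cohort import GroupTruth, simulate_study
from placebo_rl.hierarchical import (HierarchicalModel, McmcConfig, PosteriorDraws,
                                     Priors, pointwise_loglik)
from placebo_rl.qlearning import AgentParams, ModelVariant, sequence_loglik

TINY = McmcConfig(n_chains=2, n_warmup=150, n_draws=150, seed=3)


def toy_study(n_trials_per_dataset=3) -> pd.DataFrame:
    """Two tiny single-subject datasets (baseline + HU)."""
    rows = []
    seqs = {"baseline": [("AB", "A", 1), ("AB", "B", 0), ("CD", "C", 1)],
            "HU": [("EF", "F", 0), ("AB", "A", 1), ("CD", "D", 0)]}
    for cond, seq in seqs.items():
        for i, (pair, choice, reward) in enumerate(seq[:n_trials_per_dataset]):
            rows.append({"subject_id": 1, "condition": cond, "phase": "learning",
                         "block": 0, "trial_index": i, "pair": pair, "choice": choice,
                         "correct": 1, "reward": reward, "rt": 0.5, "missed": 0})
    return pd.DataFrame(rows)


def hand_log_density(model, mu, sigma, delta, theta) -> float:
    """Term-by-term oracle: priors + hierarchy + likelihood, all explicit."""
    pr = model.priors
    total = 0.0
    for j in range(len(mu)):
        total += norm.logpdf(mu[j], 0, pr.mean_scale)
        total += halfnorm.logpdf(sigma[j], scale=pr.sigma_scale)
        total += norm.logpdf(delta[j, 0], 0, pr.delta_scale)
        total += norm.logpdf(delta[j, 1], 0, pr.delta_scale)
    for i in range(model.n_datasets):
        lu, hu = model.design[i, 1], model.design[i, 2]
        for j in range(len(mu)):
            mean = mu[j] + delta[j, 0] * lu + delta[j, 1] * hu
            total += norm.logpdf(theta[i, j], mean, sigma[j])
        total += model.dataset_loglik(i, theta[i])
    return total


class TestLogDensity:
    def test_matches_term_by_term_oracle(self):
        model = HierarchicalModel(toy_study())
        rng = np.random.default_rng(0)
        mu = rng.normal(0, 1, 3)
        sigma = np.abs(rng.normal(0.5, 0.2, 3)) + 0.05
        delta = rng.normal(0, 0.5, (3, 2))
        theta = rng.normal(0, 1, (2, 3))
        point = {"mu": mu, "sigma": sigma, "delta": delta, "theta": theta}
        assert model.log_density(point) == pytest.approx(
            hand_log_density(model, mu, sigma, delta, theta), abs=1e-9)

    def test_likelihood_term_is_sequence_loglik(self):
        model = HierarchicalModel(toy_study())
        theta = np.array([0.0, -1.0, 0.5])
        from scipy.special import expit

        params = AgentParams(expit(0.0), expit(-1.0), np.exp(0.5))
        trials = toy_study().query("condition == 'baseline'")
        i = model.dataset_index.query("condition == 'baseline'").index[0]
        assert model.dataset_loglik(i, theta) == pytest.approx(
            sequence_loglik(trials, params).sum(), abs=1e-10)

    def test_zero_data_limit_equals_log_prior(self):
        study = toy_study()
        study["phase"] = "test"  # no learning trials -> no likelihood terms
        model = HierarchicalModel(study)
        rng = np.random.default_rng(1)
        mu = rng.normal(0, 1, 3)
        sigma = np.array([0.5, 0.7, 0.3])
        delta = rng.normal(0, 1, (3, 2))
        theta = rng.normal(0, 1, (2, 3))
        got = model.log_density({"mu": mu, "sigma": sigma, "delta": delta, "theta": theta})
        assert got == pytest.approx(hand_log_density(model, mu, sigma, delta, theta), abs=1e-9)
        assert all(d.n_trials == 0 for d in model.datasets)

    def test_dual_equal_rates_matches_single_up_to_extra_priors(self):
        study = toy_study()
        dual = HierarchicalModel(study, variant=ModelVariant.DUAL_RATE)
        single = HierarchicalModel(study, variant=ModelVariant.SINGLE_RATE)
        rng = np.random.default_rng(2)
        mu_a, mu_b = -1.2, 0.4
        sig_a, sig_b = 0.6, 0.3
        d_a = rng.normal(0, 0.5, 2)
        d_b = rng.normal(0, 0.5, 2)
        theta_a = rng.normal(-1, 0.5, 2)
        theta_b = rng.normal(0.5, 0.3, 2)
        point_single = {"mu": [mu_a, mu_b], "sigma": [sig_a, sig_b],
                        "delta": np.vstack([d_a, d_b]),
                        "theta": np.column_stack([theta_a, theta_b])}
        point_dual = {"mu": [mu_a, mu_a, mu_b], "sigma": [sig_a, sig_a, sig_b],
                      "delta": np.vstack([d_a, d_a, d_b]),
                      "theta": np.column_stack([theta_a, theta_a, theta_b])}
        extra = norm.logpdf(mu_a, 0, dual.priors.mean_scale) \
            + halfnorm.logpdf(sig_a, scale=dual.priors.sigma_scale) \
            + norm.logpdf(d_a, 0, dual.priors.delta_scale).sum()
        for i in range(2):
            lu, hu = dual.design[i, 1], dual.design[i, 2]
            extra += norm.logpdf(theta_a[i], mu_a + d_a[0] * lu + d_a[1] * hu, sig_a)
        assert dual.log_density(point_dual) == pytest.approx(
            single.log_density(point_single) + extra, abs=1e-9)

    def test_single_dataset_refused(self):
        study = toy_study().query("condition == 'baseline'")
        with pytest.raises(ValueError):
            HierarchicalModel(study)


class GaussianToyModel(HierarchicalModel):
    """Hierarchical machinery with a Gaussian observation per dataset.

    Each dataset contributes N(y_i | theta_i0, tau); with tau small the
    transformed parameter is pinned to y_i and the group level reduces to
    the standard normal model, giving closed-form expectations to test the
    Gibbs/slice updates against.
    """

    def __init__(self, y: np.ndarray, tau: float):
        self.variant = ModelVariant.SINGLE_RATE
        self.priors = Priors()
        self.q_init = 0.5
        self.symbols = ("A", "B")
        self.param_specs = (("alpha", "logit"), ("beta", "log"))
        self.y = np.asarray(y, dtype=float)
        self.tau = float(tau)

        class _Stub:
            n_trials = 1

        self.datasets = [_Stub() for _ in y]
        self.dataset_index = pd.DataFrame({"subject_id": np.arange(len(y)),
                                           "condition": "baseline"})
        self.design = np.column_stack([np.ones(len(y)), np.zeros(len(y)), np.zeros(len(y))])

    def dataset_loglik(self, i, theta_row):
        return float(norm.logpdf(self.y[i], theta_row[0], self.tau))


class TestSamplerCorrectness:
    def test_group_posterior_matches_normal_model(self):
        rng = np.random.default_rng(11)
        y = rng.normal(-1.0, 0.6, 40)
        model = GaussianToyModel(y, tau=0.02)
        fit = model.fit(McmcConfig(n_chains=2, n_warmup=400, n_draws=600, seed=9))
        mu = fit.get("mu_alpha")
        sig = fit.get("sigma_alpha")
        # with theta pinned at y, mu | sigma ~ N(ybar, sigma/sqrt(n)) and the
        # prior is negligible at these scales
        assert mu.mean() == pytest.approx(y.mean(), abs=3 * y.std() / np.sqrt(len(y)))
        assert mu.std() == pytest.approx(y.std(ddof=1) / np.sqrt(len(y)), rel=0.35)
        assert sig.mean() == pytest.approx(y.std(ddof=1), rel=0.25)

    def test_fit_determinism(self, small_study):
        sub = small_study[small_study["subject_id"] <= 3]
        model = HierarchicalModel(sub)
        a = model.fit(TINY)
        b = HierarchicalModel(sub).fit(TINY)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k]), k

    def test_dataset_draws_on_natural_scale(self, small_study):
        sub = small_study[small_study["subject_id"] <= 3]
        fit = HierarchicalModel(sub).fit(TINY)
        for name in ("alpha_gain_i", "alpha_loss_i"):
            x = fit.get(name)
            assert np.all((x > 0) & (x < 1))
        assert np.all(fit.get("beta_i") > 0)

    def test_summary_and_registry(self, small_study):
        sub = small_study[small_study["subject_id"] <= 3]
        fit = HierarchicalModel(sub).fit(TINY)
        expected = {f"{kind}_{p}" for kind in ("mu", "sigma")
                    for p in ("alpha_gain", "alpha_loss", "beta")}
        expected |= {f"delta_{p}_{c}" for p in ("alpha_gain", "alpha_loss", "beta")
                     for c in ("LU", "HU")}
        assert expected <= set(fit.scalar_names)
        summary = fit.summary()
        assert (summary["hdi_low"] <= summary["hdi_high"]).all()
        assert np.isfinite(summary["rhat"]).all()

    def test_pointwise_loglik_shape_and_scale(self, small_study):
        sub = small_study[small_study["subject_id"] <= 3]
        model = HierarchicalModel(sub)
        fit = model.fit(TINY)
        ll = pointwise_loglik(model, fit, thin=10)
        n_trials = sum(d.n_trials for d in model.datasets)
        assert ll.shape == (2 * 15, n_trials)
        assert np.all(ll <= 0.0)
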