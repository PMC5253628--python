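"""Pipeline orchestration: simulate -> fit -> compare -> recover.

Library-level entry points behind the command-line interface.  A single
top-level seed fans out deterministically to every stage through
``numpy.random.SeedSequence`` spawning, so any published report is
re-derivable from config plus seed alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import GroupTruth, simulate_arousal, simulate_study, simulate_subjective
from .hierarchical import (FULL_PROFILE, REDUCED_PROFILE, HierarchicalModel, McmcConfig,
                           pointwise_loglik)
from .posterior import compare_models, exceedance_probability, hdi, waic
from .qlearning import ModelVariant
from .regressions import (fit_accuracy_model, fit_arousal_model, fit_rt_model,
                          fit_subjective_softmax)

log = logging.getLogger("placebo_rl")

GROUP_PARAM_TRUTH_MAP = {
    "mu_alpha_gain": lambda t: t.mu_alpha_gain,
    "mu_alpha_loss": lambda t: t.mu_alpha_loss,
    "mu_beta": lambda t: t.mu_log_beta,
    "sigma_alpha_gain": lambda t: t.sigma_alpha_gain,
    "sigma_alpha_loss": lambda t: t.sigma_alpha_loss,
    "sigma_beta": lambda t: t.sigma_log_beta,
    "delta_alpha_gain_LU": lambda t: t.delta[("alpha_gain", "LU")],
    "delta_alpha_gain_HU": lambda t: t.delta[("alpha_gain", "HU")],
    "delta_alpha_loss_LU": lambda t: t.delta[("alpha_loss", "LU")],
    "delta_alpha_loss_HU": lambda t: t.delta[("alpha_loss", "HU")],
    "delta_beta_LU": lambda t: t.delta[("beta", "LU")],
    "delta_beta_HU": lambda t: t.delta[("beta", "HU")],
}


def profile_config(profile: str, seed: int) -> McmcConfig:
    base = FULL_PROFILE if profile == "full" else REDUCED_PROFILE
    return McmcConfig(n_chains=base.n_chains, n_warmup=base.n_warmup,
                      n_draws=base.n_draws, seed=seed,
                      rhat_threshold=base.rhat_threshold, thin=base.thin)


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0] % (2 ** 31))


def cmd_simulate(config: pio.PipelineConfig, out_dir) -> dict:
    """Simulate a complete study and write its CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = config.seed
    trials = simulate_study(config.truth, config.rt, config.n_subjects,
                            seed=_stage_seed(seed, 1), config=config.task,
                            miss_rate=config.miss_rate)
    subjective = simulate_subjective(config.subjective_profiles, config.n_subjects,
                                     seed=_stage_seed(seed, 2))
    arousal = simulate_arousal(config.arousal, config.n_subjects, seed=_stage_seed(seed, 3))
    pio.write_trials(trials, out / "trials.csv", seed=seed)
    pio.write_table(subjective, out / "subjective.csv", seed=seed)
    pio.write_table(arousal, out / "arousal.csv", seed=seed)
    config.save(out / "config.yaml")
    manifest = pio.write_manifest(out, seed, [out / "trials.csv", out / "subjective.csv",
                                              out / "arousal.csv"])
    log.info("stage=simulate seed=%d duration=%.1fs", seed, time.time() - t0)
    return {"trials": str(out / "trials.csv"), "subjective": str(out / "subjective.csv"),
            "arousal": str(out / "arousal.csv"), "manifest": str(manifest)}


def fit_rl_models(trials: pd.DataFrame, mcmc: McmcConfig, waic_thin: int = 4) -> dict:
    """Fit dual- and single-rate hierarchical RL models and compare them by WAIC."""
    out = {}
    waics = {}
    for variant in (ModelVariant.DUAL_RATE, ModelVariant.SINGLE_RATE):
        t0 = time.time()
        model = HierarchicalModel(trials, variant=variant)
        fit = model.fit(mcmc)
        ll = pointwise_loglik(model, fit, thin=waic_thin)
        w = waic(ll)
        waics[variant.value] = w
        out[variant.value] = {
            "summary": fit.summary(),
            "fit": fit,
            "waic": w.waic,
            "p_waic": w.p_waic,
            "worst_rhat": fit.worst_rhat,
            "converged": fit.converged,
        }
        log.info("stage=fit_rl variant=%s seed=%d worst_rhat=%.3f duration=%.1fs",
                 variant.value, mcmc.seed, fit.worst_rhat, time.time() - t0)
    comp = compare_models(waics["dual_rate"], waics["single_rate"],
                          label_a="dual_rate", label_b="single_rate")
    out["comparison"] = {"delta_waic": comp.delta, "preferred": comp.preferred,
                         "strong": comp.strong}
    return out


def cmd_fit(study_dir, out_dir, profile: str = "reduced", seed: int = 0) -> dict:
    """Fit the RL models and all four behavioral regressions; write a run report."""
    study_dir, out = Path(study_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = pio.read_trials(study_dir / "trials.csv")
    subjective = pio.read_subjective(study_dir / "subjective.csv")
    arousal = pio.read_arousal(study_dir / "arousal.csv")

    mcmc = profile_config(profile, _stage_seed(seed, 10))
    rl = fit_rl_models(trials, mcmc)

    regressions = {}
    for label, fn, data in (("accuracy", fit_accuracy_model, trials),
                            ("rt", fit_rt_model, trials),
                            ("arousal", fit_arousal_model, arousal)):
        t0 = time.time()
        res = fn(data, seed=_stage_seed(seed, 20))
        res.to_frame().to_csv(out / f"regression_{label}.csv", index=False)
        regressions[label] = {"flags": res.flags,
                              "coefficients": {k: [c.mean, c.hdi_low, c.hdi_high]
                                               for k, c in res.coefficients.items()}}
        log.info("stage=regression model=%s duration=%.1fs", label, time.time() - t0)
    sm = fit_subjective_softmax(subjective, seed=_stage_seed(seed, 21))
    regressions["subjective"] = {"flags": sm.flags,
                                 "coefficients": {k: [c.mean, c.hdi_low, c.hdi_high]
                                                  for k, c in sm.coefficients.items()}}

    for variant in ("dual_rate", "single_rate"):
        rl[variant]["summary"].to_csv(out / f"posterior_{variant}.csv", index=False)
        rl[variant]["fit"].to_frame().to_csv(out / f"draws_{variant}.csv", index=False)

    dual = rl["dual_rate"]["fit"]
    effects = rl["dual_rate"]["summary"]
    effects = effects[effects["name"].str.startswith(("delta_", "mu_", "sigma_"))]
    report = {
        "status": "UNRELIABLE" if not rl["dual_rate"]["converged"] else "ok",
        "worst_rhat": rl["dual_rate"]["worst_rhat"],
        "waic": {"dual_rate": rl["dual_rate"]["waic"],
                 "single_rate": rl["single_rate"]["waic"],
                 **rl["comparison"]},
        "rl_effects": {row["name"]: [row["mean"], row["hdi_low"], row["hdi_high"]]
                       for _, row in effects.iterrows()},
        "p_delta_alpha_gain_HU_gt_LU": exceedance_probability(
            dual.get("delta_alpha_gain_HU"), dual.get("delta_alpha_gain_LU")),
        "regressions": regressions,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run_recovery(truth: GroupTruth, n_subjects: int, n_replicates: int,
                 profile: str = "reduced", seed: int = 0,
                 rt_truth=None) -> pd.DataFrame:
    """Simulate-fit loop: bias, HDI coverage and sign recovery per group parameter."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        study = simulate_study(truth, rt_truth, n_subjects, seed=_stage_seed(seed, 100 + rep))
        model = HierarchicalModel(study)
        fit = model.fit(profile_config(profile, _stage_seed(seed, 200 + rep)))
        p_hu_pos = exceedance_probability(fit.get("delta_alpha_gain_HU"),
                                          np.zeros(fit.get("delta_alpha_gain_HU").size))
        for name, get_truth in GROUP_PARAM_TRUTH_MAP.items():
            x = fit.get(name)
            lo, hi = hdi(x)
            true = float(get_truth(truth))
            rows.append({
                "replicate": rep, "parameter": name, "truth": true,
                "mean": float(x.mean()), "hdi_low": lo, "hdi_high": hi,
                "bias": float(x.mean()) - true,
                "covered": bool(lo <= true <= hi),
                "sign_correct": bool(np.sign(np.median(x)) == np.sign(true)) if true != 0 else None,
                "converged": fit.converged, "worst_rhat": fit.worst_rhat,
                "p_delta_alpha_gain_HU_positive": p_hu_pos,
            })
        log.info("stage=recover replicate=%d worst_rhat=%.3f", rep, fit.worst_rhat)
    return pd.DataFrame(rows)
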