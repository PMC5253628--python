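"""Synthetic cohort generator: populations, agents, studies, reports, arousal."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from placebo_rl.cohort import (ArousalCoefs, GroupTruth, sample_population,
                               simulate_agent, simulate_arousal, simulate_study,
                               simulate_subjective)
from placebo_rl.qlearning import AgentParams
from placebo_rl.task import TaskConfig, generate_learning_schedule, generate_test_schedule


def degenerate_truth(**kwargs) -> GroupTruth:
    base = dict(sigma_alpha_gain=0.0, sigma_alpha_loss=0.0, sigma_log_beta=0.0)
    base.update(kwargs)
    return GroupTruth(**base)


class TestSamplePopulation:
    def test_degenerate_distribution_returns_mean(self):
        truth = degenerate_truth(mu_alpha_gain=logit(0.07))
        truth = GroupTruth(mu_alpha_gain=logit(0.07), sigma_alpha_gain=0.0,
                           sigma_alpha_loss=0.0, sigma_log_beta=0.0,
                           delta={k: 0.0 for k in truth.delta})
        pop = sample_population(truth, 5, "baseline", seed=1)
        assert all(a.alpha_gain == pytest.approx(0.07, abs=1e-12) for a in pop)

    def test_condition_offset_closed_form(self):
        truth = degenerate_truth(mu_alpha_gain=-2.586)
        pop = sample_population(truth, 3, "HU", seed=2)
        # logit-scale -2.586 + 1.17 -> inverse logit
        assert all(a.alpha_gain == pytest.approx(expit(-1.416), abs=1e-6) for a in pop)
        assert pop[0].alpha_gain == pytest.approx(0.195, abs=1e-3)

    def test_positive_delta_raises_population_mean(self):
        truth = GroupTruth()
        base = sample_population(truth, 400, "baseline", seed=3)
        hu = sample_population(truth, 400, "HU", seed=3)
        assert np.mean([a.alpha_gain for a in hu]) > np.mean([a.alpha_gain for a in base])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            GroupTruth(sigma_alpha_gain=-0.1)

    def test_incomplete_delta_rejected(self):
        with pytest.raises(ValueError):
            GroupTruth(delta={("alpha_gain", "LU"): 0.5})

    def test_tied_rates(self):
        pop = sample_population(GroupTruth(), 10, "baseline", seed=4, tie_rates=True)
        assert all(a.alpha_gain == a.alpha_loss for a in pop)


@pytest.fixture(scope="module")
def schedule(config):
    return pd.concat([generate_learning_schedule(config, 1),
                      generate_test_schedule(config, 2)], ignore_index=True)


class TestSimulateAgent:
    def test_zero_beta_is_chance(self, config, schedule):
        recs = [simulate_agent(AgentParams(0.3, 0.1, 0.0), schedule, config, seed=s)
                for s in range(10)]
        acc = pd.concat(recs)["correct"].mean()
        assert acc == pytest.approx(0.5, abs=0.02)

    def test_easy_pair_learned_better_than_hard_pair(self, config):
        # final-block accuracy: 80/20 pair should beat 60/40 with a sharp learner
        wins = 0
        for s in range(200):
            sched = generate_learning_schedule(config, seed=s)
            rec = simulate_agent(AgentParams(0.3, 0.01, 5.0), sched, config, seed=1000 + s)
            last = rec[rec["block"] == 5]
            ab = last[last["pair"] == "AB"]["correct"].mean()
            ef = last[last["pair"] == "EF"]["correct"].mean()
            wins += ab > ef
        assert wins > 120

    def test_determinism(self, config, schedule):
        p = AgentParams(0.2, 0.05, 3.0)
        a = simulate_agent(p, schedule, config, seed=77)
        b = simulate_agent(p, schedule, config, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_trial_record_invariants(self, config, schedule):
        rec = simulate_agent(AgentParams(0.2, 0.05, 3.0), schedule, config, seed=5,
                             miss_rate=0.1)
        ok = rec["missed"] == 0
        assert rec.loc[~ok, "rt"].isna().all()
        assert (rec.loc[ok, "rt"] <= config.response_window + 1e-9).all()
        # feedback exists only on non-missed learning trials
        learning = rec["phase"] == "learning"
        assert set(rec.loc[learning & ok, "reward"]) <= {0, 1}
        assert (rec.loc[~(learning & ok), "reward"] == -1).all()

    def test_higher_beta_raises_easy_pair_accuracy(self, config):
        means = []
        for beta in (0.5, 2.0, 6.0):
            accs = []
            for s in range(40):
                sched = generate_learning_schedule(config, seed=200 + s)
                rec = simulate_agent(AgentParams(0.2, 0.2, beta), sched, config,
                                     seed=300 + s)
                accs.append(rec[rec["pair"] == "AB"]["correct"].mean())
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]


class TestSimulateStudy:
    def test_shapes_and_counts(self, small_study):
        assert small_study["subject_id"].nunique() == 6
        assert set(small_study["condition"]) == {"baseline", "LU", "HU"}
        learn = small_study[small_study["phase"] == "learning"]
        assert len(learn) == 6 * 3 * 360
        test = small_study[small_study["phase"] == "test"]
        assert len(test) == 6 * 3 * 180

    def test_single_subject_refused(self, default_truth):
        with pytest.raises(ValueError):
            simulate_study(default_truth, n_subjects=1, seed=1)

    def test_zero_deltas_make_conditions_exchangeable(self):
        truth = GroupTruth(delta={k: 0.0 for k in GroupTruth().delta})
        diffs = []
        for rep in range(12):
            df = simulate_study(truth, n_subjects=6, seed=500 + rep)
            learn = df[df["phase"] == "learning"]
            acc = learn.groupby("condition")["correct"].mean()
            diffs.append(acc["HU"] - acc["baseline"])
        assert abs(np.mean(diffs)) < 0.02

    def test_placebo_conditions_boost_accuracy(self, default_truth):
        hu_beats_lu = 0
        lu_beats_base = 0
        n = 15
        for rep in range(n):
            df = simulate_study(default_truth, n_subjects=8, seed=900 + rep)
            acc = df[df["phase"] == "learning"].groupby("condition")["correct"].mean()
            hu_beats_lu += acc["HU"] > acc["LU"]
            lu_beats_base += acc["LU"] > acc["baseline"]
        assert lu_beats_base > n / 2
        assert hu_beats_lu > n / 2


class TestSimulateSubjective:
    def test_degenerate_profile(self):
        profiles = {("LU", "anticipated"): (0.0, 0.0, 1.0)}
        df = simulate_subjective(profiles, n_subjects=20, seed=1)
        assert (df["response"] == "improve").all()

    def test_empirical_frequencies(self):
        profiles = {("LU", "anticipated"): (0.07, 0.34, 0.59)}
        df = simulate_subjective(profiles, n_subjects=10_000, seed=2)
        freq = df["response"].value_counts(normalize=True)
        assert freq["decline"] == pytest.approx(0.07, abs=0.02)
        assert freq["neutral"] == pytest.approx(0.34, abs=0.02)
        assert freq["improve"] == pytest.approx(0.59, abs=0.02)

    def test_default_profiles_complete(self):
        df = simulate_subjective(n_subjects=5, seed=3)
        assert len(df) == 5 * 4  # 2 conditions x 2 questions
        counts = df.groupby(["subject_id", "condition", "question"]).size()
        assert set(counts) == {1}

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError):
            simulate_subjective({("LU", "anticipated"): (0.5, 0.1, 0.1)}, 5, 1)


class TestSimulateArousal:
    def test_zero_noise_rounding(self):
        coefs = ArousalCoefs(subject_sd=0.0, noise_sd=0.0)
        df = simulate_arousal(coefs, n_subjects=3, seed=1)
        base = df[df["condition"] == "baseline"]
        assert (base[base["time"] == "before"]["rating"] == 7).all()   # round(7.22)
        assert (base[base["time"] == "after"]["rating"] == 6).all()    # round(6.31)

    def test_constant_when_all_effects_zero(self):
        coefs = ArousalCoefs(intercept=5.0, b_after=0, b_LU=0, b_HU=0,
                             b_LU_after=0, b_HU_after=0, subject_sd=0.0, noise_sd=0.0)
        df = simulate_arousal(coefs, n_subjects=4, seed=2)
        assert (df["rating"] == 5).all()

    def test_clipping_to_scale(self):
        coefs = ArousalCoefs(intercept=12.0, subject_sd=0.0, noise_sd=0.0,
                             b_after=0, b_LU=0, b_HU=0, b_LU_after=0, b_HU_after=0)
        df = simulate_arousal(coefs, n_subjects=3, seed=3)
        assert (df["rating"] == 10).all()

    def test_ratings_within_scale(self):
        df = simulate_arousal(ArousalCoefs(noise_sd=5.0), n_subjects=50, seed=4)
        assert df["rating"].between(0, 10).all()
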