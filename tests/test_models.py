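import math

import numpy as np
import pandas as pd
import pytest

from semtraj.models import (
    ConvergenceReport,
    DifferenceSummary,
    MCMCConfig,
    MixedModelSpec,
    PowerLawPosterior,
    PowerLawSpec,
    check_convergence,
    compare_null_model,
    difference_distribution,
    fit_mixed_model,
    fit_power_law,
    leave_one_out_by_subject,
    power_curve,
    split_rhat,
)
from semtraj.synth import generate_power_law_records
from semtraj.trajectory import records_to_frame

FAST = MCMCConfig(chains=2, iterations=400, seed=0)


def _mixed_frame(beta=0.05, sigma_s=0.05, sigma_w=0.05, sigma_e=0.3,
                 n_co=10, n_hp=4, n_words=15, n_reps=2, mu=-1.6, seed=0):
    """Lognormal mixed-effects data with known generating parameters."""
    rng = np.random.default_rng(seed)
    rows = []
    words = [f"w{k:02d}" for k in range(n_words)]
    w_eff = rng.normal(0, sigma_w, size=n_words)
    for group, count in (("CO", n_co), ("HP", n_hp)):
        for j in range(count):
            sid = f"{group}{j:02d}"
            s_eff = rng.normal(0, sigma_s)
            for k, word in enumerate(words):
                for _ in range(n_reps):
                    log_y = (mu + (beta if group == "HP" else 0.0) + s_eff
                             + w_eff[k] + rng.normal(0, sigma_e))
                    rows.append(dict(subject_id=sid, group=group, target_word=word,
                                     score=float(np.exp(log_y))))
    return pd.DataFrame(rows)


class TestSplitRhat:
    def test_identical_distribution_chains(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.02)

    def test_offset_chain_fails(self, rng):
        chains = rng.standard_normal((4, 500))
        chains[0] += 50.0
        assert split_rhat(chains) > 5.0

    def test_textbook_formula_oracle(self, rng):
        # independent implementation from the split-half definition
        chains = rng.standard_normal((3, 200)) * 1.3 + 0.4
        chains[1] *= 1.5
        n = 100
        halves = [chains[c, i * n:(i + 1) * n] for c in range(3) for i in range(2)]
        m = len(halves)
        means = [float(np.mean(h)) for h in halves]
        variances = [float(np.var(h, ddof=1)) for h in halves]
        w = sum(variances) / m
        grand = sum(means) / m
        b = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
        expected = math.sqrt(((n - 1) / n * w + b / n) / w)
        assert split_rhat(chains) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_arviz(self, rng):
        import arviz as az

        chains = rng.standard_normal((4, 400))
        chains[2] += 0.3
        ours = split_rhat(chains)
        theirs = float(az.rhat(chains))  # rank-normalized variant
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_single_chain_raises(self, rng):
        with pytest.raises(ValueError):
            split_rhat(rng.standard_normal((1, 100)))


class TestCheckConvergence:
    def test_good_chains_pass(self, rng):
        draws = {"theta": rng.standard_normal((4, 2000))}
        report = check_convergence(draws, threshold=1.01)
        assert report.passed
        assert report.ess["theta"] > 100

    def test_bad_chain_detected(self, rng):
        draws = {"theta": rng.standard_normal((4, 500))}
        draws["theta"][0] += 10
        report = check_convergence(draws, threshold=1.01)
        assert not report.passed
        assert report.rhat["theta"] > 1.5

    def test_single_chain_raises(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence({"theta": rng.standard_normal((1, 500))})

    def test_vector_params_expanded(self, rng):
        draws = {"v": rng.standard_normal((4, 200, 3))}
        report = check_convergence(draws)
        assert set(report.rhat) == {"v[0]", "v[1]", "v[2]"}


class TestMixedModel:
    def test_null_effect_covers_zero(self):
        df = _mixed_frame(beta=0.0, seed=3)
        post, _ = fit_mixed_model(df, MixedModelSpec(), FAST)
        beta = post.flat("beta_group")
        lo, hi = np.percentile(beta, [2.5, 97.5])
        assert lo <= 0.0 <= hi

    def test_known_effect_recovered(self):
        df = _mixed_frame(beta=0.05, n_co=15, n_hp=5, n_words=35, seed=4)
        post, _ = fit_mixed_model(df, MixedModelSpec(),
                                  MCMCConfig(chains=2, iterations=600, seed=1))
        beta = post.flat("beta_group")
        assert abs(beta.mean() - 0.05) < 2 * beta.std()

    def test_single_group_raises(self):
        df = _mixed_frame(n_hp=0)
        with pytest.raises(ValueError, match="two groups"):
            fit_mixed_model(df, MixedModelSpec(), FAST)

    def test_nonpositive_scores_dropped_and_counted(self):
        df = _mixed_frame(seed=5)
        df.loc[:4, "score"] = -0.01
        post, _ = fit_mixed_model(df, MixedModelSpec(), FAST)
        assert post.n_dropped == 5
        assert post.n_obs == len(df) - 5

    def test_shift_min_policy_keeps_everything(self):
        df = _mixed_frame(seed=5)
        df.loc[:4, "score"] = -0.01
        spec = MixedModelSpec(lognormal_policy="shift_min")
        post, _ = fit_mixed_model(df, spec, FAST)
        assert post.n_dropped == 0
        assert post.n_obs == len(df)
        assert post.shift > 0.01

    def test_normal_family_allows_negatives(self):
        df = _mixed_frame(seed=6)
        df["score"] = df["score"] - df["score"].mean()
        post, _ = fit_mixed_model(df, MixedModelSpec(response_family="normal"), FAST)
        assert post.n_dropped == 0

    def test_sigma_draws_positive(self):
        df = _mixed_frame(seed=7, n_words=8, n_reps=1)
        post, _ = fit_mixed_model(df, MixedModelSpec(), FAST)
        for name in ("sigma_subject", "sigma_word", "sigma_resid"):
            assert np.all(post.flat(name) > 0)

    def test_draw_bookkeeping(self):
        df = _mixed_frame(seed=8, n_words=8, n_reps=1)
        mcmc = MCMCConfig(chains=3, iterations=200, warmup=120, seed=2)
        post, _ = fit_mixed_model(df, MixedModelSpec(), mcmc)
        assert post.draws["beta_group"].shape == (3, 80)

    def test_reproducible_given_seed(self):
        df = _mixed_frame(seed=9, n_words=8, n_reps=1)
        p1, _ = fit_mixed_model(df, MixedModelSpec(), FAST)
        p2, _ = fit_mixed_model(df, MixedModelSpec(), FAST)
        assert np.array_equal(p1.flat("beta_group"), p2.flat("beta_group"))


class TestPowerLaw:
    def test_f_of_one_equals_a(self):
        xs = np.arange(1, 6)
        assert power_curve(0.37, -1.2, 1) == pytest.approx(0.37)
        assert power_curve(0.37, 0.0, xs) == pytest.approx([0.37] * 5)

    def test_recovery_small(self):
        co, _ = generate_power_law_records(a=0.25, b=-0.2, noise_sd=0.05,
                                           n_subjects=8, x_max=5, seed=1,
                                           n_reps=15, group="CO")
        hp, _ = generate_power_law_records(a=0.25, b=-0.1, noise_sd=0.05,
                                           n_subjects=4, x_max=5, seed=2,
                                           n_reps=15, group="HP")
        post, _ = fit_power_law(records_to_frame(co + hp), PowerLawSpec(),
                                MCMCConfig(chains=2, iterations=500, seed=3))
        assert post.group_mean("a", "CO").mean() == pytest.approx(0.25, abs=0.04)
        assert post.group_mean("b", "CO").mean() == pytest.approx(-0.2, abs=0.06)
        assert post.group_mean("b", "HP").mean() == pytest.approx(-0.1, abs=0.06)

    def test_b_zero_gives_flat_fit(self):
        recs, _ = generate_power_law_records(a=0.3, b=0.0, noise_sd=0.02,
                                             n_subjects=4, x_max=5, seed=4,
                                             n_reps=10, group="CO")
        hp, _ = generate_power_law_records(a=0.3, b=0.0, noise_sd=0.02,
                                           n_subjects=4, x_max=5, seed=5,
                                           n_reps=10, group="HP")
        df = records_to_frame(recs + hp)
        post, _ = fit_power_law(df, PowerLawSpec(),
                                MCMCConfig(chains=2, iterations=500, seed=6))
        assert post.group_mean("b", "CO").mean() == pytest.approx(0.0, abs=0.03)
        assert post.group_mean("a", "CO").mean() == pytest.approx(
            df[df.group == "CO"]["score"].mean(), abs=0.02)

    def test_near_noiseless_interpolation(self):
        # one subject, tiny noise: posterior mean curve passes through the data
        recs, _ = generate_power_law_records(a=0.25, b=-0.15, noise_sd=1e-4,
                                             n_subjects=2, x_max=5, seed=7,
                                             n_reps=5, group="CO")
        hp, _ = generate_power_law_records(a=0.25, b=-0.15, noise_sd=1e-4,
                                           n_subjects=2, x_max=5, seed=8,
                                           n_reps=5, group="HP")
        post, _ = fit_power_law(records_to_frame(recs + hp), PowerLawSpec(),
                                MCMCConfig(chains=2, iterations=500, seed=9))
        a = post.group_mean("a", "CO").mean()
        b = post.group_mean("b", "CO").mean()
        for x in range(1, 6):
            assert power_curve(a, b, x) == pytest.approx(0.25 * x ** -0.15, abs=0.01)

    def test_requires_two_x_levels(self):
        recs, _ = generate_power_law_records(a=0.2, b=-0.1, noise_sd=0.01,
                                             n_subjects=2, x_max=2, seed=1)
        df = records_to_frame(recs)
        df = df[df.position == 1]
        with pytest.raises(ValueError, match="x levels"):
            fit_power_law(df, PowerLawSpec())

    def test_subject_means_mode(self):
        recs, _ = generate_power_law_records(a=0.25, b=-0.2, noise_sd=0.05,
                                             n_subjects=4, x_max=5, seed=10,
                                             n_reps=10, group="CO")
        hp, _ = generate_power_law_records(a=0.25, b=-0.2, noise_sd=0.05,
                                           n_subjects=4, x_max=5, seed=11,
                                           n_reps=10, group="HP")
        post, _ = fit_power_law(records_to_frame(recs + hp),
                                PowerLawSpec(data_mode="subject_means"),
                                MCMCConfig(chains=2, iterations=400, seed=12))
        assert post.group_mean("a", "CO").mean() == pytest.approx(0.25, abs=0.05)


class TestDifferenceDistribution:
    @staticmethod
    def _posterior(hp_a, co_a):
        draws = {
            "mean_a_HP": np.asarray(hp_a, dtype=float).reshape(1, -1),
            "mean_a_CO": np.asarray(co_a, dtype=float).reshape(1, -1),
            "mean_b_HP": np.zeros((1, len(hp_a))),
            "mean_b_CO": np.zeros((1, len(hp_a))),
        }
        return PowerLawPosterior(draws=draws, subjects=[], subject_groups={},
                                 spec=PowerLawSpec())

    def test_identical_draws(self):
        post = self._posterior([0.25, 0.26, 0.24], [0.25, 0.26, 0.24])
        summary, diff = difference_distribution(post, "a")
        assert summary.mean == 0.0
        assert np.all(diff == 0.0)

    def test_hand_enumerated_draws(self):
        # oracle: enumerate the four per-draw differences by hand
        hp = [0.25, 0.26, 0.24, 0.27]
        co = [0.24, 0.25, 0.25, 0.25]
        diffs = [h - c for h, c in zip(hp, co)]  # .01, .01, -.01, .02
        post = self._posterior(hp, co)
        summary, diff = difference_distribution(post, "a")
        assert diff.tolist() == pytest.approx(diffs, abs=1e-15)
        assert summary.mean == pytest.approx(sum(diffs) / 4)
        assert summary.proportion_positive == 0.75

    def test_antisymmetry(self):
        hp = [0.25, 0.26, 0.24, 0.27]
        co = [0.24, 0.25, 0.25, 0.25]
        _, d1 = difference_distribution(self._posterior(hp, co), "a")
        _, d2 = difference_distribution(self._posterior(co, hp), "a")
        assert np.allclose(d1, -d2)

    def test_strong_effect_proportion_near_one(self):
        co, _ = generate_power_law_records(a=0.25, b=-0.3, noise_sd=0.03,
                                           n_subjects=6, x_max=5, seed=20,
                                           n_reps=10, group="CO")
        hp, _ = generate_power_law_records(a=0.25, b=-0.05, noise_sd=0.03,
                                           n_subjects=4, x_max=5, seed=21,
                                           n_reps=10, group="HP")
        post, _ = fit_power_law(records_to_frame(co + hp), PowerLawSpec(),
                                MCMCConfig(chains=2, iterations=400, seed=22))
        summary, _ = difference_distribution(post, "b")
        assert summary.proportion_positive > 0.95

    def test_invalid_parameter(self):
        with pytest.raises(ValueError):
            difference_distribution(self._posterior([0.1], [0.1]), "c")

    def test_summary_validation(self):
        with pytest.raises(ValueError):
            DifferenceSummary("a", 0.0, 1.5, (0.0, 1.0))
        with pytest.raises(ValueError):
            DifferenceSummary("a", 0.0, 0.5, (1.0, 0.0))


class TestLeaveOneOut:
    def test_consistent_effect_survives_every_exclusion(self):
        df = _mixed_frame(beta=0.4, sigma_e=0.2, n_co=9, n_hp=4,
                          n_words=12, seed=30)
        results = leave_one_out_by_subject(df, MixedModelSpec(), FAST)
        assert len(results) == 4
        assert all(r.excludes_zero for r in results)

    def test_outlier_driven_effect_flips(self):
        df = _mixed_frame(beta=0.0, sigma_s=0.02, sigma_e=0.2,
                          n_co=9, n_hp=4, n_words=12, seed=31)
        # effect carried by exactly one subject
        driver = "HP00"
        df.loc[df.subject_id == driver, "score"] *= np.exp(1.2)
        results = leave_one_out_by_subject(df, MixedModelSpec(), FAST)
        flipped = {r.excluded_subject: r.excludes_zero for r in results}
        assert flipped[driver] is False
        assert any(v for s, v in flipped.items() if s != driver)

    def test_too_few_subjects(self):
        df = _mixed_frame(n_hp=2, seed=32)
        with pytest.raises(ValueError, match="3 subjects"):
            leave_one_out_by_subject(df, MixedModelSpec(), FAST)


class TestCoverageCalibration:
    """~95% intervals should cover the generating value in most seeded runs."""

    def test_mixed_model_beta_coverage(self):
        mcmc = MCMCConfig(chains=2, iterations=300, seed=0)
        covered = 0
        n_sims = 20
        for sim in range(n_sims):
            df = _mixed_frame(beta=0.05, n_co=8, n_hp=4, n_words=10, n_reps=1,
                              seed=100 + sim)
            post, _ = fit_mixed_model(df, MixedModelSpec(), mcmc)
            lo, hi = np.percentile(post.flat("beta_group"), [2.5, 97.5])
            covered += lo <= 0.05 <= hi
        assert covered >= 0.85 * n_sims

    def test_power_law_b_coverage(self):
        mcmc = MCMCConfig(chains=2, iterations=400, seed=0)
        covered = 0
        n_sims = 20
        for sim in range(n_sims):
            co, _ = generate_power_law_records(
                a=0.25, b=-0.2, noise_sd=0.05, n_subjects=6, x_max=5,
                seed=200 + sim, n_reps=8, group="CO", subject_sd_b=0.03)
            hp, _ = generate_power_law_records(
                a=0.25, b=-0.2, noise_sd=0.05, n_subjects=4, x_max=5,
                seed=500 + sim, n_reps=8, group="HP", subject_sd_b=0.03)
            post, _ = fit_power_law(records_to_frame(co + hp), PowerLawSpec(), mcmc)
            lo, hi = np.percentile(post.group_mean("b", "CO"), [2.5, 97.5])
            covered += lo <= -0.2 <= hi
        assert covered >= 0.85 * n_sims


class TestNullModelComparison:
    def test_runs_and_returns_finite(self):
        df = _mixed_frame(beta=0.3, n_co=6, n_hp=3, n_words=8, n_reps=1, seed=40)
        out = compare_null_model(df, MixedModelSpec(),
                                 MCMCConfig(chains=2, iterations=200, seed=1))
        assert np.isfinite(out["elpd_diff"])
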