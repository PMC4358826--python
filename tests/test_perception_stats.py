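import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from objdensity import (
    RatioLine,
    ObserverGenConfig,
    cohens_d,
    fdr_correct,
    fit_perceptual_lines,
    gen_observer_trials,
    lilliefors_test,
    mixed_anova,
    normalize_response,
    one_sample_t,
    pair_effect_sizes,
    posthoc_pair_anovas,
    posthoc_report,
    subject_pair_means,
    stimulus_volume_ratios,
    volume_error_ttests,
)
from objdensity.perception_stats import (
    OBJECT_SETS,
    ResponseTrial,
    _lilliefors_d,
    mixed_anova_one_within,
)
from objdensity.pair_ratios import STIMULUS_PAIRS

# frozen BH step-up q-values for p = {.025, .032, .009, .042, .031, .012}
BH_ORACLE = [0.0384, 0.0384, 0.036, 0.042, 0.0384, 0.036]


class TestNormalizeResponse:
    def test_small_left_twice_as_heavy(self):
        assert normalize_response("S-L", 20) == pytest.approx(math.log(0.5))

    def test_large_left_half(self):
        assert normalize_response("L-S", 5) == pytest.approx(math.log(0.5))

    def test_indifference(self):
        assert normalize_response("S-L", 10) == 0.0
        assert normalize_response("L-S", 10) == 0.0

    def test_non_positive_report(self):
        with pytest.raises(ValueError):
            normalize_response("S-L", 0)

    @given(st.floats(0.1, 1000))
    def test_order_reciprocal_symmetry(self, r):
        assert normalize_response("S-L", r) == pytest.approx(
            normalize_response("L-S", 100.0 / r), abs=1e-12
        )


class TestSubjectPairMeans:
    @staticmethod
    def _trials(reports_sl, reports_ls):
        rows = []
        for r in reports_sl:
            rows.append(ResponseTrial("s1", "EW", "Blobs", "AC", "S-L", r))
        for r in reports_ls:
            rows.append(ResponseTrial("s1", "EW", "Blobs", "AC", "L-S", r))
        return rows

    def test_all_twice(self):
        s = subject_pair_means(self._trials([20] * 10, [5] * 10))
        assert len(s) == 1
        assert s.loc[0, "mean_log_ratio"] == pytest.approx(math.log(0.5))
        assert s.loc[0, "n_trials"] == 20

    def test_order_symmetry(self):
        a = subject_pair_means(self._trials([20] * 10, [5] * 10))
        b = subject_pair_means(self._trials([20] * 20, []))
        assert a.loc[0, "mean_log_ratio"] == pytest.approx(b.loc[0, "mean_log_ratio"])

    def test_simulation_mean_matches_generative_expectation(self):
        cfg = ObserverGenConfig(
            n_per_group=40, compression_beta=1.0,
            prior_line=RatioLine(0.0, 0.0, "density"),
            report_log_noise_sd=0.3, trials_per_cell=10, seed=5,
        )
        s = subject_pair_means(gen_observer_trials(cfg))
        ratios = stimulus_volume_ratios()
        sub = s[(s["object_set"] == "Blobs") & (s["pair"] == "AD")]
        expected = math.log(ratios["Blobs"]["AD"])
        sem = 0.3 / math.sqrt(20 * len(sub))
        assert sub["mean_log_ratio"].mean() == pytest.approx(expected, abs=4 * sem)


class TestLilliefors:
    def test_d_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf

        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.gamma(2.0, size=30)
            d_sm, _ = sm_lf(x, dist="norm")
            assert _lilliefors_d(x) == pytest.approx(d_sm, abs=1e-12)

    def test_normal_quantiles_large_p(self):
        x = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        res = lilliefors_test(x, n_reps=2000, seed=1)
        assert res.p > 0.5

    def test_bimodal_rejected(self):
        x = np.array([-1.0] * 10 + [1.0] * 10)
        res = lilliefors_test(x, n_reps=2000, seed=1)
        assert res.p < 0.05

    def test_critical_value_against_brute_force_null(self):
        # independent null: statsmodels D on fresh standard-normal samples
        from statsmodels.stats.diagnostic import lilliefors as sm_lf

        rng = np.random.default_rng(123)
        d_null = np.array(
            [sm_lf(rng.standard_normal(20), dist="norm")[0] for _ in range(4000)]
        )
        crit = np.quantile(d_null, 0.95)
        assert crit == pytest.approx(0.19, abs=0.01)  # literature value at n = 20
        # a sample sitting at the critical D should get p ~ 0.05 from our MC
        x = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        x[-1] += 3.2  # push D close to crit
        d = _lilliefors_d(x)
        p = lilliefors_test(x, n_reps=4000, seed=9).p
        expected = float(np.mean(d_null >= d))
        assert p == pytest.approx(expected, abs=0.02)

    def test_constant_sample(self):
        with pytest.raises(ValueError):
            lilliefors_test([1.0] * 10)

    def test_seed_reproducibility(self):
        x = np.random.default_rng(3).normal(size=25)
        assert lilliefors_test(x, seed=4).p == lilliefors_test(x, seed=4).p


class TestOneSampleT:
    def test_hand_formula(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.statistic == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_mean_equals_mu0(self):
        res = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)


class TestCohensD:
    def test_identical_groups_zero(self):
        res = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_hand_value(self):
        # means 2 and 0, sds 1 and 1 -> pooled sd 1 -> d = 2
        a = [1.0, 2.0, 3.0]
        b = [-1.0, 0.0, 1.0]
        assert cohens_d(a, b).statistic == pytest.approx(2.0)

    def test_degenerate_zero_pooled_sd(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([0.0, 0.0], [1.0, 1.0])


class TestFdrCorrect:
    def test_step_up_oracle(self):
        q = fdr_correct([0.025, 0.032, 0.009, 0.042, 0.031, 0.012])
        assert q == pytest.approx(BH_ORACLE, abs=1e-12)

    def test_single_p(self):
        assert fdr_correct([0.03]) == [0.03]

    def test_all_equal(self):
        assert fdr_correct([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_correct([0.0, 0.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_monotone_and_never_below_raw(self, ps):
        q = fdr_correct(ps)
        order = np.argsort(ps)
        sorted_q = np.array(q)[order]
        assert np.all(np.diff(sorted_q) >= -1e-15)
        assert all(qq >= pp - 1e-15 for qq, pp in zip(q, ps))
        assert all(qq <= 1.0 for qq in q)


def oracle_split_plot(y):
    """Explicit-loop textbook SS decomposition for Y[g, s, a, b]."""
    G, n, p, q = y.shape
    m = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_gs = y.mean(axis=(2, 3))
    m_a = y.mean(axis=(0, 1, 3))
    m_b = y.mean(axis=(0, 1, 2))
    m_ga = y.mean(axis=(1, 3))
    m_gb = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=(0, 1))
    m_gab = y.mean(axis=1)
    m_gsa = y.mean(axis=3)
    m_gsb = y.mean(axis=2)
    ss = {}
    ss["cond"] = n * p * q * sum((m_g[g] - m) ** 2 for g in range(G))
    ss["subj"] = p * q * sum(
        (m_gs[g, s] - m_g[g]) ** 2 for g in range(G) for s in range(n)
    )
    ss["A"] = G * n * q * sum((m_a[a] - m) ** 2 for a in range(p))
    ss["GA"] = n * q * sum(
        (m_ga[g, a] - m_g[g] - m_a[a] + m) ** 2 for g in range(G) for a in range(p)
    )
    ss["A_err"] = q * sum(
        (m_gsa[g, s, a] - m_gs[g, s] - m_ga[g, a] + m_g[g]) ** 2
        for g in range(G) for s in range(n) for a in range(p)
    )
    ss["B"] = G * n * p * sum((m_b[b] - m) ** 2 for b in range(q))
    ss["GB"] = n * p * sum(
        (m_gb[g, b] - m_g[g] - m_b[b] + m) ** 2 for g in range(G) for b in range(q)
    )
    ss["B_err"] = p * sum(
        (m_gsb[g, s, b] - m_gs[g, s] - m_gb[g, b] + m_g[g]) ** 2
        for g in range(G) for s in range(n) for b in range(q)
    )
    ss["AB"] = G * n * sum(
        (m_ab[a, b] - m_a[a] - m_b[b] + m) ** 2 for a in range(p) for b in range(q)
    )
    ss["GAB"] = n * sum(
        (m_gab[g, a, b] - m_ga[g, a] - m_gb[g, b] - m_ab[a, b]
         + m_g[g] + m_a[a] + m_b[b] - m) ** 2
        for g in range(G) for a in range(p) for b in range(q)
    )
    ss_total = float(((y - m) ** 2).sum())
    ss["AB_err"] = ss_total - sum(
        ss[k] for k in ("cond", "subj", "A", "GA", "A_err", "B", "GB", "B_err",
                        "AB", "GAB")
    )
    return ss


def summaries_from_array(y, sets, pairs):
    """Build a subject_pair_means-style frame from Y[g, s, a, b]."""
    rows = []
    groups = ("EW", "PV")
    for g in range(y.shape[0]):
        for s in range(y.shape[1]):
            for a, oset in enumerate(sets):
                for b, pair in enumerate(pairs):
                    rows.append(
                        {"subject": f"{groups[g]}{s:02d}", "group": groups[g],
                         "object_set": oset, "pair": pair,
                         "mean_log_ratio": y[g, s, a, b], "n_trials": 20}
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(2, 4, 3, 6))
        summaries = summaries_from_array(y, OBJECT_SETS, STIMULUS_PAIRS)
        table = mixed_anova(summaries)
        ss = oracle_split_plot(y)
        checks = {
            "condition": ("cond", "subj", 1, 2 * 3),
            "object_set": ("A", "A_err", 2, 2 * 2 * 3),
            "pair": ("B", "B_err", 5, 5 * 2 * 3),
            "object_set x pair": ("AB", "AB_err", 10, 10 * 2 * 3),
            "object_set x pair x condition": ("GAB", "AB_err", 10, 10 * 2 * 3),
        }
        for effect, (num, den, dfn, dfd) in checks.items():
            row = table[effect]
            expected_f = (ss[num] / dfn) / (ss[den] / dfd)
            assert row.F == pytest.approx(expected_f, rel=1e-9), effect
            assert (row.df_num, row.df_den) == (dfn, dfd)
            assert row.p == pytest.approx(stats.f.sf(expected_f, dfn, dfd), rel=1e-9)

    def test_identical_groups_f_zero(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(1, 5, 3, 6))
        y = np.concatenate([half, half], axis=0)
        summaries = summaries_from_array(y, OBJECT_SETS, STIMULUS_PAIRS)
        table = mixed_anova(summaries)
        assert table["condition"].F == pytest.approx(0.0, abs=1e-20)

    def test_incomplete_design_rejected(self, noiseless_cohort):
        summaries = subject_pair_means(noiseless_cohort)
        broken = summaries.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(broken)

    def test_unbalanced_groups_rejected(self, noiseless_cohort):
        summaries = subject_pair_means(noiseless_cohort)
        broken = summaries[summaries["subject"] != "EW01"]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(broken)

    def test_null_rejection_rate_near_alpha(self):
        # no condition effect planted: reject ~5% of the time
        n_reps = 120
        rejections = 0
        for s in range(n_reps):
            cfg = ObserverGenConfig(
                n_per_group=10, compression_beta=1.0,
                prior_line=RatioLine(0.0, 0.0, "density"),
                report_log_noise_sd=0.3, trials_per_cell=1, seed=1000 + s,
            )
            summaries = subject_pair_means(gen_observer_trials(cfg))
            if mixed_anova(summaries)["condition"].p < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_reps)


class TestMixedAnovaOneWithinVsPingouin:
    def test_condition_f_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(21)
        rows = []
        for g, group in enumerate(("EW", "PV")):
            for s in range(8):
                for oset in OBJECT_SETS:
                    rows.append(
                        {"subject": f"{group}{s:02d}", "group": group,
                         "object_set": oset, "pair": "AB",
                         "mean_log_ratio": rng.normal(loc=0.3 * g),
                         "n_trials": 20}
                    )
        df = pd.DataFrame(rows)
        table = mixed_anova_one_within(df)
        pg_res = pg.mixed_anova(
            data=df, dv="mean_log_ratio", within="object_set",
            subject="subject", between="group",
        ).set_index("Source")
        assert table["condition"].F == pytest.approx(
            float(pg_res.loc["group", "F"]), rel=1e-9
        )
        assert table["object_set"].F == pytest.approx(
            float(pg_res.loc["object_set", "F"]), rel=1e-9
        )
        assert table["object_set x condition"].F == pytest.approx(
            float(pg_res.loc["Interaction", "F"]), rel=1e-9
        )


class TestPosthoc:
    def test_identical_groups_all_f_zero(self):
        rng = np.random.default_rng(2)
        half = rng.normal(size=(1, 5, 3, 6))
        y = np.concatenate([half, half], axis=0)
        summaries = summaries_from_array(y, OBJECT_SETS, STIMULUS_PAIRS)
        for pair, table in posthoc_pair_anovas(summaries).items():
            assert table["condition"].F == pytest.approx(0.0, abs=1e-18), pair

    def test_report_layout(self, noisy_cohort):
        report = posthoc_report(subject_pair_means(noisy_cohort))
        assert list(report["pair"]) == list(STIMULUS_PAIRS)
        assert set(report.columns) >= {"pair", "F_condition", "p", "q_bh"}
        assert (report["q_bh"] >= report["p"] - 1e-15).all()


class TestPipelineDirectionality:
    def test_planted_prior_makes_ew_exceed_pv_per_pair(self, noisy_cohort):
        summaries = subject_pair_means(noisy_cohort)
        means = summaries.groupby(["group", "pair"], observed=True)[
            "mean_log_ratio"
        ].mean().unstack("group")
        for pair in STIMULUS_PAIRS:
            assert means.loc[pair, "EW"] > means.loc[pair, "PV"], pair

    def test_effect_vanishes_with_zero_prior(self):
        cfg = ObserverGenConfig(
            n_per_group=10, compression_beta=0.85,
            prior_line=RatioLine(0.0, 0.0, "density"),
            report_log_noise_sd=0.0, trials_per_cell=2, seed=3,
        )
        summaries = subject_pair_means(gen_observer_trials(cfg))
        means = summaries.groupby(["group", "pair"], observed=True)[
            "mean_log_ratio"
        ].mean().unstack("group")
        assert np.allclose(means["EW"], means["PV"], atol=1e-12)

    def test_effect_sizes_positive_under_prior(self, noisy_cohort):
        sizes = pair_effect_sizes(subject_pair_means(noisy_cohort))
        for pair, res in sizes.items():
            assert res.statistic > 0, pair


class TestVolumeErrorTtests:
    def test_underestimation_detected(self, noisy_cohort):
        # beta < 1 compresses: reported small/large log ratio exceeds the
        # true one, so the log error is positive -> t > 0
        summaries = subject_pair_means(noisy_cohort)
        res = volume_error_ttests(summaries, stimulus_volume_ratios(), group="PV")
        for oset in OBJECT_SETS:
            assert res[oset].statistic > 0
            assert res[oset].df == 9

    def test_exact_reports_give_zero_error(self):
        cfg = ObserverGenConfig(
            n_per_group=4, compression_beta=1.0,
            prior_line=RatioLine(0.0, 0.0, "density"),
            report_log_noise_sd=0.1, trials_per_cell=4, seed=6,
        )
        summaries = subject_pair_means(gen_observer_trials(cfg))
        res = volume_error_ttests(summaries, stimulus_volume_ratios(), group="PV")
        # unbiased: |t| should be modest for all sets
        assert all(abs(r.statistic) < 5 for r in res.values())


class TestFitPerceptualLines:
    def test_plant_and_recover_environmental_line(self, noiseless_cohort):
        summaries = subject_pair_means(noiseless_cohort)
        lines = fit_perceptual_lines(summaries, stimulus_volume_ratios(), group="EW")
        for oset, kinds in lines.items():
            assert kinds["weight"].slope == pytest.approx(0.613, abs=1e-9), oset
            assert kinds["weight"].intercept == pytest.approx(0.114, abs=1e-9), oset

    def test_density_line_identity(self, noisy_cohort):
        summaries = subject_pair_means(noisy_cohort)
        lines = fit_perceptual_lines(summaries, stimulus_volume_ratios())
        for kinds in lines.values():
            assert kinds["density"].slope == pytest.approx(
                kinds["weight"].slope - 1.0, abs=1e-12
            )
            assert kinds["density"].intercept == kinds["weight"].intercept

    def test_missing_pair_rejected(self, noisy_cohort):
        summaries = subject_pair_means(noisy_cohort)
        broken = summaries[summaries["pair"] != "CD"]
        with pytest.raises(ValueError, match="missing pairs"):
            fit_perceptual_lines(broken, stimulus_volume_ratios())
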