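import numpy as np
import pandas as pd
import pytest

from dtmr import onesample
from dtmr.onesample import (CollinearityError, CovariateSpec, adjust_multiplicity,
                            bonferroni_threshold, derive_outcomes, factorial_effects,
                            factorial_groups, fit_adjusted, label_strata,
                            mediation_condition, panss_reduction, rescale_per_trait_units,
                            stratified_with_interaction, trend_test, two_stage_ls)


def _cohort(rng, n=500, beta=0.0, confound=0.0):
    """Minimal cohort: score, trait, outcome, a couple of covariates."""
    score = rng.standard_normal(n)
    u = rng.standard_normal(n)
    trait = 10.0 * score + confound * u + 5.0 * rng.standard_normal(n)
    outcome = beta * trait + confound * u + 10.0 * rng.standard_normal(n)
    return pd.DataFrame({
        "score": score, "trait": trait, "outcome": outcome,
        "sex": rng.integers(0, 2, n), "age": rng.uniform(18, 45, n),
    })


class TestPanssReduction:
    def test_total_quoted_formula(self):
        # [DERIVED] 100 * (90 - 60) / (90 - 30) = 50
        assert panss_reduction(90, 60) == pytest.approx(50.0)

    def test_no_change_is_zero(self):
        assert panss_reduction(80, 80) == pytest.approx(0.0)

    def test_subscale_no_offset(self):
        # [DERIVED] 100 * (20 - 10) / 20 = 50
        assert panss_reduction(20, 10, scale="subscale") == pytest.approx(50.0)

    def test_total_baseline_at_floor_errors(self):
        with pytest.raises(ValueError):
            panss_reduction(30, 20)

    def test_improvement_positive(self):
        assert panss_reduction(100, 50) > 0

    def test_responder_ties_at_median_are_non_responders(self):
        df = pd.DataFrame({
            "panss_base_total": [90.0] * 5,
            "panss_end_total": [90 - 0.6 * r for r in (10, 20, 30, 40, 50)],
        })
        out = derive_outcomes(df)
        med = out["reduction_total"].median()
        at_median = out["reduction_total"] == med
        assert (out.loc[at_median, "responder"] == 0).all()
        assert out["responder"].sum() == 2


class TestFitAdjusted:
    def test_unadjusted_matches_closed_form(self, rng):
        df = _cohort(rng, n=200, beta=0.5)
        est = fit_adjusted(df, "outcome", "trait", covariates=None)
        x = df["trait"].to_numpy()
        y = df["outcome"].to_numpy()
        expected = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_ci_from_se(self, rng):
        est = fit_adjusted(_cohort(rng, beta=0.5), "outcome", "trait")
        assert est.ci95 == pytest.approx((est.beta - 1.96 * est.se, est.beta + 1.96 * est.se))

    def test_logistic_or_recovery(self, rng):
        # [DERIVED] parameter recovery: true OR 1.2 per SD, n=5,000, 200 reps
        ors = []
        for _ in range(200):
            n = 5000
            s = rng.standard_normal(n)
            logit = np.log(1.2) * s
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            df = pd.DataFrame({"responder": y, "score": s})
            ors.append(fit_adjusted(df, "responder", "score", family="logistic").odds_ratio)
        assert 1.15 <= np.mean(ors) <= 1.25

    def test_type_one_error_null(self, rng):
        rejections = 0
        reps = 300
        for _ in range(reps):
            df = _cohort(rng, n=150)
            df["outcome"] = rng.standard_normal(len(df))
            if fit_adjusted(df, "outcome", "score", ["sex", "age"]).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_collinear_design_raises(self, rng):
        df = _cohort(rng)
        df["age_copy"] = df["age"]
        with pytest.raises(CollinearityError):
            fit_adjusted(df, "outcome", "trait", ["age", "age_copy"])

    def test_separation_raises(self, rng):
        n = 200
        s = rng.standard_normal(n)
        df = pd.DataFrame({"y": (s > 0).astype(int), "score": s})
        with pytest.raises(onesample.SeparationError):
            fit_adjusted(df, "y", "score", family="logistic")

    def test_covariate_spec_drug_class(self):
        assert "drug_class" in CovariateSpec.default(True).names
        assert "drug_class" not in CovariateSpec.default(False).names

    def test_age2_follows_age(self, rng):
        df = _cohort(rng)
        design = CovariateSpec(names=["age", "age2"], categorical=set()).design(df)
        assert design["age2"].to_numpy() == pytest.approx(df["age"].to_numpy() ** 2)


class TestTrendTest:
    def test_strong_dependence_small_p(self, rng):
        df = _cohort(rng, n=2000)
        df["char"] = 2.0 * df["score"] + rng.standard_normal(2000)
        assert trend_test(df, "char", "score") < 1e-4

    def test_constant_characteristic_errors(self, rng):
        df = _cohort(rng)
        df["char"] = 1.0
        with pytest.raises(ValueError):
            trend_test(df, "char", "score")

    def test_binary_uses_logistic(self, rng):
        df = _cohort(rng, n=1500)
        prob = 1 / (1 + np.exp(-df["score"]))
        df["flag"] = (rng.random(1500) < prob).astype(int)
        assert trend_test(df, "flag", "score") < 1e-4

    def test_categorical_f_test(self, rng):
        df = _cohort(rng, n=900)
        df["center"] = rng.choice(list("ABC"), 900)
        p = trend_test(df, "center", "score")
        assert 0 < p <= 1

    def test_null_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            df = _cohort(rng, n=100)
            df["char"] = rng.standard_normal(100)
            ps.append(trend_test(df, "char", "score"))
        assert 0.35 <= np.mean(ps) <= 0.65


class TestTwoStageLS:
    def test_noiseless_equals_truth(self, rng):
        n = 400
        s = rng.standard_normal(n)
        trait = 3.0 * s
        outcome = 0.7 * trait
        df = pd.DataFrame({"outcome": outcome, "trait": trait, "score": s})
        est = two_stage_ls(df, "outcome", "trait", "score")
        assert est.beta == pytest.approx(0.7, abs=1e-10)

    def test_weak_instrument_warning(self, rng):
        n = 300
        df = pd.DataFrame({
            "score": rng.standard_normal(n),
            "trait": rng.standard_normal(n),
            "outcome": rng.standard_normal(n),
        })
        with pytest.warns(UserWarning, match="weak instrument"):
            two_stage_ls(df, "outcome", "trait", "score")

    def test_confounded_recovery_beats_ols(self, rng):
        # [DERIVED] small-scale version of the recovery oracle (full run in acceptance)
        tsls, ols = [], []
        for _ in range(100):
            df = _cohort(rng, n=800, beta=0.5, confound=8.0)
            tsls.append(two_stage_ls(df, "outcome", "trait", "score").beta)
            ols.append(fit_adjusted(df, "outcome", "trait").beta)
        assert np.mean(tsls) == pytest.approx(0.5, abs=0.05)
        assert abs(np.mean(ols) - 0.5) > 0.1

    def test_first_stage_f_reported(self, rng):
        df = _cohort(rng, n=500, beta=0.3)
        est = two_stage_ls(df, "outcome", "trait", "score")
        assert est.first_stage_f > 10


class TestRescale:
    # [PAPER] printed conversion multipliers
    @pytest.mark.parametrize("beta_st,expected", [(-6.34, 1.58), (-2.02, 4.95), (-0.68, 14.71)])
    def test_printed_multipliers(self, beta_st, expected):
        res = rescale_per_trait_units(1.23, beta_st, unit_step=10.0)
        assert res.multiplier == pytest.approx(expected)

    def test_rescaled_effect(self):
        res = rescale_per_trait_units(1.23, -6.34, 10.0, ci95=(0.30, 2.16))
        assert res.beta == pytest.approx(1.23 * 1.58)
        assert res.ci95[0] == pytest.approx(0.30 * 1.58)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            rescale_per_trait_units(1.0, 0.0)


class TestStratified:
    def test_hyperlipemia_thresholds_inclusive(self):
        df = pd.DataFrame({"TG": [151.0, 150.9, 100.0], "HDL": [50.0, 50.0, 40.0]})
        labels = label_strata(df, "hyperlipemia")
        assert list(labels) == [1, 0, 1]

    def test_glucose_boundary(self):
        df = pd.DataFrame({"glucose": [100.7, 100.8]})
        assert list(label_strata(df, "dysglycemia")) == [0, 1]

    def test_per_stratum_and_interaction(self, rng):
        df = _cohort(rng, n=600, beta=0.2)
        df["stratum"] = rng.integers(0, 2, 600)
        res = stratified_with_interaction(df, "outcome", "score", df["stratum"], ["sex"])
        assert set(res.per_stratum) == {0, 1}
        assert 0 < res.p_interaction <= 1

    def test_low_n_flagged(self, rng):
        df = _cohort(rng, n=200)
        labels = pd.Series([1] * 20 + [0] * 180)
        res = stratified_with_interaction(df, "outcome", "score", labels)
        assert res.per_stratum[1].low_n and not res.per_stratum[0].low_n

    def test_interaction_null_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            df = _cohort(rng, n=200)
            df["outcome"] = df["score"] * 0.5 + rng.standard_normal(200)
            labels = pd.Series(rng.integers(0, 2, 200))
            res = stratified_with_interaction(df, "outcome", "score", labels)
            hits += res.p_interaction < 0.05
        assert 0.015 <= hits / reps <= 0.105


class TestMediation:
    def _mediated(self, rng, n=1500):
        # two shared variants; protein weights (1, 0.5) vs trait weights (2, 2)
        # are deliberately non-proportional so the scores separate
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.3, n).astype(float)
        protein = 1.0 * g1 + 0.5 * g2 + rng.standard_normal(n)
        trait = 2.0 * protein + 1.0 * g2 + rng.standard_normal(n)
        outcome = 0.5 * trait + rng.standard_normal(n)  # fully mediated by trait
        return pd.DataFrame({
            "outcome": outcome,
            "pqtl_score": 1.0 * g1 + 0.5 * g2,
            "trait_score": 2.0 * g1 + 2.0 * g2,
        })

    def test_variant_sets_must_match(self, rng):
        df = self._mediated(rng)
        with pytest.raises(ValueError, match="variant set"):
            mediation_condition(df, "outcome", "pqtl_score", "trait_score",
                                pqtl_variant_ids=["rs1"], trait_variant_ids=["rs2"])

    def test_identical_weights_flag_collinear(self, rng):
        df = self._mediated(rng)
        df["trait_score"] = df["pqtl_score"]
        res = mediation_condition(df, "outcome", "pqtl_score", "trait_score")
        assert res.collinear

    def test_full_mediation_attenuates_pqtl(self, rng):
        # [DERIVED] simulation oracle: protein -> trait -> outcome only
        pqtl_betas, trait_betas, marg_betas = [], [], []
        for _ in range(50):
            df = self._mediated(rng, n=1200)
            res = mediation_condition(df, "outcome", "pqtl_score", "trait_score")
            pqtl_betas.append(res.pqtl_effect.beta)
            trait_betas.append(res.trait_effect.beta)
            marg_betas.append(fit_adjusted(df, "outcome", "pqtl_score").beta)
        # conditioned pqtl coefficient collapses toward 0; trait one stays away
        assert abs(np.mean(pqtl_betas)) < 0.15 * abs(np.mean(marg_betas))
        assert abs(np.mean(trait_betas)) > 0.3

    def test_direct_effect_robust_to_conditioning(self, rng):
        betas = []
        for _ in range(50):
            n = 1200
            g = rng.binomial(2, 0.3, n).astype(float)
            trait_score = rng.standard_normal(n)  # independent pathway
            outcome = 0.8 * g + 0.5 * trait_score + rng.standard_normal(n)
            df = pd.DataFrame({"outcome": outcome, "pqtl_score": g,
                               "trait_score": trait_score})
            betas.append(mediation_condition(df, "outcome", "pqtl_score",
                                             "trait_score").pqtl_effect.beta)
        assert np.mean(betas) == pytest.approx(0.8, abs=0.05)


class TestFactorial:
    def test_four_distinct_groups(self):
        groups = factorial_groups([-1, -1, 1, 1], [-1, 1, -1, 1])
        assert sorted(groups) == [0, 1, 2, 3]

    def test_exact_median_assigned_higher(self):
        # [DERIVED] convention: >= median is "higher"
        groups = factorial_groups([1.0, 2.0, 3.0], [0.0, 0.0, 1.0])
        # median of a is 2 -> values 2,3 higher; median of b is 0 -> all >= 0 higher
        assert list(groups) == [2, 3, 3]

    def test_group_balance_uncorrelated(self, rng):
        # [DERIVED] ~n/4 per group within binomial error at n=2,000
        g = factorial_groups(rng.standard_normal(2000), rng.standard_normal(2000))
        counts = np.bincount(g, minlength=4)
        assert np.all(np.abs(counts - 500) < 100)

    def test_bonferroni_threshold(self):
        # [PAPER] 0.05 / 4 = 0.0125
        assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)

    def test_effects_and_product(self, rng):
        df = _cohort(rng, n=800)
        df["score_b"] = rng.standard_normal(800)
        df["outcome"] = 1.0 * df["score"] + 0.5 * df["score_b"] + rng.standard_normal(800)
        res = factorial_effects(df, "outcome", "score", "score_b", ["sex"])
        assert set(res.group_effects) == {1, 2, 3}
        assert res.threshold == pytest.approx(0.0125)
        assert all(v > 0 for v in res.group_sizes.values())

    def test_additive_truth_both_high_is_sum(self, rng):
        # [DERIVED] additivity oracle over replicates
        gaps = []
        for _ in range(60):
            n = 1000
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            y = 2.0 * a + 1.0 * b + rng.standard_normal(n)
            df = pd.DataFrame({"outcome": y, "a": a, "b": b})
            res = factorial_effects(df, "outcome", "a", "b")
            eff = res.group_effects
            gaps.append(eff[3].beta - (eff[1].beta + eff[2].beta))
        assert abs(np.mean(gaps)) < 0.05

    def test_product_null_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 300
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            y = a + b + rng.standard_normal(n)
            df = pd.DataFrame({"outcome": y, "a": a, "b": b})
            hits += factorial_effects(df, "outcome", "a", "b").p_product_interaction < 0.05
        assert 0.015 <= hits / reps <= 0.105


class TestMultiplicity:
    def test_bh_hand_example(self):
        # [DERIVED] step-up by hand: all adjusted to 0.04
        adj = adjust_multiplicity([0.01, 0.02, 0.03, 0.04], "bh")
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_all_equal(self):
        adj = adjust_multiplicity([0.03, 0.03, 0.03], "bh")
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_definition(self):
        assert adjust_multiplicity([0.02], "bonferroni", m=4)[0] == pytest.approx(0.08)

    def test_bh_matches_bruteforce_oracle(self, rng):
        # [DERIVED] "largest k with p_(k) <= k q / m" rejection-set equivalence
        for _ in range(50):
            p = rng.random(20)
            adj = adjust_multiplicity(p, "bh")
            for q in (0.01, 0.05, 0.1, 0.25):
                srt = np.sort(p)
                ks = np.nonzero(srt <= np.arange(1, 21) * q / 20)[0]
                k_star = ks.max() + 1 if len(ks) else 0
                rejected_brute = set(np.argsort(p)[:k_star])
                rejected_adj = set(np.nonzero(adj <= q)[0])
                assert rejected_adj == rejected_brute

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.random(10))
        adj = adjust_multiplicity(p, "bh")
        assert np.all(np.diff(adj) >= -1e-12)
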