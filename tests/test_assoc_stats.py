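from __future__ import annotations

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hst

from trdpheno import (
    ContingencyTable2x2,
    LiabilityParams,
    PrsModel,
    bonferroni_threshold,
    h2_liability_to_observed,
    h2_observed_to_liability,
    measure_overlap,
    odds_ratio,
    p_from_z,
    prevalence_percent,
    prs_association,
    prs_score,
    r2_observed_to_liability,
    select_best_threshold,
    z_compare_effects,
)

from _oracles import (
    oracle_h2_liability,
    oracle_r2_liability,
    oracle_two_sided_p,
)


class TestPrevalence:
    @pytest.mark.parametrize(
        "n_case,n_total,expected",
        [(1271, 8926, 14.24), (19979, 230096, 8.68), (0, 100, 0.0)],
    )
    def test_printed_precision(self, n_case, n_total, expected):
        assert prevalence_percent(n_case, n_total) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            prevalence_percent(1, 0)


class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        assert odds_ratio(ContingencyTable2x2(10, 10, 10, 10)).oddsratio == pytest.approx(1.0)

    def test_cross_product(self):
        res = odds_ratio(ContingencyTable2x2(20, 10, 10, 20))
        assert res.oddsratio == pytest.approx(4.0)
        assert res.ci_low < 4.0 < res.ci_high

    def test_zero_cell_triggers_flagged_continuity_correction(self):
        res = odds_ratio(ContingencyTable2x2(5, 0, 3, 7))
        assert res.continuity_corrected
        assert math.isfinite(res.oddsratio)

    @settings(max_examples=20, deadline=None)
    @given(
        a=hst.integers(3, 40), b=hst.integers(3, 40),
        c=hst.integers(3, 40), d=hst.integers(3, 40),
    )
    def test_equals_logistic_regression_on_expanded_data(self, a, b, c, d):
        """The 2x2 OR equals exp(beta) from an intercept-plus-exposure
        logistic fit on the unrolled binary records."""
        res = odds_ratio(ContingencyTable2x2(a, b, c, d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1] * (a + b) + [0] * (c + d))
        fit = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=0)
        assert res.oddsratio == pytest.approx(math.exp(fit.params[1]), rel=1e-6)


class TestLiabilityTransforms:
    def test_zero_is_fixed_point(self):
        params = LiabilityParams(0.1, 0.3)
        assert h2_observed_to_liability(0.0, params) == 0.0
        assert r2_observed_to_liability(0.0, params) == 0.0

    def test_matches_numerical_oracle(self):
        params = LiabilityParams(0.023, 0.161)
        assert h2_observed_to_liability(0.1, params) == pytest.approx(
            oracle_h2_liability(0.1, 0.023, 0.161), rel=1e-6
        )
        assert r2_observed_to_liability(0.05, params) == pytest.approx(
            oracle_r2_liability(0.05, 0.023, 0.161), rel=1e-6
        )

    def test_round_trip_identity(self):
        params = LiabilityParams(0.108, 0.25)
        for h2 in (0.01, 0.2459, 0.8):
            back = h2_observed_to_liability(h2_liability_to_observed(h2, params), params)
            assert back == pytest.approx(h2, rel=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        k=hst.floats(0.005, 0.5), p=hst.floats(0.05, 0.95),
        h2a=hst.floats(0.0, 0.5), delta=hst.floats(1e-6, 0.3),
    )
    def test_strictly_increasing_in_observed_h2(self, k, p, h2a, delta):
        params = LiabilityParams(k, p)
        assert h2_observed_to_liability(h2a + delta, params) > h2_observed_to_liability(
            h2a, params
        )

    def test_continuous_in_prevalence(self):
        values = [
            h2_observed_to_liability(0.1, LiabilityParams(k, 0.3))
            for k in np.linspace(0.01, 0.99, 200)
        ]
        steps = np.abs(np.diff(values))
        assert steps.max() < 0.05  # no jumps on a fine prevalence grid

    def test_no_ascertainment_limit_of_r2_transform(self):
        """With P = K the ascertainment term vanishes (theta = 0) and the
        transform reduces to the plain K(1-K)/z^2 rescaling."""
        k = 0.2
        params = LiabilityParams(k, k)
        c = k * (1 - k) / params.density_z**2
        assert r2_observed_to_liability(0.07, params) == pytest.approx(c * 0.07, rel=1e-10)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            LiabilityParams(0.0, 0.3)
        with pytest.raises(ValueError):
            LiabilityParams(0.1, 1.0)

    def test_threshold_and_density_consistent_with_prevalence(self):
        params = LiabilityParams(0.023, 0.161)
        from scipy.stats import norm

        assert norm.sf(params.threshold_t) == pytest.approx(0.023, rel=1e-12)
        assert params.density_z > 0


class TestPlantedVarianceRecovery:
    def test_true_weight_score_recovers_liability_r2(self):
        """Liability-scale R2 of the true-weight polygenic score in a
        liability-threshold simulation recovers the planted h2 within 20%
        relative, and the package transform agrees with the numerical
        oracle."""
        from trdpheno import GeneticConfig, simulate_genotypes, simulate_liability_case_control

        h2, k = 0.3, 0.1
        gc = GeneticConfig(n_snps=500, h2_liability=h2, prevalence_k=k, seed=42)
        rng = np.random.default_rng(42)
        geno = rng.binomial(2, rng.uniform(0.05, 0.5, gc.n_snps), size=(20_000, gc.n_snps))
        sim = simulate_liability_case_control(geno, gc, rng)
        y = sim.case.astype(float)
        r2_obs = np.corrcoef(sim.genetic_value, y)[0, 1] ** 2
        params = LiabilityParams(prevalence_k=k, case_proportion_p=float(y.mean()))
        r2_liab = r2_observed_to_liability(r2_obs, params)
        assert r2_liab == pytest.approx(oracle_r2_liability(r2_obs, k, float(y.mean())), rel=1e-6)
        assert r2_liab == pytest.approx(h2, rel=0.20)


class TestPrsScoring:
    def test_zero_weights_give_zero_scores_with_warning(self):
        model = PrsModel(np.zeros(3), np.array([0.01, 0.2, 0.5]))
        with pytest.warns(UserWarning):
            s = prs_score(np.ones((4, 3)), model, 1.0)
        assert np.all(s == 0)

    def test_dosage_weight_product_and_standardization(self):
        model = PrsModel(np.array([0.5]), np.array([1e-5]))
        s = prs_score(np.array([[2.0], [0.0]]), model, 0.05)
        assert s == pytest.approx([1.0, -1.0])  # raw scores 1.0 and 0.0, standardized

    def test_threshold_excludes_nonsignificant_snps(self):
        model = PrsModel(np.array([1.0, 1.0]), np.array([0.5, 1e-6]))
        geno = np.array([[2.0, 0.0], [0.0, 2.0]])
        s = prs_score(geno, model, 0.05)  # only SNP 2 passes
        assert s == pytest.approx([-1.0, 1.0])

    def test_model_threshold_grid_must_increase(self):
        with pytest.raises(ValueError):
            PrsModel(np.zeros(2), np.ones(2), thresholds=(0.5, 0.5))


class TestPrsAssociation:
    def test_constant_score_is_flagged_degenerate(self):
        y = np.array([0, 1] * 20)
        res = prs_association(y, np.ones(40))
        assert not res.converged and res.warning == "constant score"

    def test_recovers_planted_effect_with_covariate(self):
        rng = np.random.default_rng(0)
        n = 4000
        score = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        logit = -1.0 + 0.5 * score + 0.3 * cov
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = prs_association(y, score, cov)
        assert res.beta == pytest.approx(0.5, abs=3 * res.se)
        assert res.pvalue < 1e-10
        assert 0 < res.nagelkerke_r2 < 1

    def test_null_score_has_null_r2(self):
        rng = np.random.default_rng(1)
        y = rng.random(500) < 0.3
        res = prs_association(y, rng.standard_normal(500))
        assert res.nagelkerke_r2 < 0.02


class TestThresholdSelection:
    def test_single_threshold_is_selected(self):
        model = PrsModel(np.array([0.2, 0.1]), np.array([0.01, 0.2]), thresholds=(0.05,))
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        y = rng.random(200) < 0.3
        best, table = select_best_threshold(y, geno, model)
        assert best == 0.05 and len(table) == 1

    def test_separating_threshold_preferred_for_stratified_pvalues(self):
        """Causal SNPs carry tiny discovery p-values, null SNPs large ones;
        a threshold between the strata should win."""
        rng = np.random.default_rng(3)
        n, n_causal, n_null = 3000, 20, 180
        geno = rng.binomial(2, 0.3, size=(n, n_causal + n_null)).astype(float)
        w = np.concatenate([np.full(n_causal, 0.3), np.zeros(n_null)])
        logit = -1.0 + (geno - geno.mean(0)) @ w
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        pvals = np.concatenate(
            [rng.uniform(1e-8, 1e-5, n_causal), rng.uniform(0.1, 1.0, n_null)]
        )
        model = PrsModel(np.concatenate([np.full(n_causal, 0.3), rng.standard_normal(n_null) * 0.01]), pvals)
        best, _ = select_best_threshold(y, geno, model)
        assert best in (1e-4, 1e-3, 0.01)

    def test_tie_breaks_toward_smaller_threshold(self):
        # identical SNP sets at both thresholds -> identical R2 -> smaller wins
        model = PrsModel(np.array([0.4]), np.array([1e-9]), thresholds=(1e-6, 0.5))
        rng = np.random.default_rng(4)
        geno = rng.binomial(2, 0.4, size=(300, 1)).astype(float)
        y = rng.random(300) < 0.4
        best, _ = select_best_threshold(y, geno, model)
        assert best == 1e-6


class TestTailsAndTests:
    def test_equal_effects_give_null_z(self):
        assert z_compare_effects(0.3, 0.1, 0.3, 0.1) == (0.0, 1.0)

    def test_worked_z_value(self):
        z, p = z_compare_effects(0.3, 0.05, 0.1, 0.05)
        assert z == pytest.approx(2.8284, abs=1e-4)
        assert p == pytest.approx(oracle_two_sided_p(z), rel=1e-9)

    def test_antisymmetry(self):
        z1, p1 = z_compare_effects(0.3, 0.05, 0.1, 0.05)
        z2, p2 = z_compare_effects(0.1, 0.05, 0.3, 0.05)
        assert z1 == -z2 and p1 == p2

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_compare_effects(0.1, 0.0, 0.2, 0.1)

    @pytest.mark.parametrize("z,expected,tol", [(0.0, 1.0, 0), (1.96, 0.05, 1e-3)])
    def test_reference_points(self, z, expected, tol):
        assert p_from_z(z) == pytest.approx(expected, abs=tol)

    def test_extreme_tail_does_not_underflow(self):
        assert 0 < p_from_z(40.0) < 1e-300

    def test_bonferroni(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 88) == pytest.approx(5.6818e-4, rel=1e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_bonferroni_monotone_in_tests(self):
        vals = [bonferroni_threshold(0.05, n) for n in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMeasureOverlap:
    def test_identical_measures(self):
        pct, n = measure_overlap([True, False, True], [True, False, True])
        assert pct == 100.0 and n == 3

    def test_disjoint_measures(self):
        pct, _ = measure_overlap([True, True, False], [False, False, True])
        assert pct == 0.0

    def test_partial_overlap(self):
        a = [True, True, True, True, False]
        b = [True, True, True, False, True]
        pct, _ = measure_overlap(a, b)
        assert pct == 75.0

    def test_no_positives_gives_missing(self):
        pct, _ = measure_overlap([False, False], [True, False])
        assert pct is None

    def test_missing_values_excluded_pairwise(self):
        pct, n = measure_overlap([True, True, np.nan], [True, np.nan, True])
        assert n == 1 and pct == 100.0
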