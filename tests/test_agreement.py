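"""Correlation, regression and Bland-Altman statistics vs textbook oracles."""

import numpy as np
import pytest

from doifusion.agreement import (
    bland_altman,
    linear_fit,
    pearson_with_test,
    proportional_bias_test,
)
from doifusion.synthetic import GeneratorParams, generate_cohort


def pearson_by_definition(x, y):
    """Independent oracle: the raw product-moment definition formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return num / den


def ols_by_normal_equations(x, y):
    """Independent oracle: solve X'Xb = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    return np.linalg.solve(X.T @ X, X.T @ y)  # (intercept, slope)


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        r, p = pearson_with_test(x, x)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0, abs=1e-12)
        r_neg, _ = pearson_with_test(x, -x)
        assert r_neg == pytest.approx(-1.0)

    def test_matches_definition_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r, _ = pearson_with_test(x, y)
        assert abs(r - pearson_by_definition(x, y)) < 1e-12

    def test_constant_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_with_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, rsd = linear_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert rsd == pytest.approx(0.0, abs=1e-12)

    def test_centered_x_gives_mean_intercept(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        x -= x.mean()
        y = rng.normal(size=20)
        _, intercept, _ = linear_fit(x, y)
        assert intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 20, 10)
        y = 1.5 * x - 2 + rng.normal(0, 1, 10)
        slope, intercept, _ = linear_fit(x, y)
        b0, b1 = ols_by_normal_equations(x, y)
        assert abs(slope - b1) < 1e-10 and abs(intercept - b0) < 1e-10

    def test_consistency_with_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 3, 30)
        y = 0.8 * x + rng.normal(0, 2, 30)
        slope, _, _ = linear_fit(x, y)
        r, _ = pearson_with_test(x, y)
        assert slope * np.std(x, ddof=1) / np.std(y, ddof=1) == pytest.approx(r, abs=1e-10)


class TestBlandAltman:
    def test_constant_offset(self):
        ref = np.array([2.0, 5.0, 9.0, 14.0])
        rep = bland_altman(ref + 2.0, ref)
        assert rep.bias == pytest.approx(2.0)
        assert rep.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert rep.loa_low == pytest.approx(2.0) and rep.loa_high == pytest.approx(2.0)
        assert rep.prop_bias_slope == pytest.approx(0.0, abs=1e-12)

    def test_identity(self):
        ref = np.array([2.0, 5.0, 9.0])
        rep = bland_altman(ref, ref)
        assert rep.bias == 0.0 and rep.loa_low == 0.0 and rep.loa_high == 0.0

    def test_loa_geometry_invariant(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(1, 20, 30)
        meas = ref + rng.normal(1, 2, 30)
        rep = bland_altman(meas, ref)
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert rep.loa_high - rep.loa_low == pytest.approx(2 * 1.96 * rep.sd_diff)

    def test_recovers_simulated_us_error_parameters(self):
        n = 20_000
        cohort = generate_cohort(
            GeneratorParams(
                n_patients=n,
                us_bias_deep_slope=0.0,
                us_avail_beta0=50.0,
                us_avail_beta1=0.0,
                seed=5,
            )
        )
        rep = bland_altman(cohort.us_doi_mm, cohort.p_doi_mm)
        assert abs(rep.bias - 0.88) < 3 * 1.59 / np.sqrt(n)

    @pytest.mark.parametrize("c", [-3.0, 4.5])
    def test_translation_invariances(self, c):
        rng = np.random.default_rng(3)
        ref = rng.uniform(2, 18, 25)
        meas = ref + rng.normal(0.9, 1.6, 25)
        base = bland_altman(meas, ref)
        both = bland_altman(meas + c, ref + c)
        assert both.pearson_r == pytest.approx(base.pearson_r, abs=1e-10)
        assert both.sd_diff == pytest.approx(base.sd_diff, abs=1e-10)
        assert both.prop_bias_slope == pytest.approx(base.prop_bias_slope, abs=1e-10)
        assert both.bias == pytest.approx(base.bias, abs=1e-10)
        meas_only = bland_altman(meas + c, ref)
        assert meas_only.bias == pytest.approx(base.bias + c, abs=1e-10)
        assert meas_only.loa_low == pytest.approx(base.loa_low + c, abs=1e-10)
        assert meas_only.loa_high == pytest.approx(base.loa_high + c, abs=1e-10)

    def test_small_fixture_matches_textbook_formulas(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(1, 15, 12)
        meas = ref + rng.normal(1.0, 1.5, 12)
        rep = bland_altman(meas, ref)
        d = meas - ref
        m = (meas + ref) / 2
        assert rep.bias == pytest.approx(d.mean(), abs=1e-10)
        assert rep.sd_diff == pytest.approx(np.sqrt(((d - d.mean()) ** 2).sum() / 11), abs=1e-10)
        assert rep.loa_low == pytest.approx(d.mean() - 1.96 * rep.sd_diff, abs=1e-10)
        assert rep.pearson_r == pytest.approx(pearson_by_definition(ref, meas), abs=1e-10)
        b0, b1 = ols_by_normal_equations(m, d)
        assert rep.prop_bias_slope == pytest.approx(b1, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])
        rep = bland_altman([1.0, 2.0], [1.5, 2.5])  # n=2: no proportional-bias test
        assert rep.prop_bias_slope is None and rep.prop_bias_p is None


class TestProportionalBias:
    def test_constant_offset_has_zero_slope(self):
        ref = np.array([2.0, 6.0, 11.0, 15.0])
        slope, _ = proportional_bias_test(ref + 2.0, ref)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_detects_deep_regime_underestimation(self):
        cohort = generate_cohort(
            GeneratorParams(
                n_patients=5_000,
                us_bias_deep_slope=-0.3,
                us_knot_mm=10.0,
                us_avail_beta0=50.0,
                us_avail_beta1=0.0,
                seed=6,
            )
        )
        slope, p = proportional_bias_test(cohort.us_doi_mm, cohort.p_doi_mm)
        assert slope < 0 and p < 0.01

    def test_null_case_slope_matches_derived_artifact_value(self):
        # With depth-independent error e ~ N(0, sigma), the difference still
        # shares e/2 with the pairwise mean, so the population slope of the
        # difference-on-mean regression is not 0 but sigma^2/2 / var(mean).
        from scipy import stats

        sigma = 1.59
        cohort = generate_cohort(
            GeneratorParams(
                n_patients=5_000,
                us_sd=sigma,
                us_bias_deep_slope=0.0,
                us_avail_beta0=50.0,
                us_avail_beta1=0.0,
                seed=7,
            )
        )
        d = cohort.us_doi_mm - cohort.p_doi_mm
        m = (cohort.us_doi_mm + cohort.p_doi_mm) / 2
        expected = (sigma**2 / 2) / m.var(ddof=1)
        res = stats.linregress(m, d)
        slope, _ = proportional_bias_test(cohort.us_doi_mm, cohort.p_doi_mm)
        assert abs(slope - expected) < 3 * res.stderr
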