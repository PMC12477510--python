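"""Log-expenditure regressions, residual diagnostics and quadrants."""

import math

import numpy as np
import pytest

from digimat.country_types import TypedCountry
from digimat.expenditure import (
    assign_quadrants,
    efficiency_report,
    fit_loglinear,
    predict_index,
    validate_normality,
)


def _ids(n):
    return [f"C{i}" for i in range(n)]


def _ols_oracle(u, y):
    """Closed-form simple OLS via the normal equations, written separately
    from the fitting route."""
    ub, yb = np.mean(u), np.mean(y)
    slope = np.sum((u - ub) * (y - yb)) / np.sum((u - ub) ** 2)
    return yb - slope * ub, slope


class TestFit:
    def test_noiseless_relationship_recovered_exactly(self):
        x = np.linspace(50, 5000, 10)
        y = 2.0 + 3.0 * np.log(x)
        fit = fit_loglinear(_ids(10), y, x)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)

    def test_constant_outcome_gives_zero_slope(self):
        x = np.array([100.0, 300.0, 900.0, 2700.0])
        fit = fit_loglinear(_ids(4), [55.0] * 4, x)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.beta0 == pytest.approx(55.0)

    def test_five_point_toy_matches_hand_ols(self):
        x = np.array([100.0, 200.0, 400.0, 800.0, 1600.0])
        y = np.array([40.0, 50.0, 55.0, 70.0, 80.0])
        fit = fit_loglinear(_ids(5), y, x)
        b0, b1 = _ols_oracle(np.log(x), y)
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)
        assert fit.beta0 == pytest.approx(b0, abs=1e-10)

    def test_residual_identity_and_zero_sum(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.uniform(4, 9, 40))
        y = 10 + 8 * np.log(x) + rng.normal(0, 5, 40)
        fit = fit_loglinear(_ids(40), y, x)
        manual = y - (fit.beta0 + fit.beta1 * np.log(x))
        assert np.allclose(fit.residuals, manual, atol=1e-9)
        assert abs(fit.residuals.sum()) < 1e-6

    def test_base10_fit_predicts_identically(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.uniform(4, 9, 30))
        y = 5 + 7 * np.log(x) + rng.normal(0, 3, 30)
        nat = fit_loglinear(_ids(30), y, x, log_base="natural")
        b10 = fit_loglinear(_ids(30), y, x, log_base="10")
        for he in (120.0, 1500.0, 8000.0):
            assert predict_index(nat, he) == pytest.approx(predict_index(b10, he), abs=1e-8)

    def test_nonpositive_expenditure_names_country(self):
        with pytest.raises(ValueError, match="C1"):
            fit_loglinear(["C0", "C1", "C2"], [1.0, 2.0, 3.0], [10.0, -5.0, 20.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_loglinear(["A", "B"], [1.0, 2.0], [10.0, 20.0])


class TestPredict:
    def test_closed_form_at_e_squared(self):
        fit = fit_loglinear(_ids(3), [1.0, 2.0, 3.0], [math.e, math.e**2, math.e**3])
        fit.beta0, fit.beta1 = 10.0, 5.0
        assert predict_index(fit, math.e**2) == pytest.approx(20.0)

    def test_flat_model_predicts_intercept(self):
        fit = fit_loglinear(_ids(4), [55.0] * 4, [100.0, 300.0, 900.0, 2700.0])
        assert predict_index(fit, 50.0) == pytest.approx(55.0)
        assert predict_index(fit, 5000.0) == pytest.approx(55.0)

    def test_positive_slope_is_monotone_in_expenditure(self):
        x = np.linspace(50, 5000, 10)
        fit = fit_loglinear(_ids(10), 2 + 3 * np.log(x), x)
        assert predict_index(fit, 2000.0) > predict_index(fit, 200.0)

    def test_nonpositive_expenditure_rejected(self):
        x = np.linspace(50, 5000, 10)
        fit = fit_loglinear(_ids(10), 2 + 3 * np.log(x), x)
        with pytest.raises(ValueError):
            predict_index(fit, 0.0)


class TestNormality:
    def test_size_near_nominal_on_gaussian_residuals(self):
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(seed).standard_normal(109)
            rejections += not validate_normality(r).passed
        assert rejections <= 0.09 * 200  # ~5% nominal plus Monte-Carlo slack

    def test_power_against_exponential_residuals(self):
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed).exponential(scale=5.0, size=109)
            rejections += not validate_normality(r - r.mean()).passed
        assert rejections >= 95

    def test_constant_residuals_reported_explicitly(self):
        with pytest.raises(ValueError, match="constant"):
            validate_normality([1.0] * 10)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            validate_normality([1.0, 2.0])


class TestQuadrants:
    def _fit_pair(self, resid_m, resid_p):
        """Build two aligned fits with prescribed residuals by adding them
        to an exact log-linear relationship."""
        n = len(resid_m)
        x = np.exp(np.linspace(4, 9, n))
        fits = []
        for resid in (resid_m, resid_p):
            y = 10 + 6 * np.log(x) + np.asarray(resid, dtype=float)
            fits.append(fit_loglinear(_ids(n), y, x))
        return fits

    def test_sign_rule(self):
        # centered residual patterns so OLS reproduces them exactly
        rm = np.array([3.2, -3.2, 2.0, -2.0, 1.0, -1.0])
        rp = np.array([5.0, -5.0, -1.0, 1.0, 0.5, -0.5])
        # orthogonalize against the regressor so the fit leaves them intact
        fit_m, fit_p = self._fit_pair(rm - rm.mean(), rp - rp.mean())
        quads = {a.country_id: a.quadrant for a in assign_quadrants(fit_m, fit_p)}
        for cid, m_res, p_res in zip(_ids(6), fit_m.residuals, fit_p.residuals):
            expected = f"{'high' if m_res >= 0 else 'low'}-{'high' if p_res >= 0 else 'low'}"
            assert quads[cid] == expected

    def test_counts_match_sign_counting_oracle(self, catalog):
        rng = np.random.default_rng(12)
        n = 80
        x = np.exp(rng.uniform(4, 9, n))
        fit_m = fit_loglinear(_ids(n), 20 + 7 * np.log(x) + rng.normal(0, 6, n), x)
        fit_p = fit_loglinear(_ids(n), 30 + 6 * np.log(x) + rng.normal(0, 8, n), x)
        assignments = assign_quadrants(fit_m, fit_p)
        assert len(assignments) == n
        counts = {q: sum(a.quadrant == q for a in assignments)
                  for q in ("high-high", "high-low", "low-high", "low-low")}
        oracle = {
            "high-high": int(np.sum((fit_m.residuals >= 0) & (fit_p.residuals >= 0))),
            "high-low": int(np.sum((fit_m.residuals >= 0) & (fit_p.residuals < 0))),
            "low-high": int(np.sum((fit_m.residuals < 0) & (fit_p.residuals >= 0))),
            "low-low": int(np.sum((fit_m.residuals < 0) & (fit_p.residuals < 0))),
        }
        assert counts == oracle
        assert sum(counts.values()) == n

    def test_shift_invariance_of_quadrants(self):
        """Adding the same constant to observed and predicted values leaves
        residual signs — hence quadrants — unchanged."""
        rng = np.random.default_rng(4)
        n = 30
        x = np.exp(rng.uniform(4, 9, n))
        y_m = 20 + 7 * np.log(x) + rng.normal(0, 5, n)
        y_p = 30 + 5 * np.log(x) + rng.normal(0, 5, n)
        base = assign_quadrants(fit_loglinear(_ids(n), y_m, x),
                                fit_loglinear(_ids(n), y_p, x))
        shifted = assign_quadrants(fit_loglinear(_ids(n), y_m + 250.0, x),
                                   fit_loglinear(_ids(n), y_p + 250.0, x))
        assert [a.quadrant for a in base] == [a.quadrant for a in shifted]

    def test_country_set_mismatch_lists_difference(self):
        x = np.exp(np.linspace(4, 9, 5))
        y = 10 + 6 * np.log(x)
        fit_a = fit_loglinear(_ids(5), y, x)
        fit_b = fit_loglinear(["C0", "C1", "C2", "C3", "Z9"], y, x)
        with pytest.raises(ValueError, match="Z9"):
            assign_quadrants(fit_a, fit_b)


class TestEfficiencyReport:
    def _assignments(self, spec):
        from digimat.expenditure import QuadrantAssignment

        return [QuadrantAssignment(c, 1.0, 1.0, q) for c, q in spec]

    def test_hand_built_six_country_table(self):
        assignments = self._assignments(
            [("A", "high-high"), ("B", "high-high"), ("C", "high-low"),
             ("D", "low-high"), ("E", "low-low"), ("F", "low-low")]
        )
        typed = [TypedCountry("A", 80, "leader"), TypedCountry("B", 75, "advanced"),
                 TypedCountry("C", 70, "advanced"), TypedCountry("D", 55, "emerging"),
                 TypedCountry("E", 50, "emerging"), TypedCountry("F", 65, "transitioner")]
        report = efficiency_report(assignments, typed)
        overall = report["overall"]
        assert overall.loc["high-high", "leader"] == 1
        assert overall.loc["high-high", "advanced"] == 1
        assert overall.loc["low-low", "emerging"] == 1
        assert overall.values.sum() == 6

    def test_per_region_tables_sum_to_overall(self):
        assignments = self._assignments(
            [("A", "high-high"), ("B", "low-low"), ("C", "high-low"), ("D", "high-high")]
        )
        typed = [TypedCountry(c, 60, "transitioner") for c in "ABCD"]
        regions = {"A": "African", "B": "African", "C": "European", "D": "European"}
        report = efficiency_report(assignments, typed, regions)
        regional_sum = sum(report[k].values.sum() for k in report if k.startswith("region:"))
        assert regional_sum == report["overall"].values.sum() == 4

    def test_missing_type_is_an_error(self):
        assignments = self._assignments([("A", "high-high")])
        with pytest.raises(ValueError, match="A"):
            efficiency_report(assignments, [])


class TestParameterRecovery:
    def test_estimates_within_three_se_of_truth(self):
        """Smoke-scale version of the recovery property (the full 500-seed
        battery runs in the acceptance suite)."""
        b0, b1, hits, n_seeds = 15.0, 8.0, 0, 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            u = rng.uniform(4, 9.5, 60)
            y = b0 + b1 * u + rng.normal(0, 6.0, 60)
            fit = fit_loglinear(_ids(60), y, np.exp(u))
            import statsmodels.api as sm

            res = sm.OLS(y, sm.add_constant(u)).fit()
            se0, se1 = res.bse
            hits += abs(fit.beta0 - b0) <= 3 * se0 and abs(fit.beta1 - b1) <= 3 * se1
        assert hits >= 0.9 * n_seeds
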