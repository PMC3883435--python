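"""Standard-curve fitting and inverse prediction, vs a closed-form OLS oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipcode import (
    CalibrationPoint,
    average_replicates,
    calibrate_from_replicates,
    estimate_concentration,
    fit_standard_curve,
)
from chipcode.errors import DegenerateDesignError, FlatCurveError, InputError


def ols_normal_equations(x, y):
    """Independent closed-form oracle: slope/intercept from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = (x * x).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    m = sxy / sxx
    b = y.mean() - m * x.mean()
    syy = (y * y).sum() - y.sum() ** 2 / n
    r = sxy / math.sqrt(sxx * syy)
    return m, b, r


def pts(cs, ys):
    return [CalibrationPoint(c, y, 0.0, 1) for c, y in zip(cs, ys)]


class TestAverageReplicates:
    def test_three_plates_by_three_assays_gives_n9(self):
        rows = [
            {"concentration_mM": 50.0, "plate": p, "assay": a, "delta": 100.0}
            for p in (1, 2, 3)
            for a in (1, 2, 3)
        ]
        points = average_replicates(pd.DataFrame(rows))
        assert len(points) == 1 and points[0].n == 9

    def test_single_replicate_mean_is_value_sd_zero(self):
        df = pd.DataFrame([{"concentration_mM": 10.0, "delta": 123.0}])
        (p,) = average_replicates(df)
        assert (p.mean_delta, p.sd_delta, p.n) == (123.0, 0.0, 1)

    def test_sample_sd_with_n_minus_1_denominator(self):
        df = pd.DataFrame(
            [{"concentration_mM": 10.0, "delta": d} for d in (10.0, 20.0, 30.0)]
        )
        (p,) = average_replicates(df)
        assert p.mean_delta == 20.0
        assert p.sd_delta == pytest.approx(10.0)

    def test_empty_table_is_input_error(self):
        with pytest.raises(InputError):
            average_replicates(pd.DataFrame(columns=["concentration_mM", "delta"]))


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        curve = fit_standard_curve(pts([10, 25, 50, 100], [500, 1250, 2500, 5000]))
        assert curve.slope == pytest.approx(50.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r == pytest.approx(1.0)

    def test_decreasing_line_gives_r_minus_1(self):
        curve = fit_standard_curve(pts([0, 10, 20], [100, 50, 0]))
        assert curve.r == pytest.approx(-1.0)
        assert curve.slope == pytest.approx(-5.0)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_normal_equation_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        x = np.sort(rng.uniform(0, 100, size=6))
        if len(np.unique(x)) < 2:
            return
        y = rng.uniform(-5000, 5000, size=6)
        curve = fit_standard_curve(pts(x, y))
        m, b, r = ols_normal_equations(x, y)
        assert curve.slope == pytest.approx(m, rel=1e-9)
        assert curve.intercept == pytest.approx(b, rel=1e-9, abs=1e-9)
        assert curve.r == pytest.approx(r, rel=1e-9, abs=1e-12)

    def test_identical_concentrations_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_standard_curve(pts([10, 10, 10], [1, 2, 3]))
        with pytest.raises(DegenerateDesignError):
            fit_standard_curve(pts([10], [1]))

    def test_r_invariant_under_affine_rescaling_of_delta(self):
        rng = np.random.default_rng(5)
        x = np.arange(6, dtype=float)
        y = 30 * x + rng.normal(0, 10, 6)
        r1 = fit_standard_curve(pts(x, y)).r
        r2 = fit_standard_curve(pts(x, 3.5 * y + 1000)).r
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_raw_vs_means_flag(self):
        rows = [
            {"concentration_mM": c, "delta": 50.0 * c + off}
            for c in (10.0, 50.0, 100.0)
            for off in (-30.0, 0.0, 30.0)
        ]
        df = pd.DataFrame(rows)
        on_means = calibrate_from_replicates(df, on_means=True)
        on_raw = calibrate_from_replicates(df, on_means=False)
        # balanced noise: identical line either way, but raw keeps more dof
        assert on_raw.slope == pytest.approx(on_means.slope)
        assert on_means.n == 3
        assert on_raw.residual_se > 0

    def test_summary_mentions_key_quantities(self):
        curve = fit_standard_curve(pts([0, 10], [0, 500]), channel_slot=("DC1", 1, "G"))
        s = curve.summary()
        assert "slope" in s and "Pearson r" in s and "DC1" in s


class TestInversePrediction:
    def curve(self):
        rng = np.random.default_rng(11)
        cs = np.array([10, 25, 50, 62.5, 80, 100], float)
        ys = 50 * cs + rng.normal(0, 30, cs.size)
        return fit_standard_curve(pts(cs, ys))

    def test_inversion_arithmetic(self):
        curve = fit_standard_curve(pts([0, 100], [0, 5000]))
        est = estimate_concentration(curve, 2500.0)
        assert est.c_hat == pytest.approx(50.0)

    def test_delta_equal_intercept_gives_zero(self):
        curve = fit_standard_curve(pts([0, 10, 20], [7.0, 507.0, 1007.0]))
        est = estimate_concentration(curve, 7.0)
        assert est.c_hat == pytest.approx(0.0, abs=1e-9)

    def test_flat_curve_error(self):
        curve = fit_standard_curve(pts([0, 10, 20], [5.0, 5.0, 5.0]))
        with pytest.raises(FlatCurveError):
            estimate_concentration(curve, 5.0)

    def test_round_trip_c_to_delta_to_c(self):
        curve = self.curve()
        for c in (5.0, 37.0, 95.0):
            est = estimate_concentration(curve, curve.predict(c))
            assert est.c_hat == pytest.approx(c, rel=1e-12)
            assert est.interval[0] <= est.c_hat <= est.interval[1]

    def test_interval_widens_away_from_design_center(self):
        curve = self.curve()
        mid = estimate_concentration(curve, curve.predict(55.0))
        far = estimate_concentration(curve, curve.predict(200.0))
        assert (far.interval[1] - far.interval[0]) > (mid.interval[1] - mid.interval[0])

    def test_interval_coverage_near_nominal(self):
        """Propagated 95% interval covers the true concentration ~95% of seeds."""
        m_true, sigma, c_true = 50.0, 100.0, 40.0
        cs = np.array([10, 25, 50, 62.5, 80, 100], float)
        hits = 0
        n_trials = 300
        rng = np.random.default_rng(2024)
        for _ in range(n_trials):
            ys = m_true * cs + rng.normal(0, sigma, cs.size)
            curve = fit_standard_curve(pts(cs, ys))
            obs = m_true * c_true + rng.normal(0, sigma)
            est = estimate_concentration(curve, obs, confidence=0.95)
            hits += est.interval[0] <= c_true <= est.interval[1]
        assert 0.90 <= hits / n_trials <= 0.99

    def test_curve_json_roundtrip(self, tmp_path):
        from chipcode import StandardCurve

        curve = self.curve()
        p = tmp_path / "curve.json"
        curve.save(p)
        again = StandardCurve.load(p)
        assert again.slope == curve.slope
        assert again.points == curve.points
        est1 = estimate_concentration(curve, 2500.0)
        est2 = estimate_concentration(again, 2500.0)
        assert est1 == est2
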