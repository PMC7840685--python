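"""Cubic fits, derivative-ratio statistics, and peak location."""
import numpy as np
import pytest

from fractalarbor import optimization as fo
from fractalarbor.errors import ParameterError


def _records(D, P=None, A_s=None, A_b=None, V_b=None, V_m=None):
    n = len(D)
    P = np.ones(n) if P is None else P
    A_s = np.ones(n) if A_s is None else A_s
    A_b = np.ones(n) if A_b is None else A_b
    V_b = np.ones(n) if V_b is None else V_b
    V_m = np.ones(n) if V_m is None else V_m
    return [
        fo.MorphRecord(f"a{i}", "none", 1.0, D[i], P[i], A_s[i], A_b[i], V_b[i], V_m[i])
        for i in range(n)
    ]


class TestRecords:
    def test_ratio_consistency(self, rng):
        recs = _records(rng.uniform(1, 2, 8), P=rng.uniform(1, 5, 8),
                        A_s=rng.uniform(1, 5, 8), A_b=rng.uniform(1, 5, 8))
        for r in recs:
            assert r.P_over_Ab == pytest.approx(r.P_over_As * r.As_over_Ab, rel=1e-9)

    def test_frame_has_derived_columns(self):
        df = fo.records_frame(_records(np.linspace(1, 2, 6)))
        for col in ("P_over_As", "As_over_Ab", "P_over_Ab", "Vm_over_Vb"):
            assert col in df


class TestBinnedAverage:
    def test_constant_metric_flat(self):
        recs = _records(np.linspace(1.0, 2.0, 30), P=np.full(30, 3.0))
        out = fo.binned_average(recs, "P", n_bins=5)
        assert np.allclose(out["P"].dropna(), 3.0)

    def test_linear_metric_tracks_bin_centers(self):
        D = np.linspace(1.0, 2.0, 400)
        recs = _records(D, P=D.copy())
        out = fo.binned_average(recs, "P", n_bins=10)
        half_width = 0.05
        assert np.all(np.abs(out["P"] - out["D"]) <= half_width + 1e-9)

    def test_single_bin_is_global_mean(self):
        recs = _records(np.linspace(1, 2, 20), P=np.arange(20.0))
        out = fo.binned_average(recs, "P", n_bins=1)
        assert out["P"][0] == pytest.approx(np.mean(np.arange(20.0)))

    def test_empty_bins_flagged_nan(self):
        recs = _records(np.array([1.0, 1.01, 2.0]))
        out = fo.binned_average(recs, "P", n_bins=10)
        assert out["P"].isna().sum() > 0


class TestFitCubic:
    def test_exact_recovery(self):
        coef = np.array([0.5, -1.2, 0.3, 2.0])
        D = np.linspace(1.0, 2.5, 20)
        recs = _records(D, P=np.polyval(coef, D))
        fit = fo.fit_cubic(recs, "P")
        assert np.allclose(fit, coef, atol=1e-9)

    def test_linear_data_gives_null_leading_terms(self):
        D = np.linspace(1.0, 2.0, 30)
        recs = _records(D, P=3.0 * D + 1.0)
        fit = fo.fit_cubic(recs, "P")
        assert abs(fit[0]) < 1e-8 and abs(fit[1]) < 1e-8
        assert fit[2] == pytest.approx(3.0) and fit[3] == pytest.approx(1.0)

    def test_noisy_cubic_rmse_within_ols_bound(self, rng):
        """Coefficient RMSE over Monte-Carlo repeats ≤ 1.5× the analytic
        OLS standard errors (diag of σ²(XᵀX)⁻¹)."""
        coef = np.array([0.2, -0.8, 0.5, 1.0])
        D = np.linspace(1.0, 2.0, 200)
        X = np.vander(D, 4)
        sigma = 0.05
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        errs = []
        for _ in range(100):
            y = X @ coef + rng.normal(0, sigma, len(D))
            recs = _records(D, P=y)
            errs.append(fo.fit_cubic(recs, "P") - coef)
        rmse = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.all(rmse <= 1.5 * se)

    def test_rank_deficiency_rejected(self):
        recs = _records(np.full(6, 1.5))
        with pytest.raises(ParameterError):
            fo.fit_cubic(recs, "P")

    def test_too_few_records_rejected(self):
        with pytest.raises(ParameterError):
            fo.fit_cubic(_records(np.linspace(1, 2, 4)), "P")


def _curves(num_coef, den_pa=None, den_pv=None, D_range=(1.0, 2.0)):
    den_pa = num_coef if den_pa is None else den_pa
    den_pv = num_coef if den_pv is None else den_pv
    return fo.OptimizationCurves(
        coeffs={"P_over_Ab": np.asarray(num_coef, float),
                "As_over_Ab": np.asarray(den_pa, float),
                "Vm_over_Vb": np.asarray(den_pv, float)},
        D_range=D_range,
    )


class TestComputeR:
    def test_identical_cubics_give_unity(self):
        curves = _curves([1.0, -2.0, 0.5, 3.0])
        grid = np.linspace(1.0, 2.0, 50)
        R = fo.compute_R(curves, "R_PA", grid)
        assert np.allclose(R[np.isfinite(R)], 1.0)

    def test_proportional_cubics(self):
        curves = _curves([2.0, 0, 0, 0], den_pa=[1.0, 0, 0, 0])
        R = fo.compute_R(curves, "R_PA", np.linspace(1, 2, 10))
        assert np.allclose(R, 2.0)

    def test_denominator_zeros_masked(self):
        # denominator derivative 2D - 3 vanishes at D = 1.5
        curves = _curves([0, 1.0, 0, 0], den_pa=[0, 1.0, -3.0, 0])
        grid = np.array([1.0, 1.5, 2.0])
        R = fo.compute_R(curves, "R_PA", grid)
        assert np.isnan(R[1]) and np.isfinite(R[0]) and np.isfinite(R[2])

    def test_unknown_ratio_rejected(self):
        with pytest.raises(ParameterError):
            fo.compute_R(_curves([1, 0, 0, 0]), "R_XY", np.linspace(1, 2, 5))


class TestFindPeak:
    def test_parabola_peak_recovered(self):
        grid = np.arange(1.0, 2.0, 0.01)
        R = -((grid - 1.3) ** 2) + 5.0
        pk = fo.find_peak(R, grid)
        assert pk.D_peak == pytest.approx(1.30, abs=0.001)
        assert not pk.no_interior_peak

    def test_monotone_flags_no_interior_peak(self):
        grid = np.arange(1.0, 2.0, 0.01)
        pk = fo.find_peak(grid.copy(), grid)
        assert pk.no_interior_peak and pk.D_peak is None

    def test_analytic_ratio_peak(self):
        """Numerator cubic with num' = -(D-1.4)² + 1, denominator D:
        R = num'/1 peaks exactly at D = 1.4 (closed-form calculus)."""
        c = np.poly1d([-1 / 3, 0, 0, 0])(np.poly1d([1, -1.4])) + np.poly1d([1, 0])
        curves = _curves(c.coefficients, den_pa=[0, 0, 1.0, 0.0])
        grid = np.arange(1.0, 2.0, 0.001)
        R = fo.compute_R(curves, "R_PA", grid)
        pk = fo.find_peak(R, grid)
        assert pk.D_peak == pytest.approx(1.4, abs=0.002)

    def test_extrapolated_peak_flagged(self):
        grid = np.arange(1.0, 2.0, 0.01)
        R = -((grid - 1.3) ** 2)
        pk = fo.find_peak(R, grid, data_range=(1.5, 2.0))
        assert pk.D_peak == pytest.approx(1.3, abs=0.01)
        assert not pk.interior

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fo.find_peak(np.array([1.0, 2.0]), np.array([1.0, 1.1]))
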