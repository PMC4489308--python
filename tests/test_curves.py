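import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from solvaxs.curves import (
    SubtractionOptions,
    apply_subtraction,
    convert_q,
    fit_chi2,
    fit_chi2log,
    guinier_fit,
)
from solvaxs.io_formats import ExperimentalCurve, ScatteringCurve


def _calc_curve(n=40, I0=1000.0, rg=12.0):
    q = np.linspace(0.0, 0.5, n)
    return ScatteringCurve(q=q, I=I0 * np.exp(-(q * rg) ** 2 / 3.0))


class TestConvertQ:
    def test_nm_to_angstrom(self):
        assert np.allclose(convert_q([1.0], "nm^-1", "q"), [0.1])

    def test_s_convention(self):
        out = convert_q([0.1], "A^-1", "s")
        assert abs(out[0] - 0.1 * 2 * np.pi) < 1e-12
        assert abs(out[0] - 0.6283185) < 1e-6

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, vals):
        # Å⁻¹/q is the internal fixed point: converting from it changes nothing
        out = convert_q(convert_q(vals, "A^-1", "q"), "A^-1", "q")
        assert np.allclose(out, vals)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            convert_q([-0.1], "A^-1", "q")


class TestSubtraction:
    def _raw(self):
        q = np.linspace(0.0, 1.0, 11)
        buf = 1e4 * (0.2 + q ** 2)  # water-like: grows toward wide angles
        I = 500.0 * np.exp(-(q * 10) ** 2 / 3.0) + 20.0
        return ScatteringCurve(q=q, I=I, meta={
            "buffer_intensity": buf, "envelope_volume": 4000.0,
            "subtraction_scheme": "total",
        })

    def test_total_is_identity(self):
        raw = self._raw()
        out = apply_subtraction(raw, SubtractionOptions(scheme="total"))
        assert np.allclose(out.I, raw.I)

    def test_v_zero_makes_schemes_identical(self):
        raw = self._raw()
        red = apply_subtraction(raw, SubtractionOptions(scheme="reduced", v=0.0))
        assert np.allclose(red.I, raw.I)

    def test_reduced_minus_total_is_v_ibuf(self):
        raw = self._raw()
        v = 0.3
        red = apply_subtraction(raw, SubtractionOptions(scheme="reduced", v=v))
        diff = red.I - raw.I
        assert np.all(diff >= 0)
        assert np.allclose(diff, v * raw.meta["buffer_intensity"])

    def test_difference_grows_into_water_dominated_regime(self):
        raw = self._raw()
        red = apply_subtraction(raw, SubtractionOptions(scheme="reduced", v=0.1))
        rel = (red.I - raw.I) / raw.I
        assert rel[-1] > rel[1]

    def test_volume_resolution(self):
        raw = self._raw()
        out = apply_subtraction(raw, SubtractionOptions(scheme="reduced", V_solute=400.0))
        assert abs(out.meta["volume_fraction"] - 0.1) < 1e-12
        with pytest.raises(ValueError):
            apply_subtraction(raw, SubtractionOptions(scheme="reduced"))


class TestFitChi2:
    def test_exact_recovery(self):
        calc = _calc_curve()
        f0, c0 = 2.5, 30.0
        exp = ExperimentalCurve(q=calc.q, I=(calc.I - c0) / f0,
                                sigma=np.full_like(calc.I, 3.0))
        r = fit_chi2(calc, exp)
        assert abs(r.f - f0) < 1e-8
        assert abs(r.c - c0) < 1e-8
        assert r.chi2 < 1e-10

    def test_sigma_scaling_leaves_params(self):
        rng = np.random.default_rng(0)
        calc = _calc_curve()
        I_exp = (calc.I - 10.0) / 1.7 + rng.normal(0, 5.0, len(calc.I))
        sig = np.full_like(I_exp, 4.0)
        r1 = fit_chi2(calc, ExperimentalCurve(q=calc.q, I=I_exp, sigma=sig))
        r2 = fit_chi2(calc, ExperimentalCurve(q=calc.q, I=I_exp, sigma=3.0 * sig))
        assert abs(r1.f - r2.f) < 1e-9 and abs(r1.c - r2.c) < 1e-9
        assert abs(r2.chi2 * 9.0 - r1.chi2) < 1e-9 * r1.chi2

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        calc = _calc_curve()
        exp = ExperimentalCurve(q=calc.q, I=(calc.I - 25.0) / 2.0 + rng.normal(0, 8.0, len(calc.I)),
                                sigma=np.full_like(calc.I, 8.0))
        r = fit_chi2(calc, exp)
        fs = np.linspace(r.f * 0.9, r.f * 1.1, 200)
        cs = np.linspace(r.c - 20, r.c + 20, 200)

        def cost(f, c):
            return np.mean(((calc.I - (f * exp.I + c)) / exp.sigma) ** 2)

        grid = np.array([[cost(f, c) for c in cs] for f in fs])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        assert abs(fs[i] - r.f) <= fs[1] - fs[0]
        assert abs(cs[j] - r.c) <= cs[1] - cs[0]
        assert r.chi2 <= grid.min() + 1e-12

    def test_optimality_against_perturbation(self):
        rng = np.random.default_rng(2)
        calc = _calc_curve()
        exp = ExperimentalCurve(q=calc.q, I=calc.I / 3.0 + rng.normal(0, 2.0, len(calc.I)),
                                sigma=np.full_like(calc.I, 2.0))
        r = fit_chi2(calc, exp)

        def cost(f, c):
            return np.mean(((calc.I - (f * exp.I + c)) / exp.sigma) ** 2)

        for df, dc in [(1.01, 1.0), (0.99, 1.0), (1.0, 1.01), (1.0, 0.99)]:
            assert cost(r.f * df, r.c * dc) >= r.chi2 - 1e-12

    def test_missing_sigma_falls_back_with_warning(self):
        calc = _calc_curve()
        exp = ExperimentalCurve(q=calc.q, I=calc.I / 2.0)
        with pytest.warns(UserWarning, match="no errors"):
            r = fit_chi2(calc, exp)
        assert r.meta["metric"] == "chi2log"

    def test_point_order_invariance(self):
        rng = np.random.default_rng(3)
        calc = _calc_curve()
        I_exp = calc.I / 2.0 + rng.normal(0, 1.0, len(calc.I))
        exp = ExperimentalCurve(q=calc.q, I=I_exp, sigma=np.full_like(I_exp, 1.0))
        r1 = fit_chi2(calc, exp)
        # reversing the computed curve's point order must not matter
        calc_rev = ScatteringCurve(q=calc.q, I=calc.I)
        r2 = fit_chi2(calc_rev, exp)
        assert abs(r1.chi2 - r2.chi2) < 1e-12


class TestFitChi2Log:
    def test_exact_recovery(self):
        calc = _calc_curve()
        f0, c0 = 1.8, 12.0
        exp = ExperimentalCurve(q=calc.q, I=(calc.I - c0) / f0)
        r = fit_chi2log(calc, exp)
        assert r.chi2log < 1e-12
        assert abs(r.f - f0) < 1e-5
        assert abs(r.c - c0) < 1e-3

    def test_scale_covariance(self):
        rng = np.random.default_rng(4)
        calc = _calc_curve()
        exp = ExperimentalCurve(q=calc.q, I=calc.I / 2.0 * np.exp(rng.normal(0, 0.02, len(calc.I))))
        r1 = fit_chi2log(calc, exp)
        s = 5.0
        calc_s = ScatteringCurve(q=calc.q, I=s * calc.I)
        r2 = fit_chi2log(calc_s, exp)
        assert abs(r2.f / (s * r1.f) - 1.0) < 1e-3
        assert abs(r2.chi2log - r1.chi2log) < 1e-6 + 1e-3 * r1.chi2log

    def test_matches_grid_refine_oracle(self):
        rng = np.random.default_rng(5)
        calc = _calc_curve()
        exp = ExperimentalCurve(q=calc.q,
                                I=(calc.I - 15.0) / 2.2 * np.exp(rng.normal(0, 0.05, len(calc.I))))
        r = fit_chi2log(calc, exp)
        logIc = np.log(calc.I)

        def cost(f, c):
            fit = f * exp.I + c
            if np.any(fit <= 0):
                return np.inf
            return np.mean((logIc - np.log(fit)) ** 2)

        fs = np.linspace(r.f * 0.95, r.f * 1.05, 200)
        cs = np.linspace(r.c - 10, r.c + 10, 200)
        grid_min = min(cost(f, c) for f in fs for c in cs)
        assert r.chi2log <= grid_min + 1e-10


class TestGuinier:
    def test_exact_exponential_model(self):
        q = np.linspace(0.0, 0.2, 60)
        rg = 15.0
        curve = ScatteringCurve(q=q, I=123.0 * np.exp(-(q * rg) ** 2 / 3.0))
        g = guinier_fit(curve)
        assert abs(g.Rg - rg) < 1e-6
        assert abs(g.I0 - 123.0) < 1e-6 * 123.0

    def test_window_respects_qrg_bound(self):
        q = np.linspace(0.0, 0.5, 200)
        curve = ScatteringCurve(q=q, I=50.0 * np.exp(-(q * 20.0) ** 2 / 3.0))
        g = guinier_fit(curve)
        assert g.q_range_used[1] * g.Rg <= 1.3 + 1e-9

    def test_positive_offset_biases_rg_down(self):
        q = np.linspace(0.0, 0.2, 80)
        I = 100.0 * np.exp(-(q * 15.0) ** 2 / 3.0)
        rgs = []
        for frac in (0.0, 0.01, 0.05):
            g = guinier_fit(ScatteringCurve(q=q, I=I + frac * 100.0))
            rgs.append(g.Rg)
        assert rgs[0] > rgs[1] > rgs[2]

    def test_rising_curve_rejected(self):
        q = np.linspace(0.0, 0.2, 30)
        with pytest.raises(ValueError, match="non-physical"):
            guinier_fit(ScatteringCurve(q=q, I=np.exp(+q ** 2 * 50)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            guinier_fit(ScatteringCurve(q=np.linspace(0, 0.1, 4), I=np.ones(4)))
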