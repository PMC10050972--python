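import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from nirchar.curves import (
    SIGMOID_RANGE_FRACTION,
    SIGMOID_THRESHOLD,
    DegenerateDataError,
    NoTransitionError,
    CurveFit,
    fit_double_line,
    fit_inverse_square,
    fit_linear,
    fit_sigmoid,
    ifd_sigmoid,
    select_family,
)


def inv_sq(d, A=1e6, B=10.0, C=0.0):
    return A / (d - C) ** 2 + B


def sigmoid(d, A=200.0, B=0.05, C=150.0, D=20.0):
    return A / (1.0 + np.exp(B * (d - C))) + D


class TestFitLinear:
    def test_exact_line(self):
        d = np.linspace(0, 10, 20)
        fit = fit_linear(d, 2 * d + 1)
        assert fit.params["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_signal_flags_undefined_r2(self):
        d = np.linspace(200, 400, 30)
        fit = fit_linear(d, np.full(30, 226.0))
        assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(226.0)
        assert np.isnan(fit.r_squared)
        assert "constant_signal" in fit.warnings

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(50, 400, 50)
        I = rng.normal(100, 20, 50)
        fit = fit_linear(d, I)
        # closed-form normal equations
        sxx = np.sum((d - d.mean()) ** 2)
        slope = np.sum((d - d.mean()) * (I - I.mean())) / sxx
        intercept = I.mean() - slope * d.mean()
        assert fit.params["slope"] == pytest.approx(slope, abs=1e-9)
        assert fit.params["intercept"] == pytest.approx(intercept, abs=1e-9)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_linear(np.full(5, 100.0), np.arange(5.0))


class TestFitInverseSquare:
    def test_noiseless_self_consistency(self):
        d = np.linspace(50, 400, 100)
        fit = fit_inverse_square(d, inv_sq(d))
        assert fit.params["A"] == pytest.approx(1e6, rel=1e-6)
        assert fit.params["B"] == pytest.approx(10.0, rel=1e-6)
        assert abs(fit.params["C"]) < 1e-4
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_single_seed(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(60, 400, 500)
        I = inv_sq(d, A=1e6, B=10.0, C=30.0) + rng.normal(0, 2.0, 500)
        fit = fit_inverse_square(d, I)
        assert fit.params["A"] == pytest.approx(1e6, rel=0.1)
        assert fit.params["B"] == pytest.approx(10.0, rel=0.1)
        assert fit.params["C"] == pytest.approx(30.0, rel=0.1)

    def test_pole_constrained_below_data(self):
        d = np.linspace(50, 400, 200)
        fit = fit_inverse_square(d, inv_sq(d))
        assert fit.params["C"] < d.min()

    def test_sigmoid_data_fits_worse_than_sigmoid_model(self):
        d = np.linspace(50, 250, 300)
        I = sigmoid(d)
        inv_fit = fit_inverse_square(d, I)
        sig_fit = fit_sigmoid(d, I)
        assert inv_fit.r_squared < sig_fit.r_squared


class TestFitSigmoid:
    def test_noiseless_recovery_and_midpoint(self):
        d = np.linspace(50, 250, 200)
        fit = fit_sigmoid(d, sigmoid(d))
        assert fit.params["A"] == pytest.approx(200.0, rel=1e-6)
        assert fit.params["B"] == pytest.approx(0.05, rel=1e-6)
        assert fit.params["C"] == pytest.approx(150.0, rel=1e-6)
        assert fit.params["D"] == pytest.approx(20.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        # midpoint identity: value at d = C is D + A/2
        assert float(fit.predict(fit.params["C"])) == pytest.approx(120.0, rel=1e-6)

    def test_orientation_enforced_high_plateau_near(self):
        d = np.linspace(50, 250, 200)
        fit = fit_sigmoid(d, sigmoid(d))
        assert fit.params["B"] > 0
        assert float(fit.predict(50.0)) > float(fit.predict(250.0))

    def test_saturated_frames_excluded(self):
        d = np.linspace(50, 250, 200)
        I = np.clip(sigmoid(d, A=300.0, D=20.0), 0, 255.0)
        fit = fit_sigmoid(d, I, saturation_cap=255.0)
        assert any(w.startswith("saturated_excluded") for w in fit.warnings)
        assert fit.n_points < 200


class TestFitDoubleLine:
    def test_exact_two_line_data(self):
        # y = max(-2x + 300, -0.1x + 110) crosses at x = 100
        d = np.linspace(50, 150, 21)
        I = np.maximum(-2.0 * d + 300.0, -0.1 * d + 110.0)
        fit, res = fit_double_line(d, I)
        assert fit.params["a"] == pytest.approx(-2.0, abs=1e-9)
        assert fit.params["b"] == pytest.approx(300.0, abs=1e-6)
        assert fit.params["c"] == pytest.approx(-0.1, abs=1e-9)
        assert fit.params["d"] == pytest.approx(110.0, abs=1e-6)
        assert res.ifd == pytest.approx(100.0, abs=1e-6)

    def test_single_line_degenerates(self):
        d = np.linspace(50, 150, 30)
        I = -0.5 * d + 200.0
        try:
            fit, res = fit_double_line(d, I)
            assert "single_regime" in fit.warnings
        except NoTransitionError:
            pass  # parallel segments are also acceptable for collinear data

    def test_matches_brute_force_breakpoint_oracle(self):
        rng = np.random.default_rng(3)
        d = np.sort(rng.uniform(50, 400, 120))
        I = inv_sq(d) + rng.normal(0, 2.0, 120)
        _, res = fit_double_line(d, I)

        # independent oracle: exhaustive split, per-segment lstsq lines,
        # max-composite scoring
        best = (np.inf, None)
        for k in range(3, d.size - 2):
            X1 = np.column_stack([d[:k], np.ones(k)])
            X2 = np.column_stack([d[k:], np.ones(d.size - k)])
            (a, b), _, _, _ = np.linalg.lstsq(X1, I[:k], rcond=None)
            (c, dd), _, _, _ = np.linalg.lstsq(X2, I[k:], rcond=None)
            ss = np.sum((I - np.maximum(a * d + b, c * d + dd)) ** 2)
            if ss < best[0]:
                best = (ss, (dd - b) / (a - c))
        assert res.ifd == pytest.approx(best[1], abs=1e-9)

    @given(st.floats(-50, 50), st.integers(0, 2**31 - 1))
    def test_offset_and_order_invariance(self, offset, seed):
        rng = np.random.default_rng(seed)
        d = np.sort(rng.uniform(50, 400, 40))
        I = inv_sq(d) + rng.normal(0, 1.0, 40)
        _, ref = fit_double_line(d, I)
        perm = rng.permutation(40)
        _, out = fit_double_line(d[perm], I[perm] + offset)
        assert out.ifd == pytest.approx(ref.ifd, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_double_line(np.arange(5.0), np.arange(5.0))


class TestIfdSigmoid:
    def test_printed_constant_and_simple_case(self):
        fit = CurveFit(
            family="sigmoid",
            params={"A": 100.0, "B": 1.0, "C": 10.0, "D": 0.0},
            r_squared=1.0, n_points=10,
        )
        res = ifd_sigmoid(fit)
        assert res.ifd == pytest.approx(10.0 - 1.317, abs=1e-3)

    def test_step_function_limit_approaches_center(self):
        fit = CurveFit(
            family="sigmoid",
            params={"A": 100.0, "B": 1e3, "C": 200.0, "D": 0.0},
            r_squared=1.0, n_points=10,
        )
        assert ifd_sigmoid(fit).ifd == pytest.approx(200.0, abs=0.01)

    def test_matches_numeric_third_derivative_root(self):
        A, B, C, D = 200.0, 0.05, 150.0, 20.0
        fit = CurveFit(
            family="sigmoid", params=dict(A=A, B=B, C=C, D=D),
            r_squared=1.0, n_points=10,
        )
        res = ifd_sigmoid(fit)
        assert res.ifd == pytest.approx(150.0 - 26.34, abs=0.01)

        def f(x):
            return A / (1 + np.exp(B * (x - C))) + D

        h = 0.01 / B

        def d3(x):
            return (-f(x - 2 * h) + 2 * f(x - h) - 2 * f(x + h) + f(x + 2 * h)) / (
                2 * h**3
            )

        root = brentq(d3, C - 3 / B, C - 0.1 / B, xtol=1e-10)
        assert res.ifd == pytest.approx(root, abs=0.01)

    def test_transition_and_alternative_are_symmetric_about_center(self):
        fit = CurveFit(
            family="sigmoid",
            params={"A": 70.0, "B": 0.04, "C": 160.0, "D": 4.0},
            r_squared=1.0, n_points=10,
        )
        near = ifd_sigmoid(fit).ifd
        far = ifd_sigmoid(fit, alternative=True).ifd
        assert (near + far) / 2 == pytest.approx(160.0, abs=1e-9)

    def test_value_at_transition_is_79pct_of_range(self):
        fit = CurveFit(
            family="sigmoid",
            params={"A": 200.0, "B": 0.05, "C": 150.0, "D": 20.0},
            r_squared=1.0, n_points=10,
        )
        res = ifd_sigmoid(fit)
        frac = (res.value_at_ifd - 20.0) / 200.0
        assert frac == pytest.approx(SIGMOID_RANGE_FRACTION, abs=1e-9)
        assert round(100 * frac) == 79

    def test_analytic_constant_identities(self):
        assert SIGMOID_THRESHOLD == pytest.approx(np.log(2 + np.sqrt(3)))
        assert round(SIGMOID_THRESHOLD, 4) == 1.3170
        assert SIGMOID_RANGE_FRACTION == pytest.approx((3 + np.sqrt(3)) / 6)


class TestSelectFamily:
    def test_recovers_each_generating_family(self):
        rng = np.random.default_rng(8)
        d = np.sort(rng.uniform(60, 400, 600))
        cases = {
            "inverse_square": inv_sq(d, A=1e6, B=5.0, C=30.0),
            "sigmoid": sigmoid(d, A=100.0, B=0.04, C=220.0, D=5.0),
            "linear": np.full_like(d, 226.0) - 0.01 * d,
        }
        for family, clean in cases.items():
            I = clean + rng.normal(0, 1.5, d.size)
            sel = select_family(d, I)
            assert sel["family"] == family, family

    def test_high_r_squared_on_own_family(self):
        rng = np.random.default_rng(9)
        d = np.sort(rng.uniform(60, 400, 600))
        I = inv_sq(d) + rng.normal(0, 2.0, 600)
        sel = select_family(d, I)
        assert sel["fits"][sel["family"]].r_squared > 0.95
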