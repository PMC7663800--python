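"""Mooney-Rivlin kinematics, stress, fitting, CCC, and crosslink density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pugraft.datamodel import FitError, MooneyRivlinParams
from pugraft.hyperelastic import (
    GAS_CONSTANT,
    concordance_ccc,
    crosslink_density,
    energy,
    fit,
    initial_slope,
    stress_basis,
    uniaxial_state,
    uniaxial_stress,
)

coeff = st.floats(-5, 5, allow_nan=False)
params_st = st.builds(MooneyRivlinParams, c10=coeff, c01=coeff, c11=coeff)
stretch_st = st.floats(0.5, 3.0)


class TestUniaxialState:
    @pytest.mark.parametrize(
        "lam, i1, i2",
        [(1.0, 3.0, 3.0), (2.0, 5.0, 4.25)],
    )
    def test_invariants_hand_values(self, lam, i1, i2):
        st_ = uniaxial_state(lam)
        assert st_.i1 == pytest.approx(i1, abs=1e-12)
        assert st_.i2 == pytest.approx(i2, abs=1e-12)
        assert st_.i3 == pytest.approx(1.0, abs=1e-12)

    @given(stretch_st)
    @settings(derandomize=True)
    def test_incompressibility_holds_everywhere(self, lam):
        st_ = uniaxial_state(lam)
        assert st_.i3 == pytest.approx(1.0, abs=1e-12)
        assert st_.lambda2 == st_.lambda3

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            uniaxial_state(0.0)


class TestEnergyAndStress:
    def test_energy_vanishes_undeformed(self):
        st_ = uniaxial_state(1.0)
        assert energy(st_, MooneyRivlinParams(3.1, -2.2, 0.7)) == 0.0

    @pytest.mark.parametrize(
        "c, expected",
        [((1, 0, 0), 2.0), ((0, 0, 1), 2.5)],
    )
    def test_energy_hand_values_at_stretch_two(self, c, expected):
        # I1-3 = 2, I2-3 = 1.25 at lambda=2
        assert energy(uniaxial_state(2.0), MooneyRivlinParams(*c)) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "c, expected",
        [((1, 0, 0), 7.0), ((0, 1, 0), 3.5), ((0, 0, 1), 15.75)],
    )
    def test_stress_bracket_values_at_stretch_two(self, c, expected):
        assert uniaxial_stress(2.0, MooneyRivlinParams(*c)) == pytest.approx(
            expected, rel=1e-12
        )

    @given(params_st)
    @settings(derandomize=True)
    def test_stress_zero_at_unit_stretch(self, params):
        assert uniaxial_stress(1.0, params) == 0.0

    @given(params_st, stretch_st)
    @settings(derandomize=True, max_examples=100)
    def test_stress_is_lambda_dW_dlambda(self, params, lam):
        """sigma1 equals lambda * dW/dlambda along the incompressible path."""
        h = 1e-6
        w = lambda x: energy(uniaxial_state(x), params)
        dw = (w(lam + h) - w(lam - h)) / (2 * h)
        expected = lam * dw
        got = uniaxial_stress(lam, params)
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)

    @given(params_st, st.floats(0.5, 3.0))
    @settings(derandomize=True, max_examples=100)
    def test_stress_matches_invariant_derivative_form(self, params, lam):
        """sigma1 = 2 (lambda^2 - 1/lambda) (dW/dI1 + dW/dI2 / lambda)."""
        st_ = uniaxial_state(lam)
        dw_di1 = params.c10 + params.c11 * (st_.i2 - 3.0)
        dw_di2 = params.c01 + params.c11 * (st_.i1 - 3.0)
        expected = 2.0 * (lam**2 - 1.0 / lam) * (dw_di1 + dw_di2 / lam)
        assert uniaxial_stress(lam, params) == pytest.approx(
            expected, rel=1e-10, abs=1e-10
        )

    def test_initial_slope_is_analytic_derivative(self):
        params = MooneyRivlinParams(0.7, 1.3, -0.2)
        h = 1e-7
        numeric = (
            uniaxial_stress(1 + h, params) - uniaxial_stress(1 - h, params)
        ) / (2 * h)
        assert initial_slope(params) == pytest.approx(numeric, rel=1e-6)
        assert initial_slope(params) == pytest.approx(6 * (0.7 + 1.3))


class TestFit:
    def test_recovers_reference_coefficients_exactly(self, reference_params):
        lam = np.linspace(1.0, 2.5, 100)
        for label, truth in reference_params.items():
            fr = fit(lam, uniaxial_stress(lam, truth))
            np.testing.assert_allclose(
                fr.params.as_array(), truth.as_array(), rtol=1e-8
            )
            assert fr.rmse < 1e-10
            assert fr.ccc > 1 - 1e-12

    def test_three_point_exact_interpolation(self):
        truth = MooneyRivlinParams(0.4, 0.9, 0.05)
        lam = np.array([1.2, 1.6, 2.0])
        fr = fit(lam, uniaxial_stress(lam, truth))
        assert fr.rmse == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fr.params.as_array(), truth.as_array(), rtol=1e-9)

    def test_fit_idempotence(self):
        lam = np.linspace(1.0, 2.2, 60)
        first = fit(lam, uniaxial_stress(lam, MooneyRivlinParams(-0.8, 1.7, 0.1)))
        second = fit(lam, uniaxial_stress(lam, first.params))
        np.testing.assert_allclose(
            second.params.as_array(), first.params.as_array(), rtol=1e-10
        )

    def test_linearity_scaled_curve_scaled_coefficients(self):
        lam = np.linspace(1.0, 2.5, 80)
        sig = uniaxial_stress(lam, MooneyRivlinParams(0.5, 0.3, 0.02))
        base = fit(lam, sig)
        scaled = fit(lam, 3.0 * sig)
        np.testing.assert_allclose(
            scaled.params.as_array(), 3.0 * base.params.as_array(), rtol=1e-9
        )

    def test_nonlinear_path_agrees_with_linear(self, rng):
        lam = np.linspace(1.0, 2.5, 120)
        sig = uniaxial_stress(lam, MooneyRivlinParams(-1.41, 3.03, 0.223))
        sig = sig + rng.normal(0, 0.02, lam.size)
        lin = fit(lam, sig, method="linear")
        nls = fit(lam, sig, method="nls")
        np.testing.assert_allclose(
            nls.params.as_array(), lin.params.as_array(), rtol=1e-8, atol=1e-10
        )

    def test_unbiased_under_noise(self, reference_params):
        """Monte-Carlo: mean estimates within 3 SE of the truth (linear LS is unbiased)."""
        truth = reference_params["46.3-46.3-7.5"]
        lam = np.linspace(1.0, 2.5, 200)
        clean = uniaxial_stress(lam, truth)
        rng = np.random.default_rng(7)
        n_mc = 300
        est = np.empty((n_mc, 3))
        for i in range(n_mc):
            est[i] = fit(lam, clean + rng.normal(0, 0.02, lam.size)).params.as_array()
        se = est.std(axis=0, ddof=1) / np.sqrt(n_mc)
        assert np.all(np.abs(est.mean(axis=0) - truth.as_array()) < 3 * se)

    def test_rank_deficient_design_rejected(self):
        lam = np.full(10, 1.7)
        with pytest.raises(FitError, match="rank"):
            fit(lam, np.ones(10))

    def test_nan_input_rejected(self):
        lam = np.linspace(1.0, 2.0, 10)
        sig = uniaxial_stress(lam, MooneyRivlinParams(1, 0, 0))
        sig[3] = np.nan
        with pytest.raises(FitError):
            fit(lam, sig)


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([0.3, 1.2, 2.8, 4.0])
        assert concordance_ccc(x, x) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])  # mean zero
        assert concordance_ccc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # brute force: mx=2, my=7/3, sx2=2/3, sy2=14/9, sxy=1, bias=(1/3)^2
        # CCC = 2*1 / (2/3 + 14/9 + 1/9) = 6/7
        assert concordance_ccc([1, 2, 3], [1, 2, 4]) == pytest.approx(6 / 7, rel=1e-12)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=30),
        st.floats(0.1, 3),
        st.floats(-2, 2),
    )
    @settings(derandomize=True, max_examples=100)
    def test_ccc_bounded_by_pearson(self, xs, scale, shift):
        x = np.asarray(xs)
        y = scale * x + shift
        if np.std(x) < 1e-6:
            return
        ccc = concordance_ccc(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(pearson) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance_ccc([1, 2], [1, 2, 3])

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError):
            concordance_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestCrosslinkDensity:
    @pytest.mark.parametrize(
        "c10, expected",
        [(0.589, 0.23), (-1.41, 0.55), (-0.854, 0.33)],
    )
    def test_reference_values_to_two_sig_figs(self, c10, expected):
        v = crosslink_density(MooneyRivlinParams(c10, 0, 0, temperature=310.15))
        assert float(f"{v:.2g}") == pytest.approx(expected)

    def test_zero_c10_gives_zero(self):
        assert crosslink_density(MooneyRivlinParams(0, 1, 1), 300.0) == 0.0

    def test_unit_bookkeeping(self):
        # 1 MPa at 1 K: 1e6 / 8314 kmol/m^3
        v = crosslink_density(MooneyRivlinParams(1.0, 0, 0), 1.0)
        assert v == pytest.approx(1e6 / GAS_CONSTANT, rel=1e-12)


def test_stress_basis_columns_independent():
    lam = np.linspace(1.05, 2.5, 50)
    design = np.column_stack(stress_basis(lam))
    assert np.linalg.matrix_rank(design) == 3
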