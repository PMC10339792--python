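"""Unit and property tests for the nanofiber form factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fibersas import (
    ContrastSet,
    NanofiberGeometry,
    NanofiberModel,
    blob_scattering,
    cross_section_amplitude,
    forward_intensity,
    nanofiber_intensity,
    rect_amplitude,
    rod_factor,
)


class TestRectAmplitude:
    def test_unity_at_zero_q(self):
        assert rect_amplitude(0.0, 0.3, 26.6, 61.1) == pytest.approx(1.0)

    def test_frozen_symbolic_oracle(self):
        # sinc product at (q=0.05, alpha=pi/4, a=26.6, b=61.1) evaluated
        # term by term with 50-digit arithmetic
        val = rect_amplitude(0.05, np.pi / 4, 26.6, 61.1)
        assert val == pytest.approx(0.7868316013214420, rel=1e-12)

    @given(
        q=st.floats(0.0, 1.0),
        alpha=st.floats(0.0, np.pi / 2),
        a=st.floats(1.0, 100.0),
        b=st.floats(1.0, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_axis_swap_symmetry(self, q, alpha, a, b):
        left = rect_amplitude(q, alpha, a, b)
        right = rect_amplitude(q, np.pi / 2 - alpha, b, a)
        assert left == pytest.approx(right, rel=1e-10, abs=1e-12)

    def test_rejects_nonpositive_edges(self):
        with pytest.raises(ValueError):
            rect_amplitude(0.1, 0.1, 0.0, 10.0)
        with pytest.raises(ValueError):
            rect_amplitude(0.1, 0.1, 10.0, -1.0)


class TestRodFactor:
    def test_unity_at_zero_q(self):
        assert rod_factor(0.0, 340.0) == pytest.approx(1.0)

    def test_asymptote_pi_over_qc(self):
        c = 340.0
        for qc in (150.0, 300.0, 1000.0):
            q = qc / c
            assert rod_factor(q, c) == pytest.approx(np.pi / qc, rel=0.01)

    def test_quadrature_oracle(self):
        # orientational average of |sinc(q c cos(theta)/2)|^2 over the
        # sphere, computed by direct numerical integration
        q, c = 0.01, 340.0

        def integrand(theta):
            x = q * c * np.cos(theta) / 2.0
            return np.sinc(x / np.pi) ** 2 * np.sin(theta)

        expected, _ = quad(integrand, 0.0, np.pi / 2, limit=200)
        assert rod_factor(q, c) == pytest.approx(expected, rel=1e-8)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            rod_factor(0.1, 0.0)


class TestCrossSectionAmplitude:
    def _model(self, rho_core, rho_shell, rho_peg, rho_solv, d=0.0):
        geom = NanofiberGeometry(
            a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=2000.0, d=d
        )
        con = ContrastSet(rho_core, rho_shell, rho_peg, rho_solv, radiation="neutron")
        return NanofiberModel(geometry=geom, contrasts=con, phi=0.008)

    def test_zero_peg_layer_reduces_to_core_shell(self):
        q, alpha = 0.07, 0.5
        m0 = self._model(1e10, 3e10, 0.0, 6e10, d=0.0)
        m_junk_peg = self._model(1e10, 3e10, 5e10, 6e10, d=0.0)
        assert cross_section_amplitude(q, alpha, m0) == pytest.approx(
            cross_section_amplitude(q, alpha, m_junk_peg)
        )

    def test_contrast_collapse_is_homogeneous_rectangle(self):
        rho, solv = 4e10, 6e10
        m = self._model(rho, rho, rho, solv, d=12.0)
        g = m.geometry
        for q, alpha in [(0.02, 0.1), (0.15, 0.9), (0.4, 1.3)]:
            expected = (rho - solv) * g.v_tot * rect_amplitude(q, alpha, g.a_tot, g.b_tot)
            assert cross_section_amplitude(q, alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_contrast_matching_gives_zero(self):
        m = self._model(6e10, 6e10, 6e10, 6e10, d=12.0)
        assert cross_section_amplitude(0.1, 0.7, m) == pytest.approx(0.0, abs=1e-20)


class TestBlobScattering:
    def test_forward_limit(self):
        val = blob_scattering(0.0, 15.0, 180.0, 2790.0, 5e10)
        assert val == pytest.approx(180.0 * (5e10 * 2790.0) ** 2)

    def test_zero_contrast_gives_zero(self):
        assert blob_scattering(0.2, 15.0, 180.0, 2790.0, 0.0) == 0.0

    def test_high_q_slope_minus_two(self):
        # Gaussian-chain asymptote: the Beaucage crossover is complete
        # once q rg is well past the Guinier knee (q rg > 3)
        rg = 15.0
        q = np.array([6.0, 12.0]) / rg
        i = blob_scattering(q, rg, 180.0, 2790.0, 5e10)
        slope = np.log(i[1] / i[0]) / np.log(q[1] / q[0])
        assert slope == pytest.approx(-2.0, rel=0.02)


class TestNanofiberIntensity:
    def test_zero_contrast_gives_flat_background(self, table1_geometry, q_grid):
        con = ContrastSet(5e10, 5e10, 5e10, 5e10, radiation="neutron")
        model = NanofiberModel(
            geometry=table1_geometry, contrasts=con, phi=0.008, background=0.07
        )
        np.testing.assert_allclose(nanofiber_intensity(q_grid, model), 0.07, rtol=1e-12)

    def test_forward_limit_closed_form(self, table1_model):
        # quadrature at production settings must hit the closed form to 0.1%
        i0 = nanofiber_intensity(np.array([1e-7]), table1_model)[0]
        assert i0 == pytest.approx(forward_intensity(table1_model), rel=1e-3)

    def test_forward_limit_closed_form_with_peg(self, xray_contrasts):
        geom = NanofiberGeometry(
            a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=900.0, d=30.0
        )
        con = ContrastSet(1e9, 4.06e10, 1.0e10, 6.35e10, radiation="neutron")
        model = NanofiberModel(geometry=geom, contrasts=con, n_agg=180, phi=0.008)
        i0 = nanofiber_intensity(np.array([1e-7]), model)[0]
        assert i0 == pytest.approx(forward_intensity(model), rel=1e-3)

    def test_intensity_never_below_background(self, table1_model, q_grid):
        i = nanofiber_intensity(q_grid, table1_model)
        assert np.all(i >= table1_model.background)

    def test_axis_swap_invariance(self, q_grid, xray_contrasts):
        ga = NanofiberGeometry(a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=340.0)
        gb = NanofiberGeometry(a_core=44.1, a_shell=8.5, b_core=9.8, b_shell=8.4, c=340.0)
        ma = NanofiberModel(geometry=ga, contrasts=xray_contrasts, phi=0.008)
        mb = NanofiberModel(geometry=gb, contrasts=xray_contrasts, phi=0.008)
        np.testing.assert_allclose(
            nanofiber_intensity(q_grid, ma), nanofiber_intensity(q_grid, mb), rtol=1e-6
        )

    def test_doubling_length_doubles_forward_intensity(self, xray_contrasts):
        kw = dict(a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5)
        m1 = NanofiberModel(
            geometry=NanofiberGeometry(c=340.0, **kw), contrasts=xray_contrasts, phi=0.008
        )
        m2 = NanofiberModel(
            geometry=NanofiberGeometry(c=680.0, **kw), contrasts=xray_contrasts, phi=0.008
        )
        assert forward_intensity(m2) == pytest.approx(2.0 * forward_intensity(m1))
        i1 = nanofiber_intensity(np.array([1e-7]), m1)[0]
        i2 = nanofiber_intensity(np.array([1e-7]), m2)[0]
        assert i2 == pytest.approx(2.0 * i1, rel=1e-3)

    def test_curve_anatomy_knee_minmax_rod(self, table1_model):
        """The published geometry produces the characteristic curve: a
        cross-section Guinier knee, a pronounced minimum/maximum pair
        near Q ~ 0.2 1/A, and a low-Q rod regime steeper than the knee."""
        q = np.logspace(np.log10(0.004), np.log10(0.7), 400)
        i = nanofiber_intensity(q, table1_model)
        logq, logi = np.log(q), np.log(i)
        # local slope
        slope = np.gradient(logi, logq)
        # rod regime: slope close to -1 above the finite-length rollover
        rod = (q > 0.01) & (q < 0.02)
        assert np.median(slope[rod]) == pytest.approx(-1.0, abs=0.25)
        # below the rod regime the curve rolls over toward flat
        flat = (q > 0.004) & (q < 0.006)
        assert np.median(slope[flat]) > -0.4
        # a minimum then a maximum in 0.1 < Q < 0.35
        win = (q > 0.1) & (q < 0.35)
        iw, qw = i[win], q[win]
        k_min = np.argmin(iw)
        assert 0 < k_min < len(iw) - 1
        k_max = k_min + np.argmax(iw[k_min:])
        assert k_max > k_min
        assert iw[k_max] / iw[k_min] > 1.5  # pronounced, not numerical ripple
        assert 0.1 < qw[k_min] < 0.35

    def test_rejects_empty_and_negative_grids(self, table1_model):
        with pytest.raises(ValueError):
            nanofiber_intensity(np.array([]), table1_model)
        with pytest.raises(ValueError):
            nanofiber_intensity(np.array([-0.1, 0.1]), table1_model)


def full_orientation_intensity(q_grid, model, n_theta=400, n_phi=400):
    """Brute-force orientational average of the nested parallelepipeds
    over the full sphere (octant by symmetry) -- the independent oracle
    for the decoupling approximation."""
    g, con = model.geometry, model.contrasts
    xt, wt = np.polynomial.legendre.leggauss(n_theta)
    xp, wp = np.polynomial.legendre.leggauss(n_phi)
    theta = np.pi / 4 * (xt + 1.0)
    phi = np.pi / 4 * (xp + 1.0)
    wt = np.pi / 4 * wt
    wp = np.pi / 4 * wp
    st_, ct = np.sin(theta), np.cos(theta)
    cp, sp = np.cos(phi), np.sin(phi)

    def box_amp(q, a, b, c):
        # q: (nq,1,1); angles broadcast
        ux = st_[None, :, None] * cp[None, None, :]
        uy = st_[None, :, None] * sp[None, None, :]
        uz = ct[None, :, None]
        return (
            np.sinc(q * a * ux / (2 * np.pi))
            * np.sinc(q * b * uy / (2 * np.pi))
            * np.sinc(q * c * uz / (2 * np.pi))
        )

    q = np.asarray(q_grid, float)[:, None, None]
    amp = con.drho_core * g.v_core * box_amp(q, g.a_core, g.b_core, g.c)
    amp += con.drho_shell * (
        g.v_pep * box_amp(q, g.a_pep, g.b_pep, g.c)
        - g.v_core * box_amp(q, g.a_core, g.b_core, g.c)
    )
    if g.d > 0:
        amp += con.drho_peg * (
            g.v_tot * box_amp(q, g.a_tot, g.b_tot, g.c)
            - g.v_pep * box_amp(q, g.a_pep, g.b_pep, g.c)
        )
    weight = st_[None, :, None] * wt[None, :, None] * wp[None, None, :]
    avg = (amp**2 * weight).sum(axis=(1, 2)) * (2.0 / np.pi)
    return model.phi / g.v_tot * 1e-24 * avg + model.background


class TestDecouplingOracle:
    def test_matches_full_orientation_average(self, xray_contrasts):
        """At the decoupling-regime boundary (c = 10 x the larger
        cross-section edge) the factorized intensity must agree with the
        brute-force full-sphere parallelepiped average within 5%
        pointwise wherever q c > 10, including the form-factor minima."""
        geom = NanofiberGeometry(
            a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=10 * 61.1
        )
        model = NanofiberModel(geometry=geom, contrasts=xray_contrasts, phi=0.008)
        q = np.logspace(np.log10(11.0 / geom.c), np.log10(0.45), 25)
        assert np.all(q * geom.c > 10)
        oracle = full_orientation_intensity(q, model, n_theta=500, n_phi=500)
        decoupled = nanofiber_intensity(q, model)
        np.testing.assert_allclose(decoupled, oracle, rtol=0.05)

    def test_error_shrinks_with_length(self, xray_contrasts):
        """The decoupling error is a finite-length effect: halving the
        aspect ratio roughly quadruples the worst-case deviation."""
        errs = []
        for c in (5 * 61.1, 10 * 61.1):
            geom = NanofiberGeometry(
                a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=c
            )
            model = NanofiberModel(geometry=geom, contrasts=xray_contrasts, phi=0.008)
            q = np.logspace(np.log10(11.0 / geom.c), np.log10(0.45), 15)
            oracle = full_orientation_intensity(q, model, n_theta=400, n_phi=400)
            errs.append(np.max(np.abs(nanofiber_intensity(q, model) / oracle - 1.0)))
        assert errs[1] < errs[0]


class TestGeometryInvariants:
    def test_nested_dimensions_increase(self):
        g = NanofiberGeometry(a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=900.0, d=30.0)
        assert g.a_core < g.a_pep < g.a_tot
        assert g.b_core < g.b_pep < g.b_tot

    def test_decoupling_warning_flagged(self):
        with pytest.warns(UserWarning, match="decoupling"):
            NanofiberGeometry(a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=340.0)

    def test_rejects_c_below_cross_section(self):
        with pytest.raises(ValueError):
            NanofiberGeometry(a_core=9.8, a_shell=8.4, b_core=44.1, b_shell=8.5, c=50.0)

    def test_rejects_negative_lengths(self):
        with pytest.raises(ValueError):
            NanofiberGeometry(a_core=-1.0, a_shell=8.4, b_core=44.1, b_shell=8.5, c=340.0)
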