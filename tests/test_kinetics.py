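"""Kinetic models: impulse responses, residue functions, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoflow.curves import DynamicCurve
from myoflow.kinetics import (DPParams, FermiParams, KineticsError,
                              derive_microvascular, dp_residue_analytic,
                              dp_residue_laplace, dp_residue_time, fermi_irf,
                              fit_model, model_tissue_curve)


# ---------------------------------------------------------------------------
# Fermi impulse response
# ---------------------------------------------------------------------------

class TestFermi:
    def test_closed_form_mbf(self):
        # A=2, k=0.5/s, tau0=4 s -> MBF = 2 / (1 + e^-2)
        p = FermiParams(amplitude=2.0, k=0.5, tau0=4.0)
        assert p.mbf == pytest.approx(2.0 / (1.0 + math.exp(-2.0)), rel=1e-12)

    def test_limits(self):
        p = FermiParams(amplitude=2.0, k=0.5, tau0=4.0)
        t = np.array([0.0, 1e4])
        h = fermi_irf(t, p)
        assert h[-1] == pytest.approx(0.0, abs=1e-12)          # t -> inf
        big = FermiParams(amplitude=2.0, k=50.0, tau0=50.0)
        assert big.mbf == pytest.approx(2.0, rel=1e-12)         # k*tau0 -> inf

    def test_zero_before_delay_and_nonincreasing(self):
        p = FermiParams(amplitude=1.5, k=0.3, tau0=5.0, tau_d=4.0)
        t = np.linspace(0, 60, 301)
        h = fermi_irf(t, p)
        assert np.all(h[t < 4.0] == 0)
        after = h[t >= 4.0]
        assert np.all(np.diff(after) <= 1e-12)

    def test_rejects_negative_parameters(self):
        with pytest.raises(KineticsError):
            FermiParams(amplitude=-1.0, k=0.5, tau0=4.0)


# ---------------------------------------------------------------------------
# DP residue function
# ---------------------------------------------------------------------------

class TestDPResidue:
    def test_plug_flow_laplace_form(self):
        """PS=0 reduces to the plug-flow transform (1 - e^{-Tc s})/s."""
        p = DPParams(flow=1.0, v_p=0.1, v_e=0.3, ps=0.0)
        tc = p.transit_time
        s = np.array([0.05 + 0.1j, 1.0 + 0j, 2.0 - 0.5j])
        expected = (1.0 - np.exp(-tc * s)) / s
        assert np.allclose(dp_residue_laplace(s, p), expected, rtol=1e-12)

    def test_low_frequency_limit_is_vd_over_f(self):
        """s -> 0 of the transform gives the distribution volume over flow."""
        p = DPParams(flow=1.0, v_p=0.1, v_e=0.3, ps=1.0)
        val = dp_residue_laplace(np.array([1e-6 + 0j]), p)[0]
        assert val.real == pytest.approx((p.v_p + p.v_e) / (p.flow / 60.0), rel=1e-4)

    def test_transport_operator_bounded(self):
        """|h̃(s)| <= 1 on the positive real axis for any valid parameters."""
        for p in [DPParams(1.0, 0.1, 0.3, 1.0), DPParams(3.0, 0.05, 0.1, 2.0),
                  DPParams(0.5, 0.2, 0.0, 0.0)]:
            s = np.linspace(0.01, 20, 50).astype(complex)
            h = 1.0 - s * dp_residue_laplace(s, p)
            assert np.all(np.abs(h) <= 1.0 + 1e-12)

    def test_plug_flow_step(self):
        # Tc = v_p/(F/60) = 6 s: residue is 1 before, 0 after.
        p = DPParams(flow=1.0, v_p=0.1, v_e=0.3, ps=0.0)
        r = dp_residue_time(np.array([3.0, 7.0]), p)
        assert r[0] == pytest.approx(1.0, abs=1e-3)
        assert r[1] == pytest.approx(0.0, abs=1e-3)

    def test_starts_at_one_bounded_nonincreasing(self):
        p = DPParams(flow=1.5, v_p=0.08, v_e=0.25, ps=1.0)
        t = np.arange(0, 50.0, 0.5)
        r = dp_residue_time(t, p)
        assert r[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all((r >= 0) & (r <= 1))
        assert np.all(np.diff(r) <= 1e-3)

    def test_area_equals_vd_over_f(self):
        """∫R dt = v_d/F: 0.4 mL/mL over 1 mL/min/mL = 24 s, within 1 %."""
        p = DPParams(flow=1.0, v_p=0.1, v_e=0.3, ps=1.0)
        t = np.arange(0, 600.0, 0.1)
        area = np.trapezoid(dp_residue_time(t, p), t)
        assert area == pytest.approx(24.0, rel=0.01)

    def test_analytic_and_laplace_routes_agree(self):
        """Closed Bessel form and numerical inversion agree off the jump."""
        p = DPParams(flow=1.2, v_p=0.09, v_e=0.28, ps=0.9)
        t = np.arange(0.0, 60.0, 0.25)
        mask = np.abs(t - p.transit_time) > 0.5
        diff = np.abs(dp_residue_analytic(t, p) - dp_residue_time(t, p))
        assert diff[mask].max() < 1e-3

    def test_rejects_barrier_without_interstitium(self):
        with pytest.raises(KineticsError):
            DPParams(flow=1.0, v_p=0.1, v_e=0.0, ps=1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        flow=st.floats(0.3, 5.0),
        v_p=st.floats(0.01, 0.25),
        v_e=st.floats(0.0, 0.5),
        ps=st.floats(0.0, 3.0),
    )
    def test_residue_always_a_survival_function(self, flow, v_p, v_e, ps):
        """R(t) lies in [0,1] and never increases, for any valid model."""
        if v_e == 0.0:
            ps = 0.0
        p = DPParams(flow=flow, v_p=v_p, v_e=v_e, ps=ps)
        t = np.arange(0, 80.0, 0.5)
        r = dp_residue_analytic(t, p)
        assert np.all((r >= 0) & (r <= 1 + 1e-12))
        assert np.all(np.diff(r) <= 1e-9)


class TestMicrovascular:
    def test_derived_quantities(self):
        p = DPParams(flow=1.0, v_p=0.05, v_e=0.20, ps=0.0)
        m = derive_microvascular(p)
        assert m.extraction_fraction == 0.0
        assert m.v_d == pytest.approx(0.25)
        assert m.transit_time == pytest.approx(3.0)  # 0.05/(1/60)
        p2 = DPParams(flow=1.0, v_p=0.05, v_e=0.20, ps=1.0)
        assert derive_microvascular(p2).extraction_fraction == \
            pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

class TestForwardModel:
    def test_dirac_aif_returns_impulse_response(self):
        dt = 0.5
        t = np.arange(0, 40, dt)
        vals = np.zeros_like(t)
        vals[0] = 1.0 / dt  # discrete Dirac of unit area
        aif = DynamicCurve(times=t, values=vals, kind="concentration", role="aif")
        p = DPParams(flow=1.5, v_p=0.08, v_e=0.25, ps=1.0)
        out = model_tissue_curve(aif, "dp", p)
        expected = (p.flow / 60.0) * dp_residue_analytic(t, p)
        # away from the transit-time cell (where the sampled impulse
        # response carries the cell-averaged spike), samples match R(t)
        mask = np.abs(t - p.transit_time) > dt
        assert np.allclose(out.values[mask], expected[mask], atol=1e-12)

    def test_linearity_in_aif(self, aif_curve):
        p = FermiParams(amplitude=2.0, k=0.5, tau0=4.0)
        one = model_tissue_curve(aif_curve, "fermi", p)
        double = model_tissue_curve(aif_curve.with_values(2 * aif_curve.values),
                                    "fermi", p)
        assert np.allclose(double.values, 2 * one.values, rtol=1e-12)

    def test_boxcar_aif_plug_flow_matches_analytic_ramp(self):
        """Rect ⊛ step has the piecewise-linear overlap solution."""
        dt = 0.1
        t = np.arange(0, 40, dt)
        width = 8.0
        c0 = 2.0
        aif = DynamicCurve(times=t, values=np.where(t < width, c0, 0.0),
                           kind="concentration", role="aif")
        p = DPParams(flow=1.0, v_p=0.1, v_e=0.3, ps=0.0)  # Tc = 6 s
        out = model_tissue_curve(aif, "dp", p)
        tc = p.transit_time
        f_s = p.flow / 60.0
        # overlap of [t - width, t] with [0, Tc]
        overlap = np.clip(np.minimum(t, tc) - np.maximum(t - width, 0.0), 0.0, None)
        expected = f_s * c0 * overlap
        scale = expected.max()
        assert np.max(np.abs(out.values - expected)) < 0.01 * scale + f_s * c0 * dt

    def test_requires_uniform_grid(self):
        t = np.array([0.0, 1.0, 3.0])
        aif = DynamicCurve(times=t, values=np.ones(3), kind="concentration",
                           role="aif")
        with pytest.raises(Exception):
            model_tissue_curve(aif, "fermi", FermiParams(1.0, 0.5, 4.0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFitModel:
    def test_noiseless_fermi_recovery(self, aif_curve):
        truth = FermiParams(amplitude=2.0, k=0.5, tau0=4.0)
        tissue = model_tissue_curve(aif_curve, "fermi", truth, delay=1.0)
        fit = fit_model(aif_curve, tissue, "fermi")
        assert fit.delay == pytest.approx(1.0)
        assert fit.mbf == pytest.approx(truth.mbf, rel=0.01)

    def test_noiseless_dp_recovery_with_delay(self, aif_curve):
        truth = DPParams(flow=1.5, v_p=0.08, v_e=0.25, ps=1.0)
        tissue = model_tissue_curve(aif_curve, "dp", truth, delay=2.0)
        fit = fit_model(aif_curve, tissue, "dp")
        assert fit.delay == pytest.approx(2.0)
        assert fit.params.flow == pytest.approx(1.5, rel=0.02)

    def test_returned_chi2_is_minimum_over_trace(self, aif_curve, rng):
        truth = DPParams(flow=1.8, v_p=0.08, v_e=0.25, ps=1.0)
        tissue = model_tissue_curve(aif_curve, "dp", truth, delay=1.0)
        noisy = tissue.with_values(tissue.values + rng.normal(0, 0.03, tissue.n))
        fit = fit_model(aif_curve, noisy, "fermi")
        converged = [e["chi2"] for e in fit.trace if e["status"] > 0]
        assert fit.chi2 == pytest.approx(min(converged), rel=1e-9)

    def test_flat_tissue_is_degenerate_at_lower_flow_bound(self, aif_curve):
        flat = DynamicCurve(times=aif_curve.times,
                            values=np.zeros(aif_curve.n),
                            kind="concentration", role="tissue")
        fit = fit_model(aif_curve, flat, "dp")
        assert fit.degenerate
        assert fit.params.flow == pytest.approx(0.01)

    def test_rejects_mismatched_grids(self, aif_curve):
        other = DynamicCurve(times=aif_curve.times[:-1] + 0.5,
                             values=aif_curve.values[:-1],
                             kind="concentration", role="tissue")
        with pytest.raises(KineticsError):
            fit_model(aif_curve, other, "fermi")
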