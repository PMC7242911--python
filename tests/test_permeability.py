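"""Stopped-flow, quench and accumulation kinetics and the Pf/Pu conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquakin.permeability import (
    LiposomeGeometry,
    QuenchTrace,
    StopFlowTrace,
    VolumeCalibration,
    accumulation_halftime,
    channel_density,
    fit_double_exponential,
    fit_quench,
    injection_concentration,
    osmotic_permeability,
    single_channel_permeability,
    to_volume,
)
from aquakin.simulate import StopFlowDesign, gen_quench_trace, gen_stopflow_trace


class TestDoubleExponential:
    def test_noiseless_round_trip(self):
        trace = gen_stopflow_trace(StopFlowDesign(k_fast=63.7, k_slow=5.0), seed=1)
        fit = fit_double_exponential(trace)
        assert fit.k_fast == pytest.approx(63.7, rel=1e-4)
        assert fit.k_slow == pytest.approx(5.0, rel=1e-4)
        assert fit.k_selected == fit.k_fast

    def test_single_exponential_fallback(self):
        t = np.arange(0, 2, 0.002)
        y = 1.0 + 0.8 * (1 - np.exp(-10.0 * t))
        fit = fit_double_exponential(StopFlowTrace(t, y))
        assert fit.single_exponential
        assert fit.k_selected == pytest.approx(10.0, rel=1e-3)

    def test_median_bias_under_noise(self):
        # 1% noise relative to the 1.0 total amplitude, many seeds
        ks = []
        for s in range(40):
            trace = gen_stopflow_trace(
                StopFlowDesign(noise_sd=0.01), seed=2000 + s
            )
            ks.append(fit_double_exponential(trace).k_fast)
        assert abs(np.median(ks) - 63.7) / 63.7 < 0.02

    def test_falling_trace_fitted_with_signed_amplitude(self):
        t = np.arange(0, 2, 0.002)
        y = 2.0 - 0.6 * (1 - np.exp(-30.0 * t)) - 0.2 * (1 - np.exp(-3.0 * t))
        fit = fit_double_exponential(StopFlowTrace(t, y))
        assert fit.k_fast == pytest.approx(30.0, rel=1e-3)
        assert fit.a_fast == pytest.approx(-0.6, rel=1e-3)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_double_exponential(
                StopFlowTrace(np.linspace(0, 1, 10), np.ones(10))
            )


class TestPermeabilityConversions:
    def test_zero_rate_gives_zero_pf(self):
        assert osmotic_permeability(0.0) == 0.0

    def test_default_geometry_denominator(self):
        # S/V0 = 3 / 50e-7 cm = 6e5 cm^-1; denominator 6e5 * 18 * 1e-4 = 1080
        assert osmotic_permeability(1.08) == pytest.approx(1.0e-3)

    def test_inversion_to_printed_pf(self):
        assert osmotic_permeability(63.7) == pytest.approx(5.9e-2, rel=0.01)

    @given(
        k=st.floats(0, 1e3),
        radius=st.floats(1e-7, 1e-4),
        c_out=st.floats(1e-6, 1e-2),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_k_inverse_in_geometry(self, k, radius, c_out):
        geom = LiposomeGeometry(radius=radius, c_out=c_out)
        pf = osmotic_permeability(k, geom)
        assert osmotic_permeability(2 * k, geom) == pytest.approx(2 * pf)
        half_r = LiposomeGeometry(radius=radius / 2, c_out=c_out)
        assert osmotic_permeability(k, half_r) == pytest.approx(pf / 2, rel=1e-9)

    def test_molar_lpr_channel_density(self):
        # 200 lipids/channel * 0.47 nm^2 / 2 leaflets = 47 nm^2/channel
        geom = LiposomeGeometry(lpr_basis="molar")
        assert channel_density(geom) == pytest.approx(1 / 47e-14, rel=1e-9)
        assert channel_density(geom) == pytest.approx(2.13e12, rel=0.01)

    def test_doubling_lpr_halves_density(self):
        g1 = LiposomeGeometry(lpr_basis="molar", lpr=200)
        g2 = LiposomeGeometry(lpr_basis="molar", lpr=400)
        assert channel_density(g2) == pytest.approx(channel_density(g1) / 2)

    def test_single_leaflet_doubles_area_per_channel(self):
        g2 = LiposomeGeometry(lpr_basis="molar", leaflets=2)
        g1 = LiposomeGeometry(lpr_basis="molar", leaflets=1)
        assert channel_density(g1) == pytest.approx(channel_density(g2) / 2)

    def test_mass_basis_requires_molecular_weights(self):
        with pytest.raises(ValueError, match="mass"):
            channel_density(LiposomeGeometry(lpr_basis="mass"))

    def test_mass_vs_molar_consistency(self):
        # equal MWs make the two bases coincide
        g_mass = LiposomeGeometry(lpr_basis="mass")
        g_molar = LiposomeGeometry(lpr_basis="molar")
        assert channel_density(g_mass, protein_mw=700.0, lipid_mw=700.0) == \
            pytest.approx(channel_density(g_molar))

    def test_pu_proportionality(self):
        su_d = 2.0e12
        res = single_channel_permeability(su_d * 1e-13, su_d,
                                          subtract_background=False)
        assert res.pu == pytest.approx(1e-13)

    def test_pu_zero_when_control_equals_sample(self):
        res = single_channel_permeability(5.9e-2, 2.13e12, pf_control=5.9e-2)
        assert res.pu == 0.0

    def test_pu_clamped_when_control_exceeds_sample(self):
        res = single_channel_permeability(1e-2, 2.13e12, pf_control=2e-2)
        assert res.pu == 0.0 and res.flags

    def test_background_subtracted_pu_arithmetic(self):
        su_d = channel_density(LiposomeGeometry(lpr_basis="molar"))
        res = single_channel_permeability(5.9e-2, su_d, pf_control=1.2e-2)
        assert res.pu == pytest.approx((5.9e-2 - 1.2e-2) / su_d, rel=1e-12)
        assert res.pu == pytest.approx(2.2e-14, rel=0.01)

    def test_mannitol_injection_dilution(self):
        assert injection_concentration(400.0, 75.0, 75.0) == pytest.approx(200.0)


class TestQuench:
    def test_noiseless_round_trip(self):
        trace = gen_quench_trace(0.5, seed=1)
        fit = fit_quench(trace)
        assert fit.k == pytest.approx(0.5, rel=1e-6)
        assert fit.decay_detected

    def test_constant_trace_flagged(self):
        t = np.arange(0, 55, 0.05)
        fit = fit_quench(QuenchTrace(t, np.ones_like(t)))
        assert fit.k == 0.0 and not fit.decay_detected

    def test_rate_ratio_preserved_under_noise(self):
        fits = []
        for k, seed in ((1.0, 10), (0.5, 11)):
            trace = gen_quench_trace(k, seed=seed, noise_sd=0.01 * 0.4)
            fits.append(fit_quench(trace).k)
        assert fits[0] / fits[1] == pytest.approx(2.0, rel=0.02)

    def test_injection_detection_by_max_derivative(self):
        trace = gen_quench_trace(0.5, seed=2, injection_time=7.0)
        fit = fit_quench(trace, injection_time=None)
        assert fit.injection_time == pytest.approx(7.0, abs=0.2)
        assert fit.k == pytest.approx(0.5, rel=0.01)

    def test_rate_ordering_rank_correlation(self):
        # ordering of generated permeabilities survives 5% noise
        from scipy.stats import spearmanr

        truth = np.linspace(0.2, 2.0, 8)
        fitted = [
            fit_quench(gen_quench_trace(k, seed=100 + i, noise_sd=0.05 * 0.4)).k
            for i, k in enumerate(truth)
        ]
        assert spearmanr(truth, fitted).statistic == 1.0


class TestVolumeConversion:
    def test_identity_calibration(self):
        cal = VolumeCalibration([0.0, 1.0], [0.0, 1.0])
        f = np.array([0.2, 0.6, 1.0])
        v, flags = to_volume(f, cal)
        np.testing.assert_allclose(v, f)
        assert not flags

    def test_linear_calibration_arithmetic(self):
        cal = VolumeCalibration([0.0, 1.0], [0.5, 1.0], method="linear")
        v, _ = to_volume([1.0, 0.6], cal)
        assert v[0] == pytest.approx(1.0)
        assert v[1] == pytest.approx(0.8)

    def test_round_trip_through_inverse(self):
        f_cal = np.linspace(0.3, 1.0, 8)
        v_cal = 0.2 + 0.8 * f_cal**1.3  # monotone, maps 1 -> 1
        cal = VolumeCalibration(f_cal, v_cal)
        inv = VolumeCalibration(v_cal, f_cal)
        f = np.linspace(0.35, 0.95, 20)
        v, _ = to_volume(f, cal)
        f_back, _ = to_volume(v, inv)
        np.testing.assert_allclose(f_back, f, rtol=1e-10)

    def test_monotonicity_preserved(self):
        cal = VolumeCalibration([0.2, 0.6, 1.0], [0.4, 0.75, 1.0])
        f = np.linspace(0.25, 0.95, 30)
        v, _ = to_volume(f, cal)
        assert np.all(np.diff(v) > 0)

    def test_extrapolation_flagged(self):
        cal = VolumeCalibration([0.5, 1.0], [0.6, 1.0])
        _, flags = to_volume([0.1], cal)
        assert flags

    def test_non_monotone_calibration_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            VolumeCalibration([0.0, 0.5, 1.0], [0.2, 0.1, 1.0])

    def test_unit_point_required(self):
        with pytest.raises(ValueError, match="1.0"):
            VolumeCalibration([0.0, 1.0], [0.1, 0.9])


class TestAccumulation:
    @pytest.mark.parametrize("k,expected_thalf", [(0.7702, 0.9), (0.1238, 5.6)])
    def test_halftime_inversion(self, k, expected_thalf):
        t = np.linspace(0, 30, 40)
        fit = accumulation_halftime(t, 1 - np.exp(-k * t))
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.t_half == pytest.approx(expected_thalf, abs=0.05)

    def test_thalf_times_k_is_ln2(self):
        t = np.linspace(0, 12, 25)
        for k in (0.1, 0.5, 2.0):
            fit = accumulation_halftime(t, 1 - np.exp(-k * t))
            assert fit.t_half * fit.k == pytest.approx(np.log(2.0))

    def test_non_saturating_data_flagged(self):
        t = np.linspace(0, 1, 10)
        y = 0.02 * t  # nearly linear, far from plateau
        fit = accumulation_halftime(t, y)
        assert not fit.converged


class TestStopflowGenerator:
    def test_noiseless_closed_form(self):
        d = StopFlowDesign(k_fast=63.7, k_slow=5.0, a_fast=0.7, a_slow=0.3)
        trace = gen_stopflow_trace(d, seed=1)
        expected = (
            1.0
            + 0.7 * (1 - np.exp(-63.7 * trace.time))
            + 0.3 * (1 - np.exp(-5.0 * trace.time))
        )
        np.testing.assert_allclose(trace.fluorescence, expected, rtol=1e-12)

    def test_read_averaging_reduces_noise_by_sqrt_n(self):
        # residual SD ratio over many seeds approaches 1/sqrt(10)
        def resid_sd(n_reads, seed):
            d = StopFlowDesign(noise_sd=0.05, n_reads=n_reads, dt=0.01)
            tr = gen_stopflow_trace(d, seed=seed)
            clean = (
                1.0
                + 0.7 * (1 - np.exp(-63.7 * tr.time))
                + 0.3 * (1 - np.exp(-5.0 * tr.time))
            )
            return np.std(tr.fluorescence - clean)

        r10 = np.mean([resid_sd(10, s) for s in range(100)])
        r1 = np.mean([resid_sd(1, 10_000 + s) for s in range(100)])
        assert r10 / r1 == pytest.approx(1 / np.sqrt(10), rel=0.1)

    def test_invalid_rate_ordering_rejected(self):
        with pytest.raises(ValueError, match="k_fast"):
            StopFlowDesign(k_fast=1.0, k_slow=2.0)

    def test_pipeline_recovers_pf_within_3_percent(self):
        d = StopFlowDesign(k_fast=63.7, k_slow=5.0, noise_sd=0.01)
        trace = gen_stopflow_trace(d, seed=77)
        fit = fit_double_exponential(trace)
        pf = osmotic_permeability(fit.k_selected)
        assert pf == pytest.approx(osmotic_permeability(63.7), rel=0.03)
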