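"""SR-FLASH forward model, LUT inversion, dual-bolus AIF assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perfquant.curves import InvalidInputError, SampledCurve
from perfquant.mr_signal import (
    FootDetectionError,
    MRProtocol,
    PHANTOM_PROTOCOL,
    SaturationError,
    assemble_dual_bolus_aif,
    build_lut,
    detect_bolus_foot,
    normalize_aif_integral,
    signal_to_concentration,
    srflash_signal,
)


class TestSRFlashSignal:
    def test_zero_concentration_baseline(self):
        """S(0) = M0 sin(alpha) (1 - exp(-TI/T10))."""
        p = PHANTOM_PROTOCOL
        expect = p.m0 * np.sin(np.radians(p.flip_deg)) * (1 - np.exp(-p.ti_ms / p.t10_ms))
        assert srflash_signal(0.0, p) == pytest.approx(expect, rel=1e-12)
        assert srflash_signal(0.0, p) > 0

    def test_saturation_ceiling(self):
        p = PHANTOM_PROTOCOL
        ceiling = p.m0 * np.sin(np.radians(p.flip_deg))
        assert srflash_signal(1e6, p) == pytest.approx(ceiling, rel=1e-9)

    def test_sublinearity_at_neat_bolus_concentrations(self):
        """The signal-concentration relation is visibly sub-linear above ~2 mmol/L."""
        p = MRProtocol(ti_ms=100.0, flip_deg=10.0, t10_ms=2000.0, r1_relaxivity=5.0)
        assert srflash_signal(4.0, p) / srflash_signal(0.4, p) < 10.0

    def test_strictly_monotone_on_grid(self):
        for p in (PHANTOM_PROTOCOL, MRProtocol(ti_ms=115, flip_deg=14, t10_ms=1900)):
            s = srflash_signal(np.linspace(0, 10, 2001), p)
            assert np.all(np.diff(s) > 0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(InvalidInputError):
            srflash_signal(-0.1, PHANTOM_PROTOCOL)

    def test_protocol_validation(self):
        with pytest.raises(InvalidInputError):
            MRProtocol(flip_deg=0.0)
        with pytest.raises(InvalidInputError):
            MRProtocol(n_baseline=240, n_dynamics=240)


class TestLUT:
    def test_minimal_grid_endpoints(self):
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=5.0, n_points=2)
        assert lut.conc_grid.tolist() == [0.0, 5.0]
        assert lut.signal_grid[0] == pytest.approx(srflash_signal(0.0, PHANTOM_PROTOCOL))

    def test_round_trip_inversion(self):
        """conc -> signal -> LUT inversion within 1e-3 mmol/L at 4096 points."""
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=6.0, n_points=4096)
        rng = np.random.default_rng(11)
        conc_true = np.sort(rng.uniform(0.0, 5.5, 50))
        t = np.arange(len(conc_true), dtype=float)
        sig = SampledCurve(t, srflash_signal(conc_true, PHANTOM_PROTOCOL), unit="a.u.")
        baseline = srflash_signal(0.0, PHANTOM_PROTOCOL)
        out = signal_to_concentration(sig, lut, baseline)
        assert np.max(np.abs(out.curve.values - conc_true)) < 1e-3
        assert out.n_clamped == 0

    def test_round_trip_with_rescaled_m0(self):
        """Baseline calibration absorbs an arbitrary receiver gain."""
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=4.0, n_points=4096)
        conc_true = np.linspace(0.0, 3.0, 40)
        gain = 2.7
        t = np.arange(len(conc_true), dtype=float)
        sig = SampledCurve(t, gain * srflash_signal(conc_true, PHANTOM_PROTOCOL), unit="a.u.")
        out = signal_to_concentration(sig, lut, gain * srflash_signal(0.0, PHANTOM_PROTOCOL))
        assert np.max(np.abs(out.curve.values - conc_true)) < 1e-3

    def test_baseline_curve_maps_to_zero(self):
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=4.0, n_points=256)
        b = srflash_signal(0.0, PHANTOM_PROTOCOL)
        sig = SampledCurve([0.0, 1.0, 2.0], [b, b, b], unit="a.u.")
        out = signal_to_concentration(sig, lut, b)
        assert np.all(out.curve.values == 0)

    def test_below_baseline_clamps_and_counts(self):
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=4.0, n_points=256)
        b = srflash_signal(0.0, PHANTOM_PROTOCOL)
        sig = SampledCurve([0.0, 1.0, 2.0], [0.99 * b, b, 1.2 * b], unit="a.u.")
        out = signal_to_concentration(sig, lut, b)
        assert out.n_clamped == 1
        assert out.curve.values[0] == 0.0

    def test_saturation_error_names_time_points(self):
        lut = build_lut(PHANTOM_PROTOCOL, conc_max=1.0, n_points=64)
        b = srflash_signal(0.0, PHANTOM_PROTOCOL)
        high = srflash_signal(5.0, PHANTOM_PROTOCOL)
        sig = SampledCurve([0.0, 7.0], [b, high], unit="a.u.")
        with pytest.raises(SaturationError, match="7.0"):
            signal_to_concentration(sig, lut, b)


class TestDualBolusAssembly:
    @staticmethod
    def _bolus(t0, peak=1.0, n=120):
        t = np.arange(float(n))
        s = np.maximum(t - t0, 0.0)
        v = peak * (s / 12.0) ** 3 * np.exp(3 - s / 4.0)
        v[s <= 0] = 0
        return SampledCurve(t, v, unit="mmol/L")

    def test_identity_when_already_aligned(self):
        dilute = self._bolus(12.0)
        foot = detect_bolus_foot(dilute)
        out = assemble_dual_bolus_aif(dilute, 1.0, foot)
        assert np.allclose(out.values, dilute.values)
        assert np.allclose(out.times, dilute.times)

    def test_dose_ratio_scales_peak(self):
        dilute = self._bolus(12.0)
        out = assemble_dual_bolus_aif(dilute, 10.0, 137.0)
        assert out.values.max() == pytest.approx(10 * dilute.values.max(), rel=1e-12)

    def test_known_shift_recovery(self):
        """Foot at 12 s moved to 137 s lands within one sample."""
        dilute = self._bolus(12.0)
        out = assemble_dual_bolus_aif(dilute, 10.0, 137.0)
        foot_out = detect_bolus_foot(out)
        assert abs(foot_out - 137.0) <= 1.0

    def test_translation_equivariance(self):
        dilute = self._bolus(12.0)
        shifted_in = SampledCurve(dilute.times + 30.0, dilute.values, unit="mmol/L")
        a = assemble_dual_bolus_aif(dilute, 10.0, 150.0)
        b = assemble_dual_bolus_aif(shifted_in, 10.0, 150.0)
        assert np.allclose(a.values, b.values)
        assert np.allclose(np.interp(160.0, a.times, a.values),
                           np.interp(160.0, b.times, b.values))

    def test_flat_curve_raises_detection_error(self):
        flat = SampledCurve(np.arange(50.0), np.zeros(50), unit="mmol/L")
        with pytest.raises(FootDetectionError):
            assemble_dual_bolus_aif(flat, 10.0, 100.0)


class TestNormalizeAifIntegral:
    def test_unit_scale_when_integrals_match(self, gamma_aif):
        out = normalize_aif_integral(gamma_aif, gamma_aif)
        assert np.allclose(out.values, gamma_aif.values)

    def test_boxcar_hand_integration(self):
        t = np.linspace(0.0, 10.0, 101)
        aif = SampledCurve(t, np.full_like(t, 2.0), unit="mmol/L")
        myo = SampledCurve(t, np.full_like(t, 1.0), unit="mmol/L")
        out = normalize_aif_integral(aif, myo)
        assert np.allclose(out.values, 1.0)

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(0.01, 100.0))
    def test_invariant_to_prior_scaling(self, c):
        t = np.arange(0.0, 80.0, 0.5)
        v = np.maximum(t - 10, 0) ** 2 * np.exp(-(t - 10) / 5.0)
        aif = SampledCurve(t, v, unit="mmol/L")
        myo = aif.with_values(0.3 * aif.values)
        a = normalize_aif_integral(aif, myo)
        b = normalize_aif_integral(aif.with_values(c * aif.values), myo)
        assert np.allclose(a.values, b.values, rtol=1e-9)

    def test_idempotent(self, gamma_aif):
        myo = gamma_aif.with_values(0.5 * gamma_aif.values)
        once = normalize_aif_integral(gamma_aif, myo)
        twice = normalize_aif_integral(once, myo)
        assert np.allclose(once.values, twice.values, rtol=1e-13)
        assert once.integral() == pytest.approx(myo.integral(), rel=1e-12)

    def test_zero_integral_raises(self):
        t = np.arange(10.0)
        zero = SampledCurve(t, np.zeros(10), unit="mmol/L")
        myo = SampledCurve(t, np.ones(10), unit="mmol/L")
        with pytest.raises(ZeroDivisionError):
            normalize_aif_integral(zero, myo)
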