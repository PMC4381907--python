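"""Estimators: dF/F, tail extrapolation, Boltzmann, exponentials, Hill."""

import numpy as np
import pytest

from iksgate.analysis import (
    delta_f_over_f,
    dose_response,
    extract_gv,
    fit_boltzmann,
    fit_exponentials,
    fraction_inhibited_timeseries,
    permeability_ratio,
    tail_amplitude,
)
from iksgate.constants import DEFAULT_CONSTANTS
from iksgate.recording import Recording


def make_recording(times, voltage, current=None, fluor=None, **meta):
    n = len(times)
    return Recording(
        times_ms=np.asarray(times, dtype=float),
        voltage_mv=np.asarray(voltage, dtype=float),
        current=np.zeros(n) if current is None else np.asarray(current, dtype=float),
        fluorescence=np.ones(n) if fluor is None else np.asarray(fluor, dtype=float),
        meta=meta,
    )


def boltzmann_curve(v, z, v_half, amp=1.0):
    c = DEFAULT_CONSTANTS
    return amp / (1.0 + np.exp(-z * c.F * ((v - v_half) / 1000.0) / (c.R * c.T)))


class TestDeltaFOverF:
    def _rec(self, fluor, pulse_start=2000.0, n=4000):
        t = np.arange(n, dtype=float)
        v = np.where(t < pulse_start, -80.0, 0.0)
        return make_recording(t, v, fluor=fluor), pulse_start

    def test_doubling_gives_unity(self):
        t = np.arange(4000, dtype=float)
        f = np.where(t < 2000, 1000.0, 2000.0)
        rec, start = self._rec(f)
        dff, (b0, b1) = delta_f_over_f(rec, start)
        assert b0 == pytest.approx(1000.0) and b1 == pytest.approx(0.0, abs=1e-9)
        assert dff[-1] == pytest.approx(1.0, rel=1e-9)

    def test_pure_linear_drift_removed(self):
        t = np.arange(4000, dtype=float)
        f = 800.0 - 0.02 * t
        rec, start = self._rec(f)
        dff, _ = delta_f_over_f(rec, start)
        assert np.abs(dff).max() < 1e-9

    def test_multiplicative_signal_recovered_through_drift(self):
        t = np.arange(5000, dtype=float)
        s = np.where(t >= 2000, 0.08 * (1 - np.exp(-(t - 2000) / 300.0)), 0.0)
        f = (1200.0 - 0.03 * t) * (1.0 + s)
        rec, start = self._rec(f, n=5000)
        dff, _ = delta_f_over_f(rec, start)
        assert np.abs(dff - s).max() < 1e-6

    def test_insufficient_baseline_window_rejected(self):
        rec, _ = self._rec(np.ones(4000) * 500.0)
        with pytest.raises(ValueError):
            delta_f_over_f(rec, 500.0)  # only 0.5 s of pre-pulse data

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(4000, dtype=float)
        f = 10.0 - 0.004 * t  # goes negative before the sweep ends
        rec, start = self._rec(f)
        with pytest.raises(ValueError):
            delta_f_over_f(rec, start)


class TestTailAmplitude:
    def test_exact_on_constructed_mono_exponential_tail(self):
        t = np.arange(0, 1000, dtype=float)
        tail_start = 400.0
        a, tau, c = 750.0, 85.0, 120.0
        i = np.where(t < tail_start, 900.0, c + a * np.exp(-(t - tail_start) / tau))
        rec = make_recording(t, np.where(t < tail_start, 40.0, -60.0), current=i)
        fit = tail_amplitude(rec, tail_start, window_ms=(0.0, 300.0), components=1)
        assert fit.converged
        assert fit.amplitude == pytest.approx(a + c, rel=1e-9)
        assert fit.tau_ms == pytest.approx(tau, rel=1e-6)

    def test_two_component_fit_handles_biexponential_tail(self):
        t = np.arange(0, 800, dtype=float)
        i = 50.0 + 400.0 * np.exp(-t / 8.0) + 250.0 * np.exp(-t / 160.0)
        rec = make_recording(t, np.full_like(t, -60.0), current=i)
        fit = tail_amplitude(rec, 0.0, window_ms=(0.0, 400.0), components=2)
        assert fit.amplitude == pytest.approx(700.0, rel=1e-6)


class TestExtractGV:
    def _family(self, amps, tail_start=500.0, tau=60.0, n=1000):
        recs = []
        t = np.arange(n, dtype=float)
        for v_test, a in amps.items():
            i = np.where(t < tail_start, a, a * np.exp(-(t - tail_start) / tau))
            v = np.where(t < tail_start, v_test, 60.0)
            recs.append(make_recording(t, v, current=i, test_voltage_mv=v_test))
        return recs, tail_start

    def test_normalization_to_highest_voltage(self):
        recs, start = self._family({-40.0: 200.0, 0.0: 600.0, 40.0: 800.0})
        df = extract_gv(recs, start)
        assert df.loc[df["voltage_mV"].idxmax(), "gv_norm"] == pytest.approx(1.0)
        assert dict(zip(df["voltage_mV"], df["gv_norm"])) == pytest.approx(
            {-40.0: 0.25, 0.0: 0.75, 40.0: 1.0}, rel=1e-6
        )

    def test_identical_recordings_give_unity_everywhere(self):
        recs, start = self._family({v: 500.0 for v in (-60.0, -20.0, 20.0)})
        df = extract_gv(recs, start)
        assert np.abs(df["gv_norm"] - 1.0).max() < 1e-9

    def test_mismatched_tail_voltages_rejected(self):
        recs, start = self._family({-40.0: 200.0, 0.0: 600.0})
        bad = recs[1]
        bad.voltage_mv[int(start) :] = -40.0
        with pytest.raises(ValueError):
            extract_gv(recs, start)


class TestBoltzmannFit:
    def test_single_component_self_consistency(self):
        v = np.arange(-100.0, 61.0, 10.0)
        y = boltzmann_curve(v, z=2.0, v_half=-20.0)
        fit = fit_boltzmann(v, y, components=1)
        c = fit.components[0]
        assert c.z == pytest.approx(2.0, rel=1e-3)
        assert c.v_half_mv == pytest.approx(-20.0, abs=0.02)

    def test_symmetric_data_fits_v_half_at_symmetry_point(self):
        v = np.arange(-60.0, 61.0, 5.0)
        y = boltzmann_curve(v, z=1.3, v_half=0.0)
        fit = fit_boltzmann(v, y, components=1)
        assert fit.components[0].v_half_mv == pytest.approx(0.0, abs=1e-6)

    def test_two_component_mixture_recovery_with_noise(self):
        rng = np.random.default_rng(42)
        v = np.arange(-100.0, 101.0, 10.0)
        y = 0.5 * boltzmann_curve(v, 2.0, -40.0) + 0.5 * boltzmann_curve(v, 1.5, 40.0)
        y_noisy = y + rng.normal(0, 0.01, y.shape)
        fit = fit_boltzmann(v, y_noisy, components=2)
        assert fit.main.v_half_mv == pytest.approx(-40.0, abs=0.02 * 80)
        assert fit.high.v_half_mv == pytest.approx(40.0, abs=0.02 * 80)
        assert fit.main.v_half_mv < fit.high.v_half_mv

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0.0, 10.0, 20.0], [0.1, 0.5, 0.9], components=1)
        with pytest.raises(ValueError):
            fit_boltzmann(np.arange(6.0), np.linspace(0, 1, 6), components=2)


class TestExponentialFit:
    def test_single_onset_self_consistency(self):
        t = np.arange(0.0, 1500.0)
        y = 10.0 + 400.0 * (1.0 - np.exp(-t / 150.0))
        fit = fit_exponentials(t, y, components=1, kind="onset")
        assert fit.components[0].tau_ms == pytest.approx(150.0, rel=5e-3)
        assert fit.components[0].amplitude == pytest.approx(400.0, rel=5e-3)

    def test_biexponential_recovery_with_noise(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 4000.0)
        y = 100.0 * (1.0 - np.exp(-t / 50.0)) + 100.0 * (1.0 - np.exp(-t / 1000.0))
        y_noisy = y + rng.normal(0, 2.0, t.shape)  # 1% of full amplitude
        fit = fit_exponentials(t, y_noisy, components=2, kind="onset")
        assert fit.tau_fast_ms == pytest.approx(50.0, rel=0.05)
        assert fit.tau_slow_ms == pytest.approx(1000.0, rel=0.05)

    def test_constant_trace_flagged_degenerate(self):
        t = np.arange(0.0, 200.0)
        fit = fit_exponentials(t, np.full_like(t, 5.0), components=1, kind="onset")
        assert fit.degenerate

    def test_decay_form(self):
        t = np.arange(0.0, 900.0)
        y = 20.0 + 300.0 * np.exp(-t / 120.0)
        fit = fit_exponentials(t, y, components=1, kind="decay")
        assert fit.components[0].tau_ms == pytest.approx(120.0, rel=1e-3)


class TestPermeabilityRatio:
    def _pair(self, scale_rb, tail_start=400.0, n=900):
        t = np.arange(n, dtype=float)
        v = np.where(t < tail_start, 60.0, -60.0)
        base = np.where(t < tail_start, 500.0, 500.0 * np.exp(-(t - tail_start) / 90.0))
        rec_k = make_recording(t, v.copy(), current=base, ion="K")
        rec_rb = make_recording(t, v.copy(), current=scale_rb * base, ion="Rb")
        return rec_k, rec_rb, tail_start

    def test_identical_recordings_give_unity(self):
        rec_k, rec_rb, start = self._pair(1.0)
        res = permeability_ratio(rec_k, rec_rb, start)
        assert res.ratio_rb_over_k == pytest.approx(1.0, rel=1e-9)

    def test_ratio_is_linear_in_tail_scale(self):
        _, _, start = self._pair(1.0)
        r1 = permeability_ratio(*self._pair(0.7)[:2], start).ratio_rb_over_k
        r2 = permeability_ratio(*self._pair(1.4)[:2], start).ratio_rb_over_k
        assert r1 == pytest.approx(0.7, rel=1e-6)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-6)

    def test_mismatched_protocols_rejected(self):
        rec_k, rec_rb, start = self._pair(0.7)
        rec_rb.voltage_mv[:10] = 0.0
        with pytest.raises(ValueError):
            permeability_ratio(rec_k, rec_rb, start)


class TestDoseResponse:
    def test_half_maximal_inhibition_at_ic50(self):
        fit = dose_response([0.5, 2.0, 8.0], [0.18, 0.45, 0.72])
        f_at_ic50 = fit.f_max * fit.ic50_um / (fit.ic50_um + fit.ic50_um)
        assert f_at_ic50 == pytest.approx(fit.f_max / 2.0)

    def test_noiseless_self_consistency(self):
        c = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        f = 0.9 * c / (c + 2.0)
        fit = dose_response(c, f)
        assert fit.ic50_um == pytest.approx(2.0, rel=0.02)
        assert fit.f_max == pytest.approx(0.9, rel=0.02)
        assert fit.hill_n == 1.0

    def test_no_block_gives_zero_inhibition_series(self):
        t = np.arange(100.0)
        rec = make_recording(t, np.zeros_like(t), current=np.full_like(t, 3.0))
        series = fraction_inhibited_timeseries(rec, rec)
        assert np.nanmax(np.abs(series)) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_response([1.0, 2.0], [0.3, 0.5])
        with pytest.raises(ValueError):
            dose_response([0.0, 1.0, 2.0], [0.1, 0.3, 0.5])
        with pytest.raises(ValueError):
            dose_response([1.0, 2.0, 4.0], [0.0, 0.0, 0.0])
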