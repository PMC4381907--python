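"""Voltage-clamp-fluorometry analysis procedures.

Implements the standard VCF analysis chain:

* dF/F with a linearly extrapolated pre-pulse baseline,
* GV extraction from instantaneous tail currents (mono-exponential
  extrapolation back to the tail-step time), normalized to the
  highest-voltage test pulse,
* single / double Boltzmann fits of GV and FV curves, with the
  lower-V1/2 component of a double fit labelled "main" and the other
  "high",
* single / bi-exponential kinetics of current and fluorescence onsets
  and tails,
* Rb+/K+ permeability ratios as ratios of instantaneous tail-current
  amplitudes, and
* XE991 dose-response fits to a Hill equation with coefficient fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .recording import Recording

DEFAULT_TAIL_WINDOW_MS = (0.0, 100.0)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannComponent:
    amplitude: float
    z: float
    v_half_mv: float
    amplitude_stderr: Optional[float] = None
    z_stderr: Optional[float] = None
    v_half_stderr: Optional[float] = None


@dataclass
class BoltzmannFit:
    components: List[BoltzmannComponent]
    residual_norm: float
    n_components: int
    baseline: float = 0.0

    @property
    def main(self) -> BoltzmannComponent:
        """Lower-V1/2 component (the 'main', low-voltage component)."""
        return min(self.components, key=lambda c: c.v_half_mv)

    @property
    def high(self) -> BoltzmannComponent:
        """Higher-V1/2 component of a two-component fit."""
        return max(self.components, key=lambda c: c.v_half_mv)

    def predict(self, v_mv: np.ndarray, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        y = np.full_like(v, self.baseline, dtype=float)
        for c in self.components:
            y += c.amplitude * _boltzmann(v, c.z, c.v_half_mv, constants)
        return y

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "baseline": self.baseline,
            "residual_norm": self.residual_norm,
            "components": [
                {
                    "amplitude": c.amplitude,
                    "z": c.z,
                    "v_half_mv": c.v_half_mv,
                    "amplitude_stderr": c.amplitude_stderr,
                    "z_stderr": c.z_stderr,
                    "v_half_stderr": c.v_half_stderr,
                }
                for c in self.components
            ],
        }


@dataclass
class ExponentialComponent:
    amplitude: float
    tau_ms: float


@dataclass
class ExponentialFit:
    components: List[ExponentialComponent]  # fast first
    y0: float
    residual_norm: float
    n_components: int
    kind: str  # "onset" or "decay"
    degenerate: bool = False
    tau_exceeds_segment: bool = False

    @property
    def tau_fast_ms(self) -> float:
        return self.components[0].tau_ms

    @property
    def tau_slow_ms(self) -> float:
        return self.components[-1].tau_ms

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        y = np.full_like(t, self.y0, dtype=float)
        for c in self.components:
            if self.kind == "onset":
                y += c.amplitude * (1.0 - np.exp(-t / c.tau_ms))
            else:
                y += c.amplitude * np.exp(-t / c.tau_ms)
        return y


@dataclass
class TailFit:
    """Instantaneous tail amplitude from a mono-exponential extrapolation."""

    amplitude: float  # extrapolated value at the tail-step time
    tau_ms: float
    steady: float  # fitted asymptote
    residual_norm: float
    converged: bool
    fallback_first_sample: bool = False


@dataclass
class PermeabilityResult:
    tail_amplitude_k: float
    tail_amplitude_rb: float
    ratio_rb_over_k: float
    uncertainty: Optional[float] = None


@dataclass
class DoseResponseFit:
    ic50_um: float
    hill_n: float
    f_max: float
    residual_norm: float
    ic50_stderr: Optional[float] = None


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------

def delta_f_over_f(
    rec: Recording,
    pulse_start_ms: float,
    baseline_window_ms: float = 2000.0,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Baseline-corrected relative fluorescence dF/F(t).

    A line is fit to the raw fluorescence over the `baseline_window_ms`
    (default 2 s) preceding the pulse, while the command voltage sits at
    the holding potential; the line is extrapolated over the whole sweep
    and dF/F = (F - baseline)/baseline.  Returns the dF/F series and the
    (intercept, slope per ms) of the baseline fit.
    """
    t = np.asarray(rec.times_ms, dtype=float)
    mask = (t >= pulse_start_ms - baseline_window_ms - 1e-9) & (t < pulse_start_ms - 1e-9)
    if mask.sum() < 10 or (t[mask].max() - t[mask].min()) < 0.95 * baseline_window_ms:
        raise ValueError(
            f"insufficient pre-pulse window: need {baseline_window_ms} ms of data "
            f"before t={pulse_start_ms} ms"
        )
    holding = rec.voltage_mv[mask]
    if np.ptp(holding) > 1e-6:
        raise ValueError("pre-pulse window is not at a constant holding potential")
    slope, intercept = np.polyfit(t[mask], rec.fluorescence[mask], 1)
    baseline = intercept + slope * t
    if np.any(baseline <= 0):
        raise ValueError("extrapolated baseline is non-positive; cannot form dF/F")
    dff = (rec.fluorescence - baseline) / baseline
    return dff, (intercept, slope)


# ---------------------------------------------------------------------------
# tail currents and GV
# ---------------------------------------------------------------------------

def tail_amplitude(
    rec: Recording,
    tail_start_ms: float,
    window_ms: Tuple[float, float] = DEFAULT_TAIL_WINDOW_MS,
    components: int = 2,
) -> TailFit:
    """Instantaneous tail-current amplitude at the tail-step time.

    Fits I(t) = I_inf + sum_i a_i exp(-(t - t0)/tau_i) over the window
    (offsets from the tail step, default 0-100 ms) and extrapolates to t0;
    the default two components absorb the fast pore relaxation and the
    slower VSD relaxation of the tail.  Deterministic multi-starts over
    tau; best residual wins.  Falls back (flagged) to the first in-window
    sample if every start fails.
    """
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    t = np.asarray(rec.times_ms, dtype=float)
    m = (t >= tail_start_ms + window_ms[0] - 1e-9) & (t <= tail_start_ms + window_ms[1] + 1e-9)
    if m.sum() < 3 + 2 * components:
        raise ValueError("too few samples in the tail window")
    tt = t[m] - tail_start_ms
    yy = np.asarray(rec.current, dtype=float)[m]
    span_ms = max(window_ms[1] - window_ms[0], 1.0)

    def residual(p):
        model = np.full_like(yy, p["i_inf"].value)
        for i in range(components):
            model = model + p[f"a{i}"].value * np.exp(-tt / p[f"tau{i}"].value)
        return model - yy

    if components == 1:
        tau_starts = [[span_ms / 10], [span_ms / 3], [span_ms]]
    else:
        tau_starts = [
            [span_ms / 20, span_ms / 2],
            [span_ms / 10, span_ms],
            [span_ms / 40, span_ms / 4],
        ]
    best = None
    for taus in tau_starts:
        params = lmfit.Parameters()
        params.add("i_inf", value=float(yy[-1]))
        for i, tau0 in enumerate(taus):
            params.add(f"a{i}", value=float(yy[0] - yy[-1]) / components)
            params.add(f"tau{i}", value=float(tau0), min=1e-3)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if np.isfinite(res.chisqr) and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        return TailFit(
            amplitude=float(yy[0]), tau_ms=np.nan, steady=np.nan,
            residual_norm=np.nan, converged=False, fallback_first_sample=True,
        )
    p = best.params
    taus = sorted(float(p[f"tau{i}"].value) for i in range(components))
    amplitude = float(p["i_inf"].value) + sum(
        float(p[f"a{i}"].value) for i in range(components)
    )
    return TailFit(
        amplitude=amplitude,
        tau_ms=taus[0],
        steady=float(p["i_inf"].value),
        residual_norm=float(np.sqrt(best.chisqr)),
        converged=True,
    )


def _test_voltage(rec: Recording, tail_start_ms: float) -> float:
    """Test-pulse voltage: the command value just before the tail step."""
    if "test_voltage_mv" in rec.meta:
        return float(rec.meta["test_voltage_mv"])
    t = np.asarray(rec.times_ms, dtype=float)
    before = t < tail_start_ms - 1e-9
    return float(rec.voltage_mv[before][-1])


def extract_gv(
    recordings: Sequence[Recording],
    tail_start_ms: float,
    window_ms: Tuple[float, float] = DEFAULT_TAIL_WINDOW_MS,
) -> pd.DataFrame:
    """Normalized GV table from a family of test-pulse recordings.

    All recordings must share the tail voltage.  Each row holds the
    test-pulse voltage, the extrapolated instantaneous tail amplitude, and
    the amplitude normalized to the highest-voltage pulse.
    """
    if len(recordings) == 0:
        raise ValueError("no recordings")
    tail_volts = {
        round(float(r.voltage_mv[np.searchsorted(r.times_ms, tail_start_ms + 1e-6)]), 6)
        for r in recordings
    }
    if len(tail_volts) != 1:
        raise ValueError(f"recordings do not share a tail voltage: {sorted(tail_volts)}")
    rows = []
    for rec in recordings:
        fit = tail_amplitude(rec, tail_start_ms, window_ms)
        rows.append(
            dict(
                voltage_mV=_test_voltage(rec, tail_start_ms),
                gv_raw=fit.amplitude,
                tail_tau_ms=fit.tau_ms,
                converged=fit.converged,
                fallback=fit.fallback_first_sample,
            )
        )
    df = pd.DataFrame(rows).sort_values("voltage_mV").reset_index(drop=True)
    ref = df.loc[df["voltage_mV"].idxmax(), "gv_raw"]
    df["gv_norm"] = df["gv_raw"] / ref
    return df


def extract_fv(
    recordings: Sequence[Recording],
    pulse_start_ms: float,
    pulse_end_ms: float,
    baseline_window_ms: float = 2000.0,
    end_margin_ms: float = 10.0,
    end_window_ms: float = 40.0,
) -> pd.DataFrame:
    """Normalized FV table: end-of-pulse dF/F per test voltage, normalized
    to the highest-voltage pulse.

    The end-of-pulse value is averaged over a short window ending
    `end_margin_ms` before the pulse/tail boundary: the margin keeps the
    (zero-phase) low-pass filter from smearing the tail-step response into
    the reading, and the window averages acquisition noise while the
    signal is near equilibrium.
    """
    rows = []
    for rec in recordings:
        dff, _ = delta_f_over_f(rec, pulse_start_ms, baseline_window_ms)
        t = np.asarray(rec.times_ms, dtype=float)
        hi = pulse_end_ms - end_margin_ms
        m = (t >= hi - end_window_ms - 1e-9) & (t <= hi + 1e-9)
        if m.sum() < 1:
            raise ValueError("end-of-pulse window contains no samples")
        rows.append(
            dict(voltage_mV=_test_voltage(rec, pulse_end_ms), fv_raw=float(dff[m].mean()))
        )
    df = pd.DataFrame(rows).sort_values("voltage_mV").reset_index(drop=True)
    ref = df.loc[df["voltage_mV"].idxmax(), "fv_raw"]
    df["fv_norm"] = df["fv_raw"] / ref
    return df


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------

def _boltzmann(v, z, v_half, constants: PhysicalConstants) -> np.ndarray:
    x = -z * constants.F * ((v - v_half) / 1000.0) / (constants.R * constants.T)
    return 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))


def fit_boltzmann(
    voltages_mv: Sequence[float],
    y: Sequence[float],
    components: int = 1,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    fit_baseline: bool = False,
    fixed_amplitudes: Optional[Sequence[float]] = None,
) -> BoltzmannFit:
    """Least-squares fit of a sum of Boltzmann activation curves.

    y(V) = baseline + sum_i a_i / (1 + exp(-z_i F (V - V1/2,i) / RT)).
    Two-component fits use 8 deterministic multi-starts over a coarse
    (z, V1/2) grid and keep the best residual; the lower-V1/2 component is
    the "main" one.  `fixed_amplitudes` pins the a_i ratio (a shared
    overall scale stays free) -- useful when the component amplitude split
    is known structurally, as for fluorescence components whose weights
    are set by the fluorophore; this removes the amplitude/position
    degeneracy of two-component fits on smooth curves.
    """
    v = np.asarray(voltages_mv, dtype=float)
    yy = np.asarray(y, dtype=float)
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    if len(v) < 4 * components:
        raise ValueError(f"need at least {4 * components} points for {components} component(s)")

    vspan = (v.min(), v.max())

    if fixed_amplitudes is not None and len(fixed_amplitudes) != components:
        raise ValueError("fixed_amplitudes must have one entry per component")

    def make_params(starts):
        p = lmfit.Parameters()
        p.add("baseline", value=0.0, vary=fit_baseline)
        if fixed_amplitudes is not None:
            p.add("amp_scale", value=1.0, min=1e-6)
        for i, (a0, z0, vh0) in enumerate(starts):
            if fixed_amplitudes is not None:
                p.add(f"a{i}", expr=f"{float(fixed_amplitudes[i])!r} * amp_scale")
            else:
                p.add(f"a{i}", value=a0, min=1e-6)
            p.add(f"z{i}", value=z0, min=0.05, max=12.0)
            p.add(f"vh{i}", value=vh0, min=vspan[0] - 150.0, max=vspan[1] + 150.0)
        return p

    def residual(p):
        model = np.full_like(yy, p["baseline"].value)
        for i in range(components):
            model = model + p[f"a{i}"].value * _boltzmann(
                v, p[f"z{i}"].value, p[f"vh{i}"].value, constants
            )
        return model - yy

    amp0 = max(yy.max() - yy.min(), 0.1)
    if components == 1:
        vh_guess = float(v[np.argmin(np.abs(yy - 0.5 * (yy.min() + yy.max())))])
        starts_list = [
            [(amp0, z0, vh_guess)] for z0 in (0.5, 1.5, 3.0)
        ]
    else:
        lo, hi = vspan[0] + 0.25 * (vspan[1] - vspan[0]), vspan[0] + 0.75 * (vspan[1] - vspan[0])
        starts_list = [
            [(amp0 * 0.5, z1, vh1), (amp0 * 0.5, z2, vh2)]
            for z1, z2 in ((1.0, 1.0), (2.5, 1.0))
            for vh1, vh2 in ((lo, hi), (lo - 20, hi + 20), (lo, hi + 40), (lo - 40, hi))
        ]

    best = None
    for starts in starts_list:
        try:
            res = lmfit.minimize(residual, make_params(starts), method="leastsq")
        except Exception:
            continue
        if not np.isfinite(res.chisqr):
            continue
        if best is None or res.chisqr < best.chisqr - 1e-15:
            best = res
        elif abs(res.chisqr - best.chisqr) <= 1e-15:
            # tie-break: lower main-component V1/2
            vh_new = min(res.params[f"vh{i}"].value for i in range(components))
            vh_old = min(best.params[f"vh{i}"].value for i in range(components))
            if vh_new < vh_old:
                best = res
    if best is None:
        raise RuntimeError("Boltzmann fit failed to converge from every start")

    comps = []
    for i in range(components):
        p = best.params
        comps.append(
            BoltzmannComponent(
                amplitude=float(p[f"a{i}"].value),
                z=float(p[f"z{i}"].value),
                v_half_mv=float(p[f"vh{i}"].value),
                amplitude_stderr=_stderr(p[f"a{i}"]),
                z_stderr=_stderr(p[f"z{i}"]),
                v_half_stderr=_stderr(p[f"vh{i}"]),
            )
        )
    comps.sort(key=lambda c: c.v_half_mv)
    return BoltzmannFit(
        components=comps,
        residual_norm=float(np.sqrt(best.chisqr)),
        n_components=components,
        baseline=float(best.params["baseline"].value),
    )


def _stderr(param) -> Optional[float]:
    return float(param.stderr) if param.stderr is not None else None


# ---------------------------------------------------------------------------
# exponential kinetics
# ---------------------------------------------------------------------------

def fit_exponentials(
    times_ms: Sequence[float],
    y: Sequence[float],
    components: int = 1,
    kind: str = "onset",
) -> ExponentialFit:
    """Single or bi-exponential fit of a trace segment.

    Onset form: y = y0 + sum_i a_i (1 - exp(-t/tau_i)); decay form:
    y = y0 + sum_i a_i exp(-t/tau_i).  Times are offsets from the segment
    start (the pulse onset or tail step).  Components are returned fast
    first.  A fit whose total amplitude is negligible against the data
    scale is flagged degenerate; a tau longer than the segment is flagged.
    """
    t = np.asarray(times_ms, dtype=float)
    t = t - t[0]
    yy = np.asarray(y, dtype=float)
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    if len(t) < 10 * components:
        raise ValueError("too few samples for the requested component count")
    if kind not in ("onset", "decay"):
        raise ValueError("kind must be 'onset' or 'decay'")

    span = t[-1]
    data_scale = max(np.ptp(yy), abs(yy).max(), 1e-30)

    def residual(p):
        model = np.full_like(yy, p["y0"].value)
        for i in range(components):
            a, tau = p[f"a{i}"].value, p[f"tau{i}"].value
            if kind == "onset":
                model = model + a * (1.0 - np.exp(-t / tau))
            else:
                model = model + a * np.exp(-t / tau)
        return model - yy

    amp_guess = (yy[-1] - yy[0]) if kind == "onset" else (yy[0] - yy[-1])
    if components == 1:
        tau_starts = [[span / 10], [span / 3], [span]]
    else:
        tau_starts = [
            [span / 50, span / 2],
            [span / 20, span],
            [span / 100, span / 5],
            [span / 10, span * 2],
        ]

    best = None
    for taus in tau_starts:
        p = lmfit.Parameters()
        p.add("y0", value=float(yy[0]))
        for i, tau0 in enumerate(taus):
            p.add(f"a{i}", value=float(amp_guess) / components if amp_guess != 0 else data_scale / components)
            p.add(f"tau{i}", value=float(tau0), min=1e-6)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if np.isfinite(res.chisqr) and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("exponential fit failed to converge from every start")

    comps = sorted(
        (
            ExponentialComponent(
                amplitude=float(best.params[f"a{i}"].value),
                tau_ms=float(best.params[f"tau{i}"].value),
            )
            for i in range(components)
        ),
        key=lambda c: c.tau_ms,
    )
    total_amp = sum(abs(c.amplitude) for c in comps)
    return ExponentialFit(
        components=comps,
        y0=float(best.params["y0"].value),
        residual_norm=float(np.sqrt(best.chisqr)),
        n_components=components,
        kind=kind,
        degenerate=bool(total_amp < 1e-6 * data_scale),
        tau_exceeds_segment=bool(any(c.tau_ms > span for c in comps)),
    )


def compare_exponential_models(
    times_ms: Sequence[float], y: Sequence[float], kind: str = "onset", alpha: float = 0.01
) -> Tuple[ExponentialFit, ExponentialFit, float, bool]:
    """F-test comparison of mono vs bi-exponential fits.

    Returns (mono fit, bi fit, p-value, bi_preferred).  The bi-exponential
    model is preferred when the extra-sum-of-squares F-test rejects the
    mono model at level `alpha`.
    """
    mono = fit_exponentials(times_ms, y, 1, kind)
    bi = fit_exponentials(times_ms, y, 2, kind)
    n = len(times_ms)
    rss1, rss2 = mono.residual_norm**2, bi.residual_norm**2
    df1, df2 = n - 3, n - 5
    if rss2 <= 0 or df2 <= 0:
        return mono, bi, 0.0, True
    f = ((rss1 - rss2) / (df1 - df2)) / (rss2 / df2)
    p = float(stats.f.sf(max(f, 0.0), df1 - df2, df2))
    return mono, bi, p, bool(p < alpha)


# ---------------------------------------------------------------------------
# permeability ratio
# ---------------------------------------------------------------------------

def permeability_ratio(
    rec_k: Recording,
    rec_rb: Recording,
    tail_start_ms: float,
    window_ms: Tuple[float, float] = DEFAULT_TAIL_WINDOW_MS,
) -> PermeabilityResult:
    """Rb+/K+ tail-amplitude ratio from a matched pair of recordings.

    Both recordings must share the voltage protocol; the ratio of the
    extrapolated instantaneous tail amplitudes (Rb over K) is the
    operational permeability ratio.
    """
    if len(rec_k.times_ms) != len(rec_rb.times_ms) or np.any(
        np.abs(rec_k.voltage_mv - rec_rb.voltage_mv) > 1e-6
    ):
        raise ValueError("recordings do not share a voltage protocol")
    fit_k = tail_amplitude(rec_k, tail_start_ms, window_ms)
    fit_rb = tail_amplitude(rec_rb, tail_start_ms, window_ms)
    if abs(fit_k.amplitude) < 1e-12:
        raise ValueError("K+ tail amplitude is (near) zero; ratio undefined")
    ratio = fit_rb.amplitude / fit_k.amplitude
    unc = None
    if fit_k.converged and fit_rb.converged and np.isfinite(fit_k.residual_norm):
        nk = max(np.sqrt(len(rec_k.times_ms)), 1.0)
        rel = np.hypot(
            fit_k.residual_norm / (abs(fit_k.amplitude) * nk),
            fit_rb.residual_norm / (abs(fit_rb.amplitude) * nk),
        )
        unc = abs(ratio) * rel
    return PermeabilityResult(
        tail_amplitude_k=fit_k.amplitude,
        tail_amplitude_rb=fit_rb.amplitude,
        ratio_rb_over_k=ratio,
        uncertainty=unc,
    )


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def fraction_inhibited_timeseries(rec_ctl: Recording, rec_drug: Recording) -> np.ndarray:
    """1 - I_drug(t)/I_ctl(t) on the shared time grid (NaN where I_ctl ~ 0)."""
    if len(rec_ctl.times_ms) != len(rec_drug.times_ms):
        raise ValueError("recordings do not share a time grid")
    ictl = np.asarray(rec_ctl.current, dtype=float)
    scale = np.abs(ictl).max()
    out = np.full_like(ictl, np.nan)
    ok = np.abs(ictl) > 1e-6 * max(scale, 1e-30)
    out[ok] = 1.0 - np.asarray(rec_drug.current, dtype=float)[ok] / ictl[ok]
    return out


def dose_response(
    concentrations_um: Sequence[float],
    fractions_inhibited: Sequence[float],
) -> DoseResponseFit:
    """Hill fit (coefficient fixed at 1) of fraction inhibited vs concentration.

    f(c) = f_max * c / (c + IC50).
    """
    c = np.asarray(concentrations_um, dtype=float)
    f = np.asarray(fractions_inhibited, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any((f < -0.05) | (f > 1.05)):
        raise ValueError("fractions inhibited must lie in [0, 1]")
    if np.allclose(f, 0.0):
        raise ValueError("all-zero inhibition; IC50 undefined")

    def residual(p):
        return p["f_max"] * c / (c + p["ic50"]) - f

    params = lmfit.Parameters()
    params.add("f_max", value=min(max(f.max(), 0.1), 1.0), min=0.0, max=1.0)
    params.add("ic50", value=float(np.median(c)), min=1e-9)
    res = lmfit.minimize(residual, params, method="leastsq")
    if not res.success:
        raise RuntimeError("dose-response fit failed to converge")
    return DoseResponseFit(
        ic50_um=float(res.params["ic50"].value),
        hill_n=1.0,
        f_max=float(res.params["f_max"].value),
        residual_norm=float(np.sqrt(res.chisqr)),
        ic50_stderr=_stderr(res.params["ic50"]),
    )
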