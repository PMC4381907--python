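"""Seeded synthetic voltage-clamp-fluorometry experiments.

Emulates two-electrode voltage clamp with simultaneous fluorometry:
step protocols from a -80 mV holding potential, current sampled at 1 kHz,
fluorescence low-pass filtered at 200 Hz, additive Gaussian noise on both
channels, plus ion-substitution (K+/Rb+/Na+) tail experiments and XE991
dose-inhibition series.  Every stochastic output is a pure function of
(parameters, protocol, acquisition spec) including the mandatory seed, and
each experiment ships a ground-truth manifest listing every generating
value a downstream analysis should recover.

What is emulated: acquisition noise, analog low-pass filtering (as a
zero-phase digital filter), linear fluorescence baseline drift
(photobleaching), slow phenomenological drug block.  What is not: leak and
capacitive currents, series resistance, endogenous conductances, labelling
efficiency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .params import GatingParameters
from .protocols import VoltageProtocol, preset_protocol
from .recording import Recording
from .simulate import simulate_protocol, observables

DEFAULT_TEST_VOLTAGES = tuple(float(v) for v in range(-120, 101, 20))
DEFAULT_XE991_CONCENTRATIONS_UM = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition characteristics of the emulated rig.

    Noise standard deviations are fractions of the trace's full scale
    (max |I| for current; max dF for fluorescence).  The fluorescence
    channel is low-pass filtered (zero-phase, 2nd-order Butterworth)
    before noise is added; a cutoff at or above Nyquist disables the
    filter.  The seed is mandatory for any stochastic output.
    """

    sample_rate_hz: float = 1000.0
    fluor_cutoff_hz: float = 200.0
    current_noise_sd: float = 0.01
    fluor_noise_sd: float = 0.02
    seed: int = 0
    prepulse_ms: float = 2000.0  # holding-potential baseline window
    dff_scale: float = 0.05  # full-scale dF/F of the label
    fluor_base: float = 1000.0  # baseline photocurrent, arbitrary units
    bleach_per_s: float = -0.005  # fractional baseline slope per second

    def __post_init__(self) -> None:
        if self.fluor_cutoff_hz > self.sample_rate_hz / 2 + 1e-9:
            raise ValueError("fluorescence cutoff exceeds Nyquist frequency")
        if self.current_noise_sd < 0 or self.fluor_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def replace(self, **kw) -> "AcquisitionSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ExperimentDesign:
    """A named experiment family and its settings.

    kinds: "vcf_family" (one recording per test voltage), "permeability"
    (matched K+/Rb+ pair), "dose_response" (control plus one recording per
    XE991 concentration), "kcne1_pair" (baseline and theta-perturbed
    VCF families).
    """

    kind: str
    test_voltages_mv: Tuple[float, ...] = DEFAULT_TEST_VOLTAGES
    g_ratio_rb_k: float = 0.7
    concentrations_um: Tuple[float, ...] = DEFAULT_XE991_CONCENTRATIONS_UM
    ic50_um: float = 2.0
    f_max: float = 0.9
    tau_block_ms: float = 500.0
    theta_ic_factor: float = 20.0
    theta_ao_factor: float = 5.0

    def __post_init__(self) -> None:
        kinds = ("vcf_family", "permeability", "dose_response", "kcne1_pair")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "dose_response":
            if len(self.concentrations_um) < 3:
                raise ValueError("dose_response needs at least 3 concentrations")
            if any(c <= 0 for c in self.concentrations_um):
                raise ValueError("concentrations must be strictly positive")
            if not (self.ic50_um > 0 and 0 < self.f_max <= 1):
                raise ValueError("invalid dose-response ground truth")
        if self.kind == "vcf_family" and len(self.test_voltages_mv) == 0:
            raise ValueError("vcf_family needs test voltages")
        if self.kind == "permeability" and self.g_ratio_rb_k <= 0:
            raise ValueError("conductance ratio must be positive")
        if self.kind == "kcne1_pair" and not (
            self.theta_ic_factor > 0 and self.theta_ao_factor > 0
        ):
            raise ValueError("theta factors must be positive")


def _child_seed(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_recording(
    params: GatingParameters,
    protocol: VoltageProtocol,
    acq: AcquisitionSpec,
    ion: str = "K",
    rng: Optional[np.random.Generator] = None,
    extra_meta: Optional[dict] = None,
    current_scale: Optional[np.ndarray] = None,
) -> Recording:
    """One synthetic sweep: noiseless simulation + filtering + noise.

    A holding-potential pre-pulse of `acq.prepulse_ms` is prepended to the
    protocol to provide the fluorescence-baseline window.  The raw
    fluorescence channel is baseline(t) * (1 + dff_scale * F_model(t)) with
    a linear (bleaching) baseline, mimicking what a photodiode reports.
    `current_scale`, if given, multiplies the noiseless current sample-wise
    (used for phenomenological drug block).
    """
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    dt_ms = 1000.0 / acq.sample_rate_hz
    full = protocol.with_prepulse(acq.prepulse_ms) if acq.prepulse_ms > 0 else protocol
    if abs(full.sample_interval_ms - dt_ms) > 1e-12:
        full = VoltageProtocol(full.segments, dt_ms, full.holding_voltage_mv)
    traj = simulate_protocol(params, full)
    obs = observables(traj, params, ion=ion)

    current = obs.current.copy()
    if current_scale is not None:
        current = current * np.asarray(current_scale, dtype=float)

    base = acq.fluor_base * (1.0 + acq.bleach_per_s * traj.times_ms / 1000.0)
    fluor = base * (1.0 + acq.dff_scale * obs.fluorescence_raw)
    if acq.fluor_cutoff_hz < acq.sample_rate_hz / 2 - 1e-9:
        b, a = butter(2, acq.fluor_cutoff_hz / (acq.sample_rate_hz / 2))
        fluor = filtfilt(b, a, fluor)

    i_scale = np.abs(current).max()
    f_scale = acq.dff_scale * acq.fluor_base * max(obs.fluorescence_raw.max(), 1e-30)
    if acq.current_noise_sd > 0:
        current = current + rng.normal(0.0, acq.current_noise_sd * max(i_scale, 1e-30), current.shape)
    if acq.fluor_noise_sd > 0:
        fluor = fluor + rng.normal(0.0, acq.fluor_noise_sd * f_scale, fluor.shape)

    seg_edges = np.cumsum([0.0] + [d for d, _ in full.segments])
    meta = {
        "ion": ion,
        "seed": int(acq.seed),
        "sample_rate_hz": acq.sample_rate_hz,
        "params_digest": params.digest(),
        "prepulse_ms": acq.prepulse_ms,
        "pulse_start_ms": float(seg_edges[1]) if acq.prepulse_ms > 0 else 0.0,
        "segments": [list(s) for s in full.segments],
        "drug_concentration_um": 0.0,
        "dff_scale": acq.dff_scale,
    }
    if extra_meta:
        meta.update(extra_meta)
    return Recording(
        times_ms=traj.times_ms,
        voltage_mv=obs.voltage_mv,
        current=current,
        fluorescence=fluor,
        meta=meta,
    )


def _block_time_course(
    times_ms: np.ndarray, onset_ms: float, fraction: float, tau_block_ms: float
) -> np.ndarray:
    """Multiplicative current scale for slowly developing drug block."""
    scale = np.ones_like(times_ms, dtype=float)
    after = times_ms >= onset_ms
    dt = times_ms[after] - onset_ms
    scale[after] = 1.0 - fraction * (1.0 - np.exp(-dt / tau_block_ms))
    return scale


def generate_experiment(
    design: ExperimentDesign,
    params: GatingParameters,
    acq: AcquisitionSpec,
) -> Tuple[Dict[str, Recording], dict]:
    """Generate the full recording family for a design plus its manifest.

    The manifest lists every generating value an analysis stage should
    recover (test voltages, conductance ratios, IC50/f_max/tau of the
    emulated block, theta perturbation factors, parameter digests).
    """
    recs: Dict[str, Recording] = {}
    manifest: dict = {
        "kind": design.kind,
        "seed": int(acq.seed),
        "params_digest": params.digest(),
    }

    if design.kind == "vcf_family":
        protocol = preset_protocol("vcf_family")
        for i, v in enumerate(design.test_voltages_mv):
            rng = _child_seed(acq.seed, i)
            recs[f"vcf_{v:+.0f}mV"] = generate_recording(
                params,
                preset_protocol("vcf_family", test_mv=v),
                acq,
                rng=rng,
                extra_meta={"test_voltage_mv": v},
            )
        manifest.update(
            test_voltages_mv=list(design.test_voltages_mv),
            pulse_ms=4000.0,
            tail_voltage_mv=60.0,
        )

    elif design.kind == "permeability":
        protocol = preset_protocol("permeability")
        ratio = design.g_ratio_rb_k
        g_k = params.ions["K"].g
        ions = dict(params.ions)
        ions["Rb"] = dataclasses.replace(ions["Rb"], g=g_k * ratio)
        p2 = params.replace(ions=ions)
        recs["K"] = generate_recording(
            p2, protocol, acq, ion="K", rng=_child_seed(acq.seed, 0),
            extra_meta={"test_voltage_mv": 60.0},
        )
        recs["Rb"] = generate_recording(
            p2, protocol, acq, ion="Rb", rng=_child_seed(acq.seed, 1),
            extra_meta={"test_voltage_mv": 60.0},
        )
        manifest.update(
            g_ratio_rb_k=ratio,
            tail_start_ms=acq.prepulse_ms + 5000.0,
            tail_voltage_mv=-60.0,
        )

    elif design.kind == "dose_response":
        protocol = preset_protocol("xe991")
        ctl = generate_recording(
            params, protocol, acq, rng=_child_seed(acq.seed, 0),
            extra_meta={"test_voltage_mv": 60.0},
        )
        recs["control"] = ctl
        onset = acq.prepulse_ms  # block develops during the depolarizing pulse
        noiseless_times = ctl.times_ms
        fractions_at = {}
        for i, c in enumerate(design.concentrations_um):
            f_c = design.f_max * c / (c + design.ic50_um)
            scale = _block_time_course(noiseless_times, onset, f_c, design.tau_block_ms)
            recs[f"xe991_{c:g}uM"] = generate_recording(
                params, protocol, acq, rng=_child_seed(acq.seed, i + 1),
                extra_meta={"test_voltage_mv": 60.0, "drug_concentration_um": c},
                current_scale=scale,
            )
            fractions_at[f"{c:g}"] = f_c
        manifest.update(
            concentrations_um=list(design.concentrations_um),
            ic50_um=design.ic50_um,
            f_max=design.f_max,
            tau_block_ms=design.tau_block_ms,
            pulse_start_ms=onset,
            asymptotic_fractions=fractions_at,
        )

    elif design.kind == "kcne1_pair":
        from .kcne1 import Perturbation, apply_perturbation

        pert = Perturbation(
            theta_ic_factor=design.theta_ic_factor,
            theta_ao_factor=design.theta_ao_factor,
        )
        perturbed = apply_perturbation(params, pert)
        for label, pset, base_key in (("baseline", params, 0), ("perturbed", perturbed, 1)):
            for i, v in enumerate(design.test_voltages_mv):
                rng = _child_seed(acq.seed, base_key, i)
                recs[f"{label}_{v:+.0f}mV"] = generate_recording(
                    pset,
                    preset_protocol("vcf_family", test_mv=v),
                    acq,
                    rng=rng,
                    extra_meta={"test_voltage_mv": v, "condition": label},
                )
        manifest.update(
            test_voltages_mv=list(design.test_voltages_mv),
            theta_ic_factor=design.theta_ic_factor,
            theta_ao_factor=design.theta_ao_factor,
            perturbed_digest=perturbed.digest(),
            pulse_ms=4000.0,
            tail_voltage_mv=60.0,
        )

    return recs, manifest


def write_experiment(recs: Dict[str, Recording], manifest: dict, outdir) -> None:
    """Write an experiment as per-recording CSVs plus manifest.json."""
    import json
    from pathlib import Path

    from .recording import write_recording_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rec in recs.items():
        write_recording_csv(rec, out / f"{name}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
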