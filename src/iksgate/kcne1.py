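"""In-silico KCNE1 experiment.

KCNE1 is represented purely as a perturbation of two VSD-pore coupling
strengths: strengthening the intermediate-closed interaction (theta_IC,
which keeps the pore shut while VSDs sit in the intermediate state) and
strengthening the activated-open interaction (theta_AO, which stabilizes
the conducting state once VSDs are fully activated).  All intrinsic k
parameters are untouched.

The module quantifies the resulting gating signatures against the baseline
model (GV right-shift, reassignment of the GV to the high-voltage FV
component, delayed current onset, increased maximal current, left-shifted
low-voltage FV component) and fits theta factors back from GV/FV tables to
show the two-parameter change is identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .analysis import fit_boltzmann, BoltzmannFit
from .params import GatingParameters, THETA_KEYS
from .simulate import simulate_protocol, observables, steady_state_curves
from .protocols import VoltageProtocol

DEFAULT_SIGNATURE_VOLTAGES = tuple(float(v) for v in range(-120, 101, 20))
AMBIGUITY_MV = 2.0  # nearest-V1/2 assignments closer than this are flagged


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative factors on coupling strengths.

    The canonical KCNE1 perturbation touches only theta_IC and theta_AO
    (both strengthened).  Arbitrary extra factors can be supplied for
    counterfactual experiments such as weakening theta_IO.
    """

    theta_ic_factor: float = 1.0
    theta_ao_factor: float = 1.0
    other_factors: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for name, val in self.factors().items():
            if not (val > 0):
                raise ValueError(f"factor on {name} must be positive, got {val}")
            if name not in THETA_KEYS:
                raise ValueError(f"unknown coupling parameter {name!r}")

    def factors(self) -> Dict[str, float]:
        f = {"theta_ic": self.theta_ic_factor, "theta_ao": self.theta_ao_factor}
        for name, val in self.other_factors:
            f[name] = f.get(name, 1.0) * val
        return f

    def compose(self, other: "Perturbation") -> "Perturbation":
        mine, theirs = self.factors(), other.factors()
        combined = {k: mine.get(k, 1.0) * theirs.get(k, 1.0) for k in set(mine) | set(theirs)}
        ic = combined.pop("theta_ic", 1.0)
        ao = combined.pop("theta_ao", 1.0)
        return Perturbation(ic, ao, tuple(sorted(combined.items())))


def apply_perturbation(params: GatingParameters, pert: Perturbation) -> GatingParameters:
    """Return a parameter set with theta factors applied; all k unchanged."""
    changes = {
        name: getattr(params, name) * factor
        for name, factor in pert.factors().items()
        if factor != 1.0
    }
    return params.replace(**changes) if changes else params


def kcne1_default_perturbation() -> Perturbation:
    """Canonical KCNE1 perturbation: theta_IC x20, theta_AO x5."""
    return Perturbation(theta_ic_factor=20.0, theta_ao_factor=5.0)


def theta_io_weakening_alternative(factor: float = 20.0, theta_ao_factor: float = 5.0) -> Perturbation:
    """Counterfactual: weaken theta_IO instead of strengthening theta_IC.

    Decouples opening from the first VSD step just as the canonical
    perturbation does (the open/closed bias of an intermediate-state VSD is
    theta_IO/theta_IC, so dividing theta_IO mirrors multiplying theta_IC),
    but leaves the closed-state stabilities untouched and therefore cannot
    left-shift the low-voltage FV component.
    """
    return Perturbation(
        theta_ic_factor=1.0,
        theta_ao_factor=theta_ao_factor,
        other_factors=(("theta_io", 1.0 / factor),),
    )


# ---------------------------------------------------------------------------
# signature report
# ---------------------------------------------------------------------------

@dataclass
class SignatureReport:
    """Quantified gating signatures of a perturbation vs its baseline."""

    gv_v_half_baseline_mv: float
    gv_v_half_perturbed_mv: float
    delta_gv_v_half_mv: float
    f_main_v_half_baseline_mv: float
    f_main_v_half_perturbed_mv: float
    delta_f_main_v_half_mv: float
    f_high_v_half_baseline_mv: float
    f_high_v_half_perturbed_mv: float
    gv_assignment_baseline: str  # "main" | "high"
    gv_assignment_perturbed: str
    assignment_ambiguous_baseline: bool
    assignment_ambiguous_perturbed: bool
    onset_delay_baseline_ms: float
    onset_delay_perturbed_ms: float
    max_current_fold_change: float
    flags: Dict[str, bool] = field(default_factory=dict)
    gv_fv_tables: Optional[Dict[str, pd.DataFrame]] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "gv_fv_tables"}
        return d


def _assign_gv_to_fv(gv_vhalf: float, fv_fit: BoltzmannFit) -> Tuple[str, bool]:
    d_main = abs(gv_vhalf - fv_fit.main.v_half_mv)
    d_high = abs(gv_vhalf - fv_fit.high.v_half_mv)
    assignment = "main" if d_main <= d_high else "high"
    return assignment, bool(abs(d_main - d_high) < AMBIGUITY_MV)


def onset_delay(
    params: GatingParameters,
    test_mv: float = 40.0,
    pulse_ms: float = 4000.0,
    fraction: float = 0.1,
    sample_interval_ms: float = 1.0,
) -> float:
    """Time (ms) for the current to reach `fraction` of its end-of-pulse value."""
    protocol = VoltageProtocol([(pulse_ms, test_mv)], sample_interval_ms=sample_interval_ms)
    traj = simulate_protocol(params, protocol)
    obs = observables(traj, params)
    i_end = obs.current[-1]
    if abs(i_end) < 1e-30:
        return float("nan")
    rel = obs.current / i_end
    above = np.nonzero(rel >= fraction)[0]
    if len(above) == 0:
        return float(pulse_ms)
    return float(traj.times_ms[above[0]])


def signature_report(
    baseline: GatingParameters,
    perturbed: GatingParameters,
    test_voltages_mv: Sequence[float] = DEFAULT_SIGNATURE_VOLTAGES,
    tail_voltage_mv: float = 60.0,
    pulse_duration_ms: float = 4000.0,
    delay_test_mv: float = 40.0,
    shift_threshold_mv: float = 2.0,
    keep_tables: bool = False,
) -> SignatureReport:
    """Quantify the gating signatures of `perturbed` relative to `baseline`.

    GV and FV curves come from simulated test-pulse families
    (steady_state_curves); GV is fit with one Boltzmann and FV with the sum
    of two.  Each qualitative flag is true iff the directional signature
    holds beyond `shift_threshold_mv` (or, for delay and amplitude, beyond
    trivial numerical slack).
    """
    tables: Dict[str, pd.DataFrame] = {}
    fits: Dict[str, Dict[str, BoltzmannFit]] = {}
    for label, pset in (("baseline", baseline), ("perturbed", perturbed)):
        df = steady_state_curves(
            pset, list(test_voltages_mv), tail_voltage_mv, pulse_duration_ms
        )
        tables[label] = df
        # the FV amplitude split is structural: the first VSD step carries
        # f_i of the per-VSD signal and the second f_a - f_i
        fv_split = (pset.f_i / pset.f_a, (pset.f_a - pset.f_i) / pset.f_a)
        fits[label] = {
            "gv": fit_boltzmann(df["voltage_mV"], df["gv_norm"], components=1),
            # free baseline: dF/F is referenced to the holding potential, so
            # curves can sit below zero at hyperpolarized steps
            "fv": fit_boltzmann(
                df["voltage_mV"], df["fv_norm"], components=2,
                fixed_amplitudes=fv_split, fit_baseline=True,
            ),
        }

    gv_b = fits["baseline"]["gv"].components[0].v_half_mv
    gv_p = fits["perturbed"]["gv"].components[0].v_half_mv
    fv_b, fv_p = fits["baseline"]["fv"], fits["perturbed"]["fv"]
    assign_b, amb_b = _assign_gv_to_fv(gv_b, fv_b)
    assign_p, amb_p = _assign_gv_to_fv(gv_p, fv_p)

    delay_b = onset_delay(baseline, delay_test_mv, pulse_duration_ms)
    delay_p = onset_delay(perturbed, delay_test_mv, pulse_duration_ms)

    # maximal steady-state current over the voltage family (driving force at
    # each test voltage, not the tail): N g P_open (V - E_rev)
    def max_current(df, pset):
        ic = pset.ions["K"]
        i = pset.n_channels * ic.g * df["p_open_end"] * (df["voltage_mV"] - ic.e_rev_mv)
        return float(i.abs().max())

    fold = max_current(tables["perturbed"], perturbed) / max_current(
        tables["baseline"], baseline
    )

    d_gv = gv_p - gv_b
    d_fmain = fv_p.main.v_half_mv - fv_b.main.v_half_mv
    flags = {
        "gv_right_shift": bool(d_gv > shift_threshold_mv),
        "gv_reassigned_to_high": bool(assign_b == "main" and assign_p == "high"),
        "onset_delay_increase": bool(delay_p > delay_b + 1.0),
        "max_current_fold_change_gt_1": bool(fold > 1.05),
        "f_main_left_shift": bool(d_fmain < -shift_threshold_mv),
    }

    return SignatureReport(
        gv_v_half_baseline_mv=gv_b,
        gv_v_half_perturbed_mv=gv_p,
        delta_gv_v_half_mv=d_gv,
        f_main_v_half_baseline_mv=fv_b.main.v_half_mv,
        f_main_v_half_perturbed_mv=fv_p.main.v_half_mv,
        delta_f_main_v_half_mv=d_fmain,
        f_high_v_half_baseline_mv=fv_b.high.v_half_mv,
        f_high_v_half_perturbed_mv=fv_p.high.v_half_mv,
        gv_assignment_baseline=assign_b,
        gv_assignment_perturbed=assign_p,
        assignment_ambiguous_baseline=amb_b,
        assignment_ambiguous_perturbed=amb_p,
        onset_delay_baseline_ms=delay_b,
        onset_delay_perturbed_ms=delay_p,
        max_current_fold_change=fold,
        flags=flags,
        gv_fv_tables=tables if keep_tables else None,
    )


# ---------------------------------------------------------------------------
# theta-factor recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    factors: Dict[str, float]
    stderr: Dict[str, Optional[float]]
    residual_norm: float
    identifiable: bool
    n_evaluations: int


def recover_perturbation(
    gv_table: pd.DataFrame,
    fv_table: pd.DataFrame,
    baseline: GatingParameters,
    free: Sequence[str] = ("theta_ic", "theta_ao"),
    tail_voltage_mv: float = 60.0,
    pulse_duration_ms: float = 4000.0,
) -> RecoveryResult:
    """Fit multiplicative theta factors to normalized GV/FV tables.

    All k parameters stay fixed at the baseline values; only the named
    theta factors vary (in log space, so positivity is structural).
    Standard errors come from the residual curvature (J^T J); a flat
    direction (tiny singular value of J) marks the configuration
    non-identifiable rather than silently returning a point estimate.

    `gv_table` needs columns voltage_mV and gv_norm; `fv_table` needs
    voltage_mV and fv_norm.  If the GV table also carries raw tail
    amplitudes (gv_raw, in the simulator's current units), those are fit
    instead of the normalized curve: with channel count and conductance
    fixed, the absolute amplitude carries the information about
    open-state stabilization (theta_AO) that normalization discards.
    """
    free = list(free)
    for name in free:
        if name not in THETA_KEYS:
            raise ValueError(f"unknown coupling parameter {name!r}")
    gv_v = gv_table["voltage_mV"].to_numpy(dtype=float)
    use_raw = "gv_raw" in gv_table.columns
    gv_col = "gv_raw" if use_raw else "gv_norm"
    gv_y = gv_table[gv_col].to_numpy(dtype=float)
    gv_scale = np.abs(gv_y).max() if use_raw else 1.0
    fv_v = fv_table["voltage_mV"].to_numpy(dtype=float)
    fv_y = fv_table["fv_norm"].to_numpy(dtype=float)
    voltages = sorted(set(gv_v) | set(fv_v))
    n_eval = 0

    def predict(log_factors: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        changes = {
            name: getattr(baseline, name) * float(np.exp(lf))
            for name, lf in zip(free, log_factors)
        }
        pset = baseline.replace(**changes)
        df = steady_state_curves(pset, voltages, tail_voltage_mv, pulse_duration_ms)
        df = df.set_index("voltage_mV")
        gv_model = df.loc[gv_v, gv_col].to_numpy()
        fv_model = df.loc[fv_v, "fv_norm"].to_numpy()
        return np.concatenate([(gv_model - gv_y) / gv_scale, fv_model - fv_y])

    bound = np.log(1e3)
    res = least_squares(
        predict, x0=np.zeros(len(free)), method="trf",
        bounds=(-bound, bound), xtol=1e-12, gtol=1e-12,
    )
    J = res.jac
    sv = np.linalg.svd(J, compute_uv=False)
    identifiable = bool(sv.min() > 1e-6 * max(sv.max(), 1e-30))
    stderr: Dict[str, Optional[float]] = {}
    dof = max(len(res.fun) - len(free), 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        diag = [None] * len(free)
    factors = {}
    for i, name in enumerate(free):
        f = float(np.exp(res.x[i]))
        factors[name] = f
        stderr[name] = float(f * diag[i]) if diag[i] is not None else None
    return RecoveryResult(
        factors=factors,
        stderr=stderr,
        residual_norm=float(np.linalg.norm(res.fun)),
        identifiable=identifiable,
        n_evaluations=n_eval,
    )
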