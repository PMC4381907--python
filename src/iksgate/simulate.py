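"""Master-equation integration under voltage-clamp protocols.

Within each constant-voltage segment the occupancy evolves as
p(t) = p(t0) expm(Q(V) (t - t0)); the propagation is exact (no time-step
error) via eigendecomposition of Q, with a scaling-and-squaring fallback
when the eigenvector matrix is badly conditioned.  Segments chain
continuously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .params import GatingParameters
from .protocols import VoltageProtocol
from .ratematrix import build_rate_matrix, equilibrium_distribution
from .states import ChannelState, enumerate_states

_EIG_COND_LIMIT = 1e10


@dataclass(frozen=True)
class OccupancyTrajectory:
    """State occupancies over time: times (ms), occupancy (time x 30), protocol."""

    times_ms: np.ndarray
    occupancy: np.ndarray
    protocol: VoltageProtocol

    @property
    def voltage_mv(self) -> np.ndarray:
        return self.protocol.voltage_at(self.times_ms)


@dataclass(frozen=True)
class ObservableTraces:
    """Macroscopic observables of a trajectory.

    current = N * g_ion * P_open * (V - E_rev); fluorescence is the
    occupancy-weighted mean per-VSD signal (n_I f_I + n_A f_A)/4, reported
    raw and normalized to its maximum over the trace.
    """

    times_ms: np.ndarray
    voltage_mv: np.ndarray
    open_probability: np.ndarray
    current: np.ndarray
    fluorescence_raw: np.ndarray
    fluorescence_rel: np.ndarray
    ion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "voltage_mV": self.voltage_mv,
                "p_open": self.open_probability,
                "current": self.current,
                "dF_F_raw": self.fluorescence_raw,
                "dF_F_norm": self.fluorescence_rel,
            }
        )


def _propagate_segment(Q: np.ndarray, p0: np.ndarray, dts_s: np.ndarray) -> np.ndarray:
    """Occupancies at offsets dts_s (s) from segment start, exact in time."""
    try:
        lam, U = np.linalg.eig(Q.T)
        if np.linalg.cond(U) > _EIG_COND_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned eigenvectors")
        c = np.linalg.solve(U, p0.astype(complex))
        # p(t)^T = U diag(exp(lam t)) U^-1 p0^T
        ev = np.exp(np.outer(dts_s, lam)) * c  # (nt, n)
        return np.real(ev @ U.T)
    except np.linalg.LinAlgError:
        # uniform-grid fallback: one expm per distinct step, iterated
        out = np.empty((len(dts_s), len(p0)))
        prev_t = 0.0
        p = p0.copy()
        for i, t in enumerate(dts_s):
            dt = t - prev_t
            if dt > 0:
                p = p @ expm(Q * dt)
            out[i] = p
            prev_t = t
        return out


def simulate_protocol(
    params: GatingParameters,
    protocol: VoltageProtocol,
    initial: Union[str, np.ndarray] = "equilibrium-at-holding",
) -> OccupancyTrajectory:
    """Integrate the master equation over a piecewise-constant protocol.

    `initial` is either the string "equilibrium-at-holding" or an explicit
    probability vector over the canonical 30-state order.
    """
    n_states = len(enumerate_states())
    if isinstance(initial, str):
        if initial != "equilibrium-at-holding":
            raise ValueError(f"unknown initial condition {initial!r}")
        p0 = equilibrium_distribution(params, protocol.holding_voltage_mv)
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (n_states,) or abs(p0.sum() - 1.0) > 1e-8 or (p0 < -1e-12).any():
            raise ValueError("initial occupancy must be a probability vector over 30 states")

    dt = protocol.sample_interval_ms
    times = protocol.times_ms()
    occ = np.empty((len(times), n_states))
    occ[0] = p0
    p = p0
    seg_start = 0.0
    row = 1
    for dur_ms, v_mv in protocol.segments:
        Q = build_rate_matrix(params, v_mv)
        n_sub = int(round(dur_ms / dt))
        offsets_s = (np.arange(1, n_sub + 1) * dt) / 1000.0
        seg_occ = _propagate_segment(Q, p, offsets_s)
        if not np.all(np.isfinite(seg_occ)):
            raise FloatingPointError(
                f"non-finite occupancy in segment starting at {seg_start} ms (V={v_mv} mV)"
            )
        occ[row : row + n_sub] = seg_occ
        p = seg_occ[-1]
        row += n_sub
        seg_start += dur_ms
    # clip tiny negative round-off and renormalize
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return OccupancyTrajectory(times_ms=times, occupancy=occ, protocol=protocol)


def observables(
    traj: OccupancyTrajectory, params: GatingParameters, ion: str = "K"
) -> ObservableTraces:
    """Map an occupancy trajectory to open probability, current and fluorescence."""
    if ion not in params.ions:
        raise ValueError(f"unknown ion condition {ion!r}; configured: {sorted(params.ions)}")
    states = enumerate_states()
    open_mask = np.array([s.is_open for s in states], dtype=float)
    fweights = np.array(
        [(s.n_I * params.f_i + s.n_A * params.f_a) / 4.0 for s in states]
    )
    p_open = traj.occupancy @ open_mask
    volt = traj.voltage_mv
    ic = params.ions[ion]
    current = params.n_channels * ic.g * p_open * (volt - ic.e_rev_mv)
    f_raw = traj.occupancy @ fweights
    fmax = f_raw.max()
    f_rel = f_raw / fmax if fmax > 0 else np.zeros_like(f_raw)
    return ObservableTraces(
        times_ms=traj.times_ms,
        voltage_mv=volt,
        open_probability=p_open,
        current=current,
        fluorescence_raw=f_raw,
        fluorescence_rel=f_rel,
        ion=ion,
    )


def steady_state_curves(
    params: GatingParameters,
    test_voltages_mv: List[float],
    tail_voltage_mv: float = 60.0,
    pulse_duration_ms: float = 4000.0,
    ion: str = "K",
    equilibration_rel_tol: float = 1e-4,
    sample_interval_ms: Optional[float] = None,
    holding_voltage_mv: float = -80.0,
) -> pd.DataFrame:
    """GV and FV tables from simulated test-pulse families.

    Per test voltage: the GV point is the instantaneous tail current
    (P_open at pulse end times the tail driving force) and the FV point is
    the end-of-pulse fluorescence referenced to the holding-potential
    equilibrium fluorescence (the model counterpart of a baseline-corrected
    dF/F); both are returned raw and normalized to the highest-voltage
    point.  An `equilibrated` flag records whether P_open changed by less
    than `equilibration_rel_tol` (relative) over the final 5% of the pulse.
    """
    if len(test_voltages_mv) == 0:
        raise ValueError("empty test voltage list")
    ic = params.ions[ion]
    if abs(tail_voltage_mv - ic.e_rev_mv) < 1e-9:
        raise ValueError("tail voltage equals reversal potential: zero driving force")
    if sample_interval_ms is None:
        # coarse internal grid: only pulse-end values and a tail-window check matter
        sample_interval_ms = pulse_duration_ms / 80.0
    rows = []
    states = enumerate_states()
    open_mask = np.array([s.is_open for s in states], dtype=float)
    fweights = np.array(
        [(s.n_I * params.f_i + s.n_A * params.f_a) / 4.0 for s in states]
    )
    f_hold = float(equilibrium_distribution(params, holding_voltage_mv) @ fweights)
    for v in test_voltages_mv:
        protocol = VoltageProtocol(
            [(pulse_duration_ms, v)],
            sample_interval_ms=sample_interval_ms,
            holding_voltage_mv=holding_voltage_mv,
        )
        traj = simulate_protocol(params, protocol)
        p_open = traj.occupancy @ open_mask
        fluor = traj.occupancy @ fweights
        n_last = max(2, int(round(0.05 * (len(p_open) - 1))))
        window = p_open[-n_last:]
        scale = max(abs(window[-1]), 1e-12)
        equilibrated = (window.max() - window.min()) / scale < equilibration_rel_tol
        tail_current = (
            params.n_channels * ic.g * p_open[-1] * (tail_voltage_mv - ic.e_rev_mv)
        )
        rows.append(
            dict(
                voltage_mV=v,
                p_open_end=p_open[-1],
                gv_raw=tail_current,
                fv_raw=fluor[-1] - f_hold,
                equilibrated=bool(equilibrated),
            )
        )
    df = pd.DataFrame(rows)
    ref = df.loc[df["voltage_mV"].idxmax()]
    df["gv_norm"] = df["gv_raw"] / ref["gv_raw"]
    df["fv_norm"] = df["fv_raw"] / ref["fv_raw"]
    return df
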