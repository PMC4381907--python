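"""Brute-force labelled-VSD oracle model.

Independent implementation of the gating scheme that tracks each of the
four VSDs individually: 3^4 VSD configurations x 2 pore states = 162
microstates.  Per-VSD rates carry no multiplicity factors; aggregation is
done only when projecting results onto (pore, counts).  Used as the
cross-check for the aggregated 30-state model; deliberately avoids the
package's rate-matrix and equilibrium code paths.
"""

import math
from itertools import product

import numpy as np
from scipy.linalg import expm

VSD = ("R", "I", "A")


def micro_states():
    """All (pore, (x1,x2,x3,x4)) microstates in a fixed order."""
    return [(pore, cfg) for pore in ("C", "O") for cfg in product(VSD, repeat=4)]


def _rate(law, v_mv, constants):
    x = law.z * constants.F * (v_mv / 1000.0) / (constants.R * constants.T)
    return law.k0 * math.exp(x)


def micro_rate_matrix(params, v_mv):
    """162x162 rate matrix; Q[i, j] is the i->j rate, rows sum to zero."""
    states = micro_states()
    index = {s: i for i, s in enumerate(states)}
    c = params.constants
    k = {
        ("R", "I"): _rate(params.k_ri, v_mv, c),
        ("I", "R"): _rate(params.k_ir, v_mv, c),
        ("I", "A"): _rate(params.k_ia, v_mv, c),
        ("A", "I"): _rate(params.k_ai, v_mv, c),
    }
    n = len(states)
    Q = np.zeros((n, n))
    for i, (pore, cfg) in enumerate(states):
        # single-VSD moves
        for slot in range(4):
            x = cfg[slot]
            for y in VSD:
                if (x, y) in k:
                    target = cfg[:slot] + (y,) + cfg[slot + 1 :]
                    Q[i, index[(pore, target)]] += k[(x, y)] / params.theta(x, pore)
        # pore move
        if pore == "C":
            denom = np.prod([params.theta(x, "C") for x in cfg])
            Q[i, index[("O", cfg)]] += params.k_co / denom
        else:
            denom = np.prod([params.theta(x, "O") for x in cfg])
            Q[i, index[("C", cfg)]] += params.k_oc / denom
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def micro_equilibrium(params, v_mv):
    """Stationary distribution over the 162 microstates (nullspace solve)."""
    Q = micro_rate_matrix(params, v_mv)
    A = np.vstack([Q.T, np.ones((1, Q.shape[0]))])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return p


def project_to_counts(p_micro, canonical_states):
    """Project a microstate distribution onto the aggregated (pore, counts) order."""
    states = micro_states()
    out = np.zeros(len(canonical_states))
    lookup = {
        (s.pore, s.n_R, s.n_I, s.n_A): j for j, s in enumerate(canonical_states)
    }
    for p_i, (pore, cfg) in zip(p_micro, states):
        key = (pore, cfg.count("R"), cfg.count("I"), cfg.count("A"))
        out[lookup[key]] += p_i
    return out


def micro_simulate(params, protocol, p0_micro):
    """Propagate the microstate master equation over a protocol's sample grid.

    Returns (times_ms, occupancy) with one expm per segment step (uniform
    grid, iterated multiplication - exact for piecewise-constant Q).
    """
    dt = protocol.sample_interval_ms
    times = protocol.times_ms()
    occ = np.empty((len(times), len(p0_micro)))
    occ[0] = p0_micro
    p = np.asarray(p0_micro, dtype=float)
    row = 1
    for dur_ms, v_mv in protocol.segments:
        Q = micro_rate_matrix(params, v_mv)
        P_dt = expm(Q * (dt / 1000.0))
        for _ in range(int(round(dur_ms / dt))):
            p = p @ P_dt
            occ[row] = p
            row += 1
    return times, occ


def micro_observables(params, occupancy, volt_mv, ion="K"):
    """Open probability, current, fluorescence from microstate occupancies."""
    states = micro_states()
    open_mask = np.array([s[0] == "O" for s in states], dtype=float)
    fw = {"R": 0.0, "I": params.f_i, "A": params.f_a}
    fweights = np.array([sum(fw[x] for x in cfg) / 4.0 for _, cfg in states])
    p_open = occupancy @ open_mask
    ic = params.ions[ion]
    current = params.n_channels * ic.g * p_open * (volt_mv - ic.e_rev_mv)
    fluor = occupancy @ fweights
    return p_open, current, fluor
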