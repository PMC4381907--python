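"""Voltage-dependent rate matrix of the aggregated gating scheme.

Transition rules (single-component moves only):

* VSD step X->Y while the pore is in state P:
  rate = n(X) * k_XY(V) / theta_XP — the multiplicity counts eligible VSDs
  and the transitioning VSD's interaction with the *current* pore state
  divides the rate, so a stabilized pair is slow to leave.
* Pore opening  C->O: k_co / (theta_RC^nR * theta_IC^nI * theta_AC^nA).
* Pore closing  O->C: k_oc / (theta_RO^nR * theta_IO^nI * theta_AO^nA).

Dividing departure rates by the theta of the state being left makes the
chain reversible: the stationary distribution has closed-form Gibbs weights

  w(P, n) = multinomial(4; n) * K_RI(V)^(nI+nA) * K_IA(V)^nA
            * [K_CO if open] * prod_X theta_XP^nX

with K_xy(V) = k_xy(V)/k_yx(V) and K_CO = k_co/k_oc.
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .constants import PhysicalConstants
from .params import GatingParameters, RateLaw
from .states import ChannelState, enumerate_states, state_label

# |z F V / (R T)| beyond this is clamped; exp(700) is near the float64 limit
MAX_EXPONENT = 700.0


def vsd_rate(law: RateLaw, v_mv: float, constants: PhysicalConstants) -> float:
    """Evaluate k0 * exp(z F V / (R T)) with V given in millivolts.

    The exponent is clamped at +-700 (with a warning) to avoid overflow at
    unphysically extreme voltages.
    """
    if not np.isfinite(v_mv):
        raise ValueError("voltage must be finite")
    x = law.z * constants.F * (v_mv / 1000.0) / (constants.R * constants.T)
    if abs(x) > MAX_EXPONENT:
        warnings.warn(
            f"rate-law exponent {x:.3g} clamped to +-{MAX_EXPONENT:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        x = math.copysign(MAX_EXPONENT, x)
    return law.k0 * math.exp(x)


def _vsd_moves(state: ChannelState) -> List[Tuple[ChannelState, str, str, int]]:
    """Single-VSD moves from a state: (target, from_vsd, transition, multiplicity)."""
    moves = []
    p, nR, nI, nA = state.pore, state.n_R, state.n_I, state.n_A
    if nR > 0:
        moves.append((ChannelState(p, nR - 1, nI + 1, nA), "R", "ri", nR))
    if nI > 0:
        moves.append((ChannelState(p, nR + 1, nI - 1, nA), "I", "ir", nI))
        moves.append((ChannelState(p, nR, nI - 1, nA + 1), "I", "ia", nI))
    if nA > 0:
        moves.append((ChannelState(p, nR, nI + 1, nA - 1), "A", "ai", nA))
    return moves


def _pore_theta_product(params: GatingParameters, state: ChannelState) -> float:
    """prod_X theta_{X, pore(state)}^{n_X} for the state's current pore state."""
    p = state.pore
    return (
        params.theta("R", p) ** state.n_R
        * params.theta("I", p) ** state.n_I
        * params.theta("A", p) ** state.n_A
    )


def build_rate_matrix(
    params: GatingParameters,
    v_mv: float,
    states: Optional[List[ChannelState]] = None,
    n_vsd: int = 4,
) -> np.ndarray:
    """Transition-rate matrix Q over the canonical state order at voltage V.

    Q[i, j] is the rate from state i to state j (1/s); diagonal entries make
    each row sum to zero, so occupancy evolves as dp/dt = p @ Q.
    """
    canonical = enumerate_states(n_vsd)
    if states is None:
        states = canonical
    elif states != canonical:
        raise ValueError("states must be the canonical ordering from enumerate_states()")
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for i, s in enumerate(states):
        for target, from_vsd, transition, mult in _vsd_moves(s):
            k = vsd_rate(params.vsd_law(transition), v_mv, params.constants)
            Q[i, index[target]] = mult * k / params.theta(from_vsd, s.pore)
        # pore move
        flipped = ChannelState("O" if s.pore == "C" else "C", s.n_R, s.n_I, s.n_A)
        k_pore = params.k_co if s.pore == "C" else params.k_oc
        Q[i, index[flipped]] = k_pore / _pore_theta_product(params, s)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def log_equilibrium_weights(
    params: GatingParameters,
    v_mv: float,
    states: Optional[List[ChannelState]] = None,
    n_vsd: int = 4,
) -> np.ndarray:
    """Unnormalized log Gibbs weights over the canonical state order."""
    if states is None:
        states = enumerate_states(n_vsd)
    c = params.constants
    frt = c.F * (v_mv / 1000.0) / (c.R * c.T)
    # log equilibrium constants of the two VSD steps and the pore
    log_k1 = (
        math.log(params.k_ri.k0 / params.k_ir.k0)
        + np.clip((params.k_ri.z - params.k_ir.z) * frt, -MAX_EXPONENT, MAX_EXPONENT)
    )
    log_k2 = (
        math.log(params.k_ia.k0 / params.k_ai.k0)
        + np.clip((params.k_ia.z - params.k_ai.z) * frt, -MAX_EXPONENT, MAX_EXPONENT)
    )
    log_kco = math.log(params.k_co / params.k_oc)
    logw = np.empty(len(states))
    log_fact = gammaln(np.arange(n_vsd + 1) + 1.0)
    for i, s in enumerate(states):
        lw = (
            log_fact[n_vsd]
            - log_fact[s.n_R]
            - log_fact[s.n_I]
            - log_fact[s.n_A]
            + (s.n_I + s.n_A) * log_k1
            + s.n_A * log_k2
            + s.n_R * math.log(params.theta("R", s.pore))
            + s.n_I * math.log(params.theta("I", s.pore))
            + s.n_A * math.log(params.theta("A", s.pore))
        )
        if s.is_open:
            lw += log_kco
        logw[i] = lw
    return logw


def equilibrium_distribution(
    params: GatingParameters, v_mv: float, n_vsd: int = 4
) -> np.ndarray:
    """Stationary distribution at voltage V from the closed-form Gibbs weights.

    Computed in log space, so it is robust at voltages where equilibrium
    constants overflow a direct product.
    """
    logw = log_equilibrium_weights(params, v_mv, n_vsd=n_vsd)
    return np.exp(logw - logsumexp(logw))


def stationary_from_matrix(Q: np.ndarray, cond_warn: float = 1e12) -> np.ndarray:
    """Stationary distribution of a rate matrix via its left nullspace.

    Solves p Q = 0 with the normalization sum(p) = 1 as a least-squares
    system; warns if the system is badly conditioned.
    """
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    cond = np.linalg.cond(A)
    if cond > cond_warn:
        warnings.warn(
            f"stationary solve badly conditioned (cond={cond:.3g})", RuntimeWarning
        )
    return p


def open_probability(params: GatingParameters, v_mv: float) -> float:
    """Equilibrium total open probability at voltage V."""
    states = enumerate_states()
    p = equilibrium_distribution(params, v_mv)
    return float(sum(pi for pi, s in zip(p, states) if s.is_open))


def rate_matrix_frame(params: GatingParameters, v_mv: float):
    """Rate matrix as a labelled pandas DataFrame (C_RRRR-style labels)."""
    import pandas as pd

    states = enumerate_states()
    labels = [state_label(s) for s in states]
    return pd.DataFrame(build_rate_matrix(params, v_mv), index=labels, columns=labels)
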