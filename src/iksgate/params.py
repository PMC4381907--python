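"""Gating parameters: intrinsic rates, VSD-pore coupling strengths, observables.

The parameterization separates

* intrinsic rates ``k`` — what each domain would do if the VSD and pore
  were completely decoupled (the model's reference state): four
  voltage-dependent VSD rate laws (R<->I, I<->A) and two
  voltage-independent pore rates (C<->O), and
* coupling strengths ``theta`` — one dimensionless factor per
  (VSD conformation, pore conformation) pair.  ``theta_XP > 1`` stabilizes
  the X-P pair and slows every transition that leaves it.

A gauge degeneracy exists: multiplying all closed-state thetas by a common
constant is equivalent to rescaling the intrinsic pore opening rate
``k_co`` (and likewise for the open-state thetas and ``k_oc``).  The
shipped defaults fix theta_RC = theta_RO = 1, using the resting VSD as the
coupling reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

from .constants import PhysicalConstants, DEFAULT_CONSTANTS

VSD_TRANSITIONS = ("ri", "ir", "ia", "ai")
THETA_KEYS = ("theta_rc", "theta_ic", "theta_ac", "theta_ro", "theta_io", "theta_ao")


@dataclass(frozen=True)
class RateLaw:
    """Voltage-dependent rate k(V) = k0 * exp(z * F * V / (R * T)).

    k0 is the rate at 0 mV in 1/s; z is the equivalent valence in
    elementary charges (signed; negative for rates slowed by
    depolarization).
    """

    k0: float
    z: float

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise ValueError(f"k0 must be positive, got {self.k0}")
        import math

        if not math.isfinite(self.z):
            raise ValueError("z must be finite")


@dataclass(frozen=True)
class IonChannelConditions:
    """Per-ion maximal conductance (arbitrary units) and reversal potential (mV)."""

    g: float
    e_rev_mv: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("conductance must be nonnegative")


@dataclass(frozen=True)
class GatingParameters:
    """Full parameter set of the 30-state gating model.

    Attributes
    ----------
    k_ri, k_ir, k_ia, k_ai:
        Intrinsic VSD rate laws (resting->intermediate, etc.).
    k_co, k_oc:
        Intrinsic pore opening / closing rates (1/s, voltage-independent).
    theta_rc ... theta_ao:
        Per-VSD coupling strengths with the closed (``*_c``) and open
        (``*_o``) pore.  Dimensionless, > 0.
    n_channels:
        Channel count N used to scale macroscopic current.
    ions:
        Mapping from ion condition ("K", "Rb", "Na") to conductance and
        reversal potential.
    f_i, f_a:
        Relative fluorescence of a VSD in the intermediate / activated
        state (resting = 0).  f_a >= f_i so the second VSD step adds signal.
    constants:
        Physical constants (F, R, T).
    """

    k_ri: RateLaw
    k_ir: RateLaw
    k_ia: RateLaw
    k_ai: RateLaw
    k_co: float
    k_oc: float
    theta_rc: float = 1.0
    theta_ic: float = 1.0
    theta_ac: float = 1.0
    theta_ro: float = 1.0
    theta_io: float = 1.0
    theta_ao: float = 1.0
    n_channels: float = 1000.0
    ions: Dict[str, IonChannelConditions] = field(
        default_factory=lambda: {
            "K": IonChannelConditions(g=1.0, e_rev_mv=-80.0),
            "Rb": IonChannelConditions(g=0.7, e_rev_mv=-80.0),
            "Na": IonChannelConditions(g=0.05, e_rev_mv=-80.0),
        }
    )
    f_i: float = 0.8
    f_a: float = 1.0
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not (self.k_co > 0 and self.k_oc > 0):
            raise ValueError("pore rates k_co, k_oc must be positive")
        for key in THETA_KEYS:
            if not (getattr(self, key) > 0):
                raise ValueError(f"{key} must be positive")
        if not (self.f_a >= self.f_i >= 0):
            raise ValueError("fluorescence weights must satisfy f_a >= f_i >= 0")

    def theta(self, vsd_state: str, pore_state: str) -> float:
        """Coupling strength for a (VSD state, pore state) pair, e.g. ('I','C')."""
        return getattr(self, f"theta_{vsd_state.lower()}{pore_state.lower()}")

    def vsd_law(self, transition: str) -> RateLaw:
        """Rate law for one VSD transition: 'ri', 'ir', 'ia' or 'ai'."""
        return getattr(self, f"k_{transition}")

    def replace(self, **changes) -> "GatingParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            t: {"k0": self.vsd_law(t).k0, "z": self.vsd_law(t).z}
            for t in VSD_TRANSITIONS
        }
        out = {
            "vsd_rates": d,
            "k_co": self.k_co,
            "k_oc": self.k_oc,
            **{k: getattr(self, k) for k in THETA_KEYS},
            "n_channels": self.n_channels,
            "ions": {
                name: {"g": ic.g, "e_rev_mv": ic.e_rev_mv}
                for name, ic in self.ions.items()
            },
            "f_i": self.f_i,
            "f_a": self.f_a,
            "constants": {"F": self.constants.F, "R": self.constants.R, "T": self.constants.T},
        }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParameters":
        vr = d["vsd_rates"]
        kwargs = dict(
            k_ri=RateLaw(**vr["ri"]),
            k_ir=RateLaw(**vr["ir"]),
            k_ia=RateLaw(**vr["ia"]),
            k_ai=RateLaw(**vr["ai"]),
            k_co=float(d["k_co"]),
            k_oc=float(d["k_oc"]),
        )
        for k in THETA_KEYS:
            if k in d:
                kwargs[k] = float(d[k])
        if "n_channels" in d:
            kwargs["n_channels"] = float(d["n_channels"])
        if "ions" in d:
            kwargs["ions"] = {
                name: IonChannelConditions(g=float(v["g"]), e_rev_mv=float(v["e_rev_mv"]))
                for name, v in d["ions"].items()
            }
        for k in ("f_i", "f_a"):
            if k in d:
                kwargs[k] = float(d[k])
        if "constants" in d:
            kwargs["constants"] = PhysicalConstants(**d["constants"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GatingParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short stable hash of the parameter values, for provenance stamps."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_kcnq1(constants: Optional[PhysicalConstants] = None) -> GatingParameters:
    """Default KCNQ1-like baseline parameter set.

    These are the package's own values, chosen to reproduce the qualitative
    gating phenotype of homomeric KCNQ1: VSD activation in two steps (a
    fast low-voltage R->I step carrying most of the fluorescence and a
    slower high-voltage I->A step), pore opening promoted already by the
    intermediate state so that the conductance-voltage curve tracks the
    low-voltage fluorescence component, and a biphasic current onset.
    They are not taken from any published table; load a user set with
    :meth:`GatingParameters.from_yaml` to override.
    """
    kwargs = {}
    if constants is not None:
        kwargs["constants"] = constants
    return GatingParameters(
        # R->I: fast, half-activated near -50 mV with 1.6 e0 net charge
        k_ri=RateLaw(k0=35.0, z=0.8),
        k_ir=RateLaw(k0=1.5, z=-0.8),
        # I->A: slow, half-activated near +25 mV with 1.4 e0 net charge
        k_ia=RateLaw(k0=2.0, z=0.7),
        k_ai=RateLaw(k0=7.8, z=-0.7),
        # intrinsic pore equilibrium biased closed (P_open = 0.02 decoupled)
        k_co=6.0,
        k_oc=300.0,
        # resting state is the coupling reference; the intermediate state
        # promotes opening (theta_io > 1) and the activated state slightly
        # more, leaving headroom for the KCNE1 theta_ao strengthening
        theta_rc=1.0,
        theta_ic=1.0,
        theta_ac=1.0,
        theta_ro=1.0,
        theta_io=2.3,
        theta_ao=2.7,
        **kwargs,
    )
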