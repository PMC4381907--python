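"""Enumeration of aggregated channel states.

Four identical, non-cooperative VSDs are aggregated by counting how many
occupy each of the three VSD conformations (resting R, intermediate I,
activated A).  With the pore factor (closed C / open O) this gives
2 * C(4+2, 2) = 30 distinct channel states.

The canonical ordering — closed block before open block, lexicographic
descending (n_R, n_I, n_A) within each block — is the indexing contract
for every rate matrix and occupancy vector in the package.
"""

from dataclasses import dataclass
from itertools import product
from typing import List

VSD_STATES = ("R", "I", "A")
PORE_STATES = ("C", "O")


@dataclass(frozen=True, order=True)
class ChannelState:
    """One aggregated channel configuration.

    Attributes
    ----------
    pore:
        "C" (closed) or "O" (open).
    n_R, n_I, n_A:
        Counts of VSDs in the resting / intermediate / activated
        conformation; they always sum to the number of VSDs (4 by default).
    """

    pore: str
    n_R: int
    n_I: int
    n_A: int

    def __post_init__(self) -> None:
        if self.pore not in PORE_STATES:
            raise ValueError(f"pore must be 'C' or 'O', got {self.pore!r}")
        for n in (self.n_R, self.n_I, self.n_A):
            if n < 0 or int(n) != n:
                raise ValueError("VSD counts must be nonnegative integers")

    @property
    def n_vsd(self) -> int:
        return self.n_R + self.n_I + self.n_A

    @property
    def is_open(self) -> bool:
        return self.pore == "O"

    def count(self, vsd_state: str) -> int:
        return {"R": self.n_R, "I": self.n_I, "A": self.n_A}[vsd_state]


def enumerate_states(n_vsd: int = 4) -> List[ChannelState]:
    """All aggregated states in canonical order.

    Canonical order: closed block first, then open; within a block,
    lexicographic descending on (n_R, n_I, n_A).  For n_vsd=4 the first
    state is C with all VSDs resting and the last is O with all activated.
    """
    if n_vsd < 0:
        raise ValueError("n_vsd must be nonnegative")
    counts = sorted(
        (
            (nR, nI, n_vsd - nR - nI)
            for nR in range(n_vsd, -1, -1)
            for nI in range(n_vsd - nR, -1, -1)
        ),
        reverse=True,
    )
    return [ChannelState(pore, *c) for pore, c in product(PORE_STATES, counts)]


def state_label(state: ChannelState) -> str:
    """Subscripted label such as 'C_RRRR' or 'O_RIIA'."""
    letters = "R" * state.n_R + "I" * state.n_I + "A" * state.n_A
    return f"{state.pore}_{letters}"


def state_index(state: ChannelState, n_vsd: int = 4) -> int:
    """Index of a state in the canonical ordering."""
    return enumerate_states(n_vsd).index(state)
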