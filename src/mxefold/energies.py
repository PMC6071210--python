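"""Nearest-neighbor duplex energy parameters (37 degrees C, kcal/mol).

Watson-Crick/Watson-Crick stack free energies are the standard
nearest-neighbor values for RNA at 37 degrees C; stacks involving G-U
wobble pairs use flat approximate values (one wobble pair: -1.3, two:
-0.5), which is a deliberate simplification — the statistic of record
downstream is the difference against matched controls, not absolute
energies. Input sequences are DNA-alphabet; T is folded as U.

Stack keys read 5'-WX-3' / 3'-ZY-5': the stack of pair W.Z followed by
pair X.Y. The table is symmetric under reading the helix from the other
strand: E[a,b,c,d] == E[d,c,b,a].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# base encoding: A=0, C=1, G=2, T/U=3
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

#: canonical Watson-Crick stack free energies, 5'-WX-3'/3'-ZY-5'
WC_STACKS: dict[str, float] = {
    "AA/UU": -0.93,
    "AU/AU": -1.10,
    "UA/UA": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}

GU_STACK_ONE = -1.3  # stack with exactly one G.U wobble pair
GU_STACK_TWO = -0.5  # stack with two wobble pairs

DUPLEX_INIT = 4.09  # duplex initiation penalty
LOOP_OPEN = 3.0  # interior/bulge loop opening penalty per loop
LOOP_PER_BASE = 0.3  # interior/bulge loop penalty per unpaired base
MAX_LOOP = 30  # max total unpaired bases inside one duplex loop

_WC = {(0, 3), (3, 0), (1, 2), (2, 1)}
_GU = {(2, 3), (3, 2)}


def _pair_table(allow_gu: bool) -> np.ndarray:
    pairs = _WC | (_GU if allow_gu else set())
    t = np.zeros((4, 4), dtype=np.bool_)
    for a, b in pairs:
        t[a, b] = True
    return t


def _stack_table(allow_gu: bool) -> np.ndarray:
    """E[a, b, c, d]: stack of pair a.b followed (3' on x, 5' on y) by
    pair c.d. Unstackable combinations hold 0 and are guarded by the
    pairability table in the DP."""
    e = np.zeros((4, 4, 4, 4), dtype=np.float64)
    pairs = _WC | (_GU if allow_gu else set())
    for a, b in pairs:
        for c, d in pairs:
            n_gu = ((a, b) in _GU) + ((c, d) in _GU)
            if n_gu == 1:
                e[a, b, c, d] = GU_STACK_ONE
            elif n_gu == 2:
                e[a, b, c, d] = GU_STACK_TWO
    for key, val in WC_STACKS.items():
        w, x, z, y = key[0], key[1], key[3], key[4]
        a, c = _ENC[w], _ENC[x]
        b, d = _ENC[z], _ENC[y]
        e[a, b, c, d] = val
        e[d, c, b, a] = val  # other-strand reading of the same stack
    return e


@dataclass
class EnergyParams:
    """Tunable parameters of the built-in duplex engine."""

    loop_open: float = LOOP_OPEN
    loop_per_base: float = LOOP_PER_BASE
    init: float = DUPLEX_INIT
    max_loop: int = MAX_LOOP
    allow_gu: bool = True
    no_lonely_pairs: bool = True
    _pairable: np.ndarray = field(init=False, repr=False)
    _stack: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.loop_per_base <= 0 or self.init <= 0 or self.loop_open < 0:
            raise ValueError("loop and initiation penalties must be positive")
        self._pairable = _pair_table(self.allow_gu)
        self._stack = _stack_table(self.allow_gu)

    def stack_energy(self, dimer_x: str, dimer_y: str) -> float:
        """Stack energy for x dimer 5'->3' over y dimer 3'->5'."""
        a, c = _ENC[dimer_x[0]], _ENC[dimer_x[1]]
        b, d = _ENC[dimer_y[0]], _ENC[dimer_y[1]]
        return float(self._stack[a, b, c, d])
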