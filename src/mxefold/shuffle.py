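"""Dinucleotide-preserving sequence shuffle.

The shuffle exchanges the middle letters of two triplets x,y,z and x,w,z
that share the same outer letters; every such exchange leaves the
overlapping-dinucleotide counts of the sequence unchanged, so the shuffled
control has exactly the composition (mono- and dinucleotide) of the input.
The exchange is repeated l times by default, where l is the sequence
length; moves without an eligible partner are no-ops but count toward the
l attempts. The first and last letters can never move.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._kernels import dinuc_shuffle_kernel

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ENC = {c: i for i, c in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from exc


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[v] for v in arr)


@dataclass
class ShuffleConfig:
    """n_swaps defaults to the sequence length when None."""

    n_swaps: int | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_swaps is not None and self.n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Counts of overlapping dinucleotides; total is len(seq) - 1."""
    return dict(Counter(seq[i : i + 2] for i in range(len(seq) - 1)))


def shuffle(seq: str, cfg: ShuffleConfig | None = None) -> str:
    """Dinucleotide-preserving shuffled copy of ``seq``.

    Sequences shorter than 3 nt are returned unchanged (logged).
    """
    cfg = cfg or ShuffleConfig()
    if len(seq) < 3:
        log.debug("sequence of length %d returned unshuffled", len(seq))
        return seq
    arr = encode(seq)
    n_swaps = cfg.n_swaps if cfg.n_swaps is not None else len(seq)
    dinuc_shuffle_kernel(arr, n_swaps, cfg.seed % (2**31))
    return decode(arr)
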