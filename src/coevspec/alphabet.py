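"""Amino-acid alphabet conventions shared by every module.

The Potts state space is the 20 canonical amino acids in alphabetical
one-letter order, followed by the gap symbol as the last state (q = 21).
The gap is a full state: it is counted in frequencies and serves as the
gauge state of the fitted models, so an all-gap column or padding scores
exactly zero.  Reduced alphabets (smaller q, used by the synthetic
generator for speed) keep the same layout: q - 1 residue letters, gap
last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues without a canonical one-letter Potts state; normalized to gap
NON_CANONICAL = set("BJOUXZ")


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with the gap as the last (gauge) state."""

    letters: str = AMINO_ACIDS + GAP
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.letters[-1] != GAP:
            raise ValueError("alphabet must end with the gap symbol")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.letters)})

    @property
    def q(self) -> int:
        return len(self.letters)

    @property
    def gap_state(self) -> int:
        return self.q - 1

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence to integer states; unknown characters raise."""
        try:
            return np.array([self._index[c] for c in seq], dtype=np.int8)
        except KeyError as exc:
            pos = next(i for i, c in enumerate(seq) if c not in self._index)
            raise ValueError(
                f"character {seq[pos]!r} at position {pos + 1} is outside "
                f"the alphabet {self.letters!r}"
            ) from exc

    def decode(self, states) -> str:
        return "".join(self.letters[int(s)] for s in states)

    @classmethod
    def reduced(cls, q: int) -> "Alphabet":
        """Alphabet with q - 1 residue letters plus gap (q >= 2)."""
        if not 2 <= q <= len(AMINO_ACIDS) + 1:
            raise ValueError(f"q must be in [2, {len(AMINO_ACIDS) + 1}], got {q}")
        return cls(AMINO_ACIDS[: q - 1] + GAP)


PROTEIN = Alphabet()
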