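"""Paired protease-substrate alignments.

Reads, validates, filters, concatenates and scrambles the two aligned
blocks (protease and substrate) that make up a paired alignment.  Rows
are matched across blocks by sequence identifier (the organism/accession
key); the concatenated row for a pair is simply protease sequence +
substrate sequence.  Scrambling re-partners substrates uniformly at
random to build the non-specific null alignment.

All user-facing coordinates are 1-based inclusive; arrays are 0-based
internally.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, NON_CANONICAL, PROTEIN, Alphabet

logger = logging.getLogger(__name__)

_GAP_CHARS = ".-"


def _normalize(seq: str, record_id: str) -> str:
    seq = seq.upper()
    out = []
    warned = set()
    for c in seq:
        if c in _GAP_CHARS:
            out.append(GAP)
        elif c in NON_CANONICAL:
            if c not in warned:
                logger.warning(
                    "record %s: non-canonical residue %r replaced by gap", record_id, c
                )
                warned.add(c)
            out.append(GAP)
        else:
            out.append(c)
    return "".join(out)


@dataclass
class AlignedBlock:
    """One aligned block (protease or substrate) of a paired alignment."""

    sequences: list[str]
    ids: list[str]
    role: str  # "protease" or "substrate"
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN)

    def __post_init__(self):
        if self.role not in ("protease", "substrate"):
            raise ValueError(f"role must be 'protease' or 'substrate', got {self.role!r}")
        if len(self.sequences) != len(self.ids):
            raise ValueError("one id per sequence required")
        if not self.sequences:
            raise ValueError("empty alignment block")
        L = len(self.sequences[0])
        for k, s in enumerate(self.sequences):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: record {self.ids[k]!r} (#{k + 1}) has "
                    f"length {len(s)}, expected {L}"
                )
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r} in {self.role} block")
        for k, s in enumerate(self.sequences):
            bad = set(s) - set(self.alphabet.letters)
            if bad:
                raise ValueError(
                    f"record {self.ids[k]!r} contains characters outside the "
                    f"alphabet: {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def to_matrix(self) -> np.ndarray:
        """Integer state matrix, shape (n_sequences, length)."""
        return np.stack([self.alphabet.encode(s) for s in self.sequences])

    def subset(self, indices: Sequence[int]) -> "AlignedBlock":
        return AlignedBlock(
            [self.sequences[i] for i in indices],
            [self.ids[i] for i in indices],
            self.role,
            self.alphabet,
        )


def read_alignment(path, fmt: str = "fasta", role: str = "protease") -> AlignedBlock:
    """Read an aligned FASTA or Stockholm file into a validated block.

    Characters are uppercased, '.' and '-' both become the gap symbol and
    non-canonical residues (B, J, O, U, X, Z) are replaced by gap with a
    logged warning.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"fmt must be 'fasta' or 'stockholm', got {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython raises on ragged or empty input; re-raise with context.
        raise ValueError(f"could not parse alignment {path}: {exc}") from exc
    if len(aln) == 0:
        raise ValueError(f"empty alignment file: {path}")
    seqs = [_normalize(str(rec.seq), rec.id) for rec in aln]
    ids = [rec.id for rec in aln]
    return AlignedBlock(seqs, ids, role)


def write_alignment(block: AlignedBlock, path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for s, i in zip(block.sequences, block.ids)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def longest_gap_run(seq: str) -> int:
    runs = re.findall(f"{re.escape(GAP)}+", seq)
    return max((len(r) for r in runs), default=0)


def filter_contiguous_gaps(block: AlignedBlock, max_run: int = 45) -> AlignedBlock:
    """Drop sequences whose longest run of consecutive gaps exceeds ``max_run``.

    Separate runs are not summed; order and ids are preserved.
    """
    if max_run < 0:
        raise ValueError("max_run must be >= 0")
    keep = [k for k, s in enumerate(block.sequences) if longest_gap_run(s) <= max_run]
    if not keep:
        raise ValueError(
            f"gap filter (max_run={max_run}) removed every sequence from the "
            f"{block.role} block"
        )
    removed = block.n_sequences - len(keep)
    if removed:
        logger.info("gap filter removed %d of %d sequences", removed, block.n_sequences)
    return block.subset(keep)


@dataclass
class PairedAlignment:
    """Protease and substrate blocks with row-wise pairing.

    Row m pairs protease sequence ``pair_index[m][0]`` with substrate
    sequence ``pair_index[m][1]``; the concatenated row is the protease
    sequence followed by the substrate sequence.  ``motif_window`` is the
    1-based inclusive column range of the P6-P1' cleavage motif within
    the substrate block (width 7).
    """

    protease_block: AlignedBlock
    substrate_block: AlignedBlock
    pair_index: list[tuple[int, int]]
    motif_window: tuple[int, int]

    def __post_init__(self):
        if self.protease_block.alphabet != self.substrate_block.alphabet:
            raise ValueError("blocks must share an alphabet")
        lo, hi = self.motif_window
        if hi - lo + 1 != 7:
            raise ValueError(f"motif window must span exactly 7 positions, got {self.motif_window}")
        if not (1 <= lo and hi <= self.substrate_block.length):
            raise ValueError(
                f"motif window {self.motif_window} outside substrate block "
                f"[1, {self.substrate_block.length}]"
            )

    @property
    def l_protease(self) -> int:
        return self.protease_block.length

    @property
    def l_substrate(self) -> int:
        return self.substrate_block.length

    @property
    def total_length(self) -> int:
        return self.l_protease + self.l_substrate

    @property
    def n_rows(self) -> int:
        return len(self.pair_index)

    @property
    def alphabet(self) -> Alphabet:
        return self.protease_block.alphabet

    def row(self, m: int) -> str:
        p, s = self.pair_index[m]
        return self.protease_block.sequences[p] + self.substrate_block.sequences[s]

    def rows(self) -> list[str]:
        return [self.row(m) for m in range(self.n_rows)]

    def to_matrix(self) -> np.ndarray:
        """Integer state matrix of concatenated rows, shape (M, L)."""
        enc = self.alphabet.encode
        return np.stack([enc(self.row(m)) for m in range(self.n_rows)])

    def row_ids(self) -> list[tuple[str, str]]:
        return [
            (self.protease_block.ids[p], self.substrate_block.ids[s])
            for p, s in self.pair_index
        ]


def concatenate_pairs(
    protease: AlignedBlock,
    substrate: AlignedBlock,
    motif_window: tuple[int, int],
) -> PairedAlignment:
    """Pair protease and substrate sequences by exact id match.

    Only ids present in both blocks form rows; unmatched sequences are
    dropped with a logged count.  Row order follows the protease block.
    """
    sub_idx = {i: k for k, i in enumerate(substrate.ids)}
    pairs = [
        (k, sub_idx[i]) for k, i in enumerate(protease.ids) if i in sub_idx
    ]
    if not pairs:
        raise ValueError("no shared ids between protease and substrate blocks")
    dropped = (protease.n_sequences - len(pairs)) + (substrate.n_sequences - len(pairs))
    if dropped:
        logger.info("dropped %d unpaired sequences", dropped)
    return PairedAlignment(protease, substrate, pairs, tuple(motif_window))


@dataclass(frozen=True)
class ScramblePlan:
    """Reproducible substrate-row permutation used to build the null alignment."""

    permutation: tuple[int, ...]
    seed: int

    def __post_init__(self):
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("not a valid permutation")

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "permutation": list(self.permutation)})

    @classmethod
    def from_json(cls, text: str) -> "ScramblePlan":
        d = json.loads(text)
        return cls(tuple(d["permutation"]), d["seed"])


def scramble_pairs(
    aln: PairedAlignment, seed: int
) -> tuple[PairedAlignment, ScramblePlan]:
    """Re-partner substrates by a uniform random permutation of rows.

    Protease rows stay fixed.  Fixed points are not forbidden: with M
    rows the expected number of pairs keeping their partner is 1, which
    is negligible against the alignment size, and the unconditioned
    uniform permutation is easier to reason about.
    """
    if aln.n_rows < 2:
        raise ValueError("scrambling needs at least 2 rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(aln.n_rows)
    new_pairs = [
        (aln.pair_index[m][0], aln.pair_index[perm[m]][1]) for m in range(aln.n_rows)
    ]
    scrambled = PairedAlignment(
        aln.protease_block, aln.substrate_block, new_pairs, aln.motif_window
    )
    return scrambled, ScramblePlan(tuple(int(p) for p in perm), seed)


def pooled_scramble(
    aln: PairedAlignment, n_scrambles: int, seed: int
) -> tuple[PairedAlignment, list[ScramblePlan]]:
    """Pool several independent scrambles into one null alignment.

    With ``n_scrambles = 1`` this is a single :func:`scramble_pairs`.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    plans = []
    all_pairs: list[tuple[int, int]] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_scrambles):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scrambled, plan = scramble_pairs(aln, sub_seed)
        plans.append(plan)
        all_pairs.extend(scrambled.pair_index)
    pooled = PairedAlignment(
        aln.protease_block, aln.substrate_block, all_pairs, aln.motif_window
    )
    return pooled, plans


def write_pair_table(aln: PairedAlignment, path) -> None:
    """TSV of (id, protease_row, substrate_row), one line per pair."""
    with open(path, "w") as fh:
        fh.write("id\tprotease_row\tsubstrate_row\n")
        for m, (p, s) in enumerate(aln.pair_index):
            fh.write(f"{aln.protease_block.ids[p]}\t{p}\t{s}\n")
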