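"""Specificity Hamiltonian scoring.

A trained specificity model holds two Potts models fit on the same
paired alignment: one on the canonical (organism-matched) pairs and one
on scrambled (randomly re-partnered) pairs.  The energy of a candidate
protease-substrate pair under either parameter set is

    H = - sum_{i in protease} sum_{j in substrate} e_ij(A_i, A_j)
        - sum_{i in all positions} h_i(A_i)

i.e. the coupling sum runs only across the protease-substrate block
boundary (intra-block couplings, although fitted, are excluded), while
the field sum runs over all positions.  The specificity score is

    H_spec = H_canonical - H_scrambled

-- more negative means stronger predicted specificity, because the
subtraction removes family-likeness shared by arbitrary protease and
substrate homologs and keeps only the signal unique to interacting
pairs.

Masked scoring zeroes every coupling and field touching substrate
positions outside the 7-residue P6-P1' motif window, in both the
canonical and the scrambled Hamiltonian, for experiments that probe the
bare motif without its extended sequence context.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from sklearn.base import BaseEstimator

from .alphabet import GAP, Alphabet
from .dca import MeanFieldDCA, PottsModel
from .msa import AlignedBlock, PairedAlignment, ScramblePlan, pooled_scramble

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificityModel",
    "HamiltonianScore",
    "MutationEffect",
    "CouplingContribution",
    "SpecificityScorer",
    "score_pair",
    "align_query",
    "mutation_scan",
    "coupling_decomposition",
]


@dataclass
class SpecificityModel:
    """Canonical + scrambled Potts models with block geometry.

    ``motif_window`` is 1-based inclusive within the substrate block.
    ``protease_profile`` / ``substrate_profile`` keep the training block
    rows so unaligned queries can be mapped onto model columns.
    """

    canonical: PottsModel
    scrambled: PottsModel
    l_protease: int
    l_substrate: int
    motif_window: tuple[int, int]
    protease_profile: list[str] = field(default_factory=list)
    substrate_profile: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.canonical.length != self.scrambled.length:
            raise ValueError("canonical and scrambled models differ in length")
        if self.canonical.q != self.scrambled.q:
            raise ValueError("canonical and scrambled models differ in q")
        if self.canonical.length != self.l_protease + self.l_substrate:
            raise ValueError("model length != l_protease + l_substrate")
        lo, hi = self.motif_window
        if not (1 <= lo <= hi <= self.l_substrate):
            raise ValueError("motif window outside substrate block")

    @property
    def alphabet(self) -> Alphabet:
        return self.canonical.alphabet

    @property
    def length(self) -> int:
        return self.canonical.length

    def substrate_mask(self, masked: bool) -> np.ndarray:
        """Boolean keep-mask over substrate columns (True = active)."""
        keep = np.ones(self.l_substrate, dtype=bool)
        if masked:
            lo, hi = self.motif_window
            keep[:] = False
            keep[lo - 1 : hi] = True
        return keep

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Single .npz container with a JSON sidecar of provenance."""
        path = Path(path)
        np.savez_compressed(
            path,
            canonical_couplings=self.canonical.couplings,
            canonical_fields=self.canonical.fields,
            scrambled_couplings=self.scrambled.couplings,
            scrambled_fields=self.scrambled.fields,
            protease_profile=np.array(self.protease_profile),
            substrate_profile=np.array(self.substrate_profile),
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "alphabet": self.alphabet.letters,
                    "gauge": self.canonical.gauge,
                    "l_protease": self.l_protease,
                    "l_substrate": self.l_substrate,
                    "motif_window": list(self.motif_window),
                }
            )
        )

    @classmethod
    def load(cls, path) -> "SpecificityModel":
        path = Path(path)
        data = np.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        alphabet = Alphabet(meta["alphabet"])
        canonical = PottsModel(
            data["canonical_couplings"], data["canonical_fields"],
            alphabet, meta["gauge"], "canonical",
        )
        scrambled = PottsModel(
            data["scrambled_couplings"], data["scrambled_fields"],
            alphabet, meta["gauge"], "scrambled",
        )
        return cls(
            canonical,
            scrambled,
            meta["l_protease"],
            meta["l_substrate"],
            tuple(meta["motif_window"]),
            [str(s) for s in data["protease_profile"]],
            [str(s) for s in data["substrate_profile"]],
        )


@dataclass(frozen=True)
class HamiltonianScore:
    h_can: float
    h_scram: float
    masked: bool
    protease_id: str = ""
    substrate_id: str = ""

    @property
    def h_spec(self) -> float:
        return self.h_can - self.h_scram


@dataclass(frozen=True)
class MutationEffect:
    position: int  # 1-based within the targeted block
    from_state: str
    to_state: str
    delta_h: float
    masked: bool
    block: str = "substrate"


@dataclass(frozen=True)
class CouplingContribution:
    protease_position: int  # 1-based
    substrate_position: int  # 1-based
    states_a: tuple[str, str]
    states_b: tuple[str, str]
    value: float
    rank: int


# ---------------------------------------------------------------------------
# scoring primitives


def _encode_pair(
    model: SpecificityModel, protease_seq: str, substrate_seq: str
) -> tuple[np.ndarray, np.ndarray]:
    if len(protease_seq) != model.l_protease:
        raise ValueError(
            f"protease sequence length {len(protease_seq)} != block length "
            f"{model.l_protease}; unaligned input must pass through align_query"
        )
    if len(substrate_seq) != model.l_substrate:
        raise ValueError(
            f"substrate sequence length {len(substrate_seq)} != block length "
            f"{model.l_substrate}; unaligned input must pass through align_query"
        )
    enc = model.alphabet.encode
    return enc(protease_seq), enc(substrate_seq)


def _hamiltonian(
    potts: PottsModel,
    prot: np.ndarray,
    sub: np.ndarray,
    l_protease: int,
    sub_keep: np.ndarray,
) -> float:
    """Inter-block couplings + all fields, with masked substrate columns zeroed."""
    pi = np.arange(l_protease)
    sj = np.flatnonzero(sub_keep)
    e = potts.couplings[
        pi[:, None], (l_protease + sj)[None, :], prot[:, None], sub[sj][None, :]
    ]
    h_prot = potts.fields[pi, prot].sum()
    h_sub = potts.fields[l_protease + sj, sub[sj]].sum()
    return float(-e.sum() - h_prot - h_sub)


def score_pair(
    model: SpecificityModel,
    protease_seq: str,
    substrate_seq: str,
    masked: bool = True,
    protease_id: str = "",
    substrate_id: str = "",
) -> HamiltonianScore:
    """Score one aligned protease-substrate pair.

    Returns the canonical and scrambled Hamiltonians; ``h_spec`` is their
    difference.  With ``masked=True`` all parameters touching substrate
    positions outside the P6-P1' window are treated as zero in both
    Hamiltonians.
    """
    prot, sub = _encode_pair(model, protease_seq, substrate_seq)
    keep = model.substrate_mask(masked)
    h_can = _hamiltonian(model.canonical, prot, sub, model.l_protease, keep)
    h_scram = _hamiltonian(model.scrambled, prot, sub, model.l_protease, keep)
    return HamiltonianScore(h_can, h_scram, masked, protease_id, substrate_id)


def score_matrix(
    model: SpecificityModel,
    proteases: list[str],
    substrates: list[str],
    masked: bool = True,
) -> np.ndarray:
    """Vectorized H_spec for every protease x substrate combination."""
    enc = model.alphabet.encode
    P = np.stack([enc(s) for s in proteases]) if proteases else np.zeros((0, 0), int)
    S = np.stack([enc(s) for s in substrates]) if substrates else np.zeros((0, 0), int)
    keep = model.substrate_mask(masked)
    lp = model.l_protease
    sj = np.flatnonzero(keep)
    de = model.canonical.couplings - model.scrambled.couplings
    dh = model.canonical.fields - model.scrambled.fields
    out = np.zeros((len(proteases), len(substrates)))
    for i in range(lp):
        for j in sj:
            out -= de[i, lp + j][P[:, i][:, None], S[:, j][None, :]]
    hp = dh[np.arange(lp)[None, :], P].sum(axis=1)
    hs = dh[(lp + sj)[None, :], S[:, sj]].sum(axis=1)
    return out - hp[:, None] - hs[None, :]


def align_query(model: SpecificityModel, raw_seq: str, role: str) -> str:
    """Map an unaligned sequence onto the model columns of one block.

    Resolution order: exact match against a training row (gaps
    stripped); a bare motif-length substrate placed into the P6-P1'
    window with gap padding elsewhere; otherwise global alignment to the
    block consensus, dropping insertions (with a warning) and writing
    deletions as gaps.  Fewer than 50% matched columns is an error.
    """
    if role not in ("protease", "substrate"):
        raise ValueError(f"role must be 'protease' or 'substrate', got {role!r}")
    raw = raw_seq.replace(GAP, "").replace(".", "").upper()
    if not raw:
        raise ValueError("empty query sequence")
    width = model.l_protease if role == "protease" else model.l_substrate
    profile = (
        model.protease_profile if role == "protease" else model.substrate_profile
    )
    for row in profile:
        if row.replace(GAP, "") == raw:
            return row
    if role == "substrate":
        lo, hi = model.motif_window
        if len(raw) == hi - lo + 1:
            return GAP * (lo - 1) + raw + GAP * (width - hi)
    if not profile:
        raise ValueError("no training profile available to align against")
    consensus = _consensus(profile, model.alphabet)
    return _map_to_consensus(raw, consensus, model.alphabet)


def _consensus(profile: list[str], alphabet: Alphabet) -> str:
    X = np.stack([alphabet.encode(s) for s in profile])
    cols = []
    for j in range(X.shape[1]):
        counts = np.bincount(X[:, j], minlength=alphabet.q)
        counts[alphabet.gap_state] = 0  # consensus prefers residues over gaps
        cols.append(alphabet.letters[int(np.argmax(counts))] if counts.sum() else GAP)
    return "".join(cols)


def _map_to_consensus(raw: str, consensus: str, alphabet: Alphabet) -> str:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0  # free end gaps: query may cover a sub-range
    aln = aligner.align(consensus, raw)[0]
    out = [GAP] * len(consensus)
    matched = 0
    dropped = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            out[t0 + k] = raw[q0 + k]
            matched += 1
    dropped = len(raw) - matched
    if dropped:
        logger.warning("query alignment dropped %d insertion residues", dropped)
    if matched < 0.5 * len(raw):
        raise ValueError(
            f"query mapped only {matched}/{len(raw)} residues onto model "
            "columns (< 50%); cannot align"
        )
    return "".join(out)


def mutation_scan(
    model: SpecificityModel,
    protease_seq: str,
    substrate_seq: str,
    targets: list[int] | None = None,
    masked: bool = True,
    block: str = "substrate",
) -> list[MutationEffect]:
    """Delta-H_spec for every non-wild-type residue at the target positions.

    Positions are 1-based within the targeted block; the wild type is
    read from the input sequences.  The update is incremental: only
    Hamiltonian terms touching the mutated position are re-evaluated,
    which equals a full rescore to numerical precision.
    """
    if block not in ("protease", "substrate"):
        raise ValueError(f"block must be 'protease' or 'substrate', got {block!r}")
    prot, sub = _encode_pair(model, protease_seq, substrate_seq)
    lp = model.l_protease
    keep = model.substrate_mask(masked)
    width = lp if block == "protease" else model.l_substrate
    if targets is None:
        targets = list(range(1, width + 1))
    de = model.canonical.couplings - model.scrambled.couplings
    dh = model.canonical.fields - model.scrambled.fields
    alphabet = model.alphabet
    residues = range(alphabet.q - 1)  # all amino acids, never the gap
    out: list[MutationEffect] = []
    sj = np.flatnonzero(keep)
    for pos in targets:
        if not 1 <= pos <= width:
            raise ValueError(f"position {pos} outside the {block} block [1, {width}]")
        if block == "substrate":
            j = pos - 1
            wt = int(sub[j])
            if not keep[j]:
                # masked column: every parameter touching it is zero
                field_col = np.zeros(alphabet.q)
                coup = np.zeros(alphabet.q)
            else:
                field_col = dh[lp + j]
                coup = de[np.arange(lp), lp + j, prot, :].sum(axis=0)
        else:
            i = pos - 1
            wt = int(prot[i])
            field_col = dh[i]
            coup = de[i, lp + sj, :, sub[sj]].sum(axis=0)
        base = -coup[wt] - field_col[wt]
        for a in residues:
            if a == wt:
                continue
            delta = (-coup[a] - field_col[a]) - base
            out.append(
                MutationEffect(
                    position=pos,
                    from_state=alphabet.letters[wt],
                    to_state=alphabet.letters[a],
                    delta_h=float(delta),
                    masked=masked,
                    block=block,
                )
            )
    return out


def coupling_decomposition(
    model: SpecificityModel,
    pair_a: tuple[str, str],
    pair_b: tuple[str, str],
    top_k: int = 10,
    masked: bool = True,
) -> list[CouplingContribution]:
    """Per-(i, j) coupling contribution differences to H_spec, pair_b - pair_a.

    Each inter-block position pair contributes
    c_ij = -(e_ij^can - e_ij^scram)(A_i, A_j) to H_spec; the returned
    values are c_ij(pair_b) - c_ij(pair_a) ranked ascending, so the most
    negative entries are the couplings most stabilizing pair_b relative
    to pair_a.  Summing all contributions plus the field terms
    reproduces the H_spec difference exactly.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    prot_a, sub_a = _encode_pair(model, *pair_a)
    prot_b, sub_b = _encode_pair(model, *pair_b)
    lp = model.l_protease
    keep = model.substrate_mask(masked)
    de = model.canonical.couplings - model.scrambled.couplings
    letters = model.alphabet.letters
    entries = []
    for i in range(lp):
        for j in np.flatnonzero(keep):
            c_a = -de[i, lp + j, prot_a[i], sub_a[j]]
            c_b = -de[i, lp + j, prot_b[i], sub_b[j]]
            entries.append(
                (
                    float(c_b - c_a),
                    i + 1,
                    j + 1,
                    (letters[prot_a[i]], letters[sub_a[j]]),
                    (letters[prot_b[i]], letters[sub_b[j]]),
                )
            )
    entries.sort(key=lambda t: t[0])
    return [
        CouplingContribution(
            protease_position=i,
            substrate_position=j,
            states_a=sa,
            states_b=sb,
            value=v,
            rank=r + 1,
        )
        for r, (v, i, j, sa, sb) in enumerate(entries[:top_k])
    ]


# ---------------------------------------------------------------------------
# estimator


class SpecificityScorer(BaseEstimator):
    """Canonical-minus-scrambled specificity model as a fit/score estimator.

    ``fit`` takes a :class:`~coevspec.msa.PairedAlignment`, trains a
    mean-field DCA Potts model on the organism-matched rows and a second
    one on substrate-scrambled rows, and stores both plus the block
    geometry.  ``predict`` / ``score_pair`` return H_spec; negative
    scores predict specific cleavage.

    Parameters
    ----------
    pseudocount : float, default=0.5
        Relative pseudocount lambda for frequency regularization.
    identity_threshold : float, default=0.8
        Sequence-reweighting identity threshold.
    n_scrambles : int, default=1
        Number of pooled random substrate permutations in the null
        alignment.
    scramble_seed : int, default=0
        Seed of the scrambling permutation(s).
    masked : bool, default=True
        Default masking mode for scoring methods.
    """

    def __init__(
        self,
        pseudocount: float = 0.5,
        identity_threshold: float = 0.8,
        n_scrambles: int = 1,
        scramble_seed: int = 0,
        masked: bool = True,
    ):
        self.pseudocount = pseudocount
        self.identity_threshold = identity_threshold
        self.n_scrambles = n_scrambles
        self.scramble_seed = scramble_seed
        self.masked = masked

    def fit(self, X: PairedAlignment, y=None):
        if not isinstance(X, PairedAlignment):
            raise TypeError("SpecificityScorer.fit expects a PairedAlignment")
        dca = MeanFieldDCA(self.pseudocount, self.identity_threshold)
        canonical = dca.fit(X, provenance="canonical").model_
        self.dca_ = dca  # kept for direct-information quality checks
        scrambled_aln, plans = pooled_scramble(X, self.n_scrambles, self.scramble_seed)
        dca2 = MeanFieldDCA(self.pseudocount, self.identity_threshold)
        scrambled = dca2.fit(scrambled_aln, provenance="scrambled").model_
        scrambled.provenance = "scrambled"
        self.scramble_plans_: list[ScramblePlan] = plans
        self.model_ = SpecificityModel(
            canonical=canonical,
            scrambled=scrambled,
            l_protease=X.l_protease,
            l_substrate=X.l_substrate,
            motif_window=X.motif_window,
            protease_profile=list(X.protease_block.sequences),
            substrate_profile=list(X.substrate_block.sequences),
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("SpecificityScorer is not fitted yet")

    def score_pair(self, protease_seq: str, substrate_seq: str,
                   masked: bool | None = None, **ids) -> HamiltonianScore:
        self._check_fitted()
        return score_pair(
            self.model_, protease_seq, substrate_seq,
            self.masked if masked is None else masked, **ids,
        )

    def predict(self, pairs) -> np.ndarray:
        """H_spec for an iterable of (protease_seq, substrate_seq) pairs."""
        self._check_fitted()
        return np.array(
            [self.score_pair(p, s).h_spec for p, s in pairs]
        )

    def score_matrix(self, proteases, substrates, masked: bool | None = None):
        self._check_fitted()
        return score_matrix(
            self.model_, list(proteases), list(substrates),
            self.masked if masked is None else masked,
        )

    def mutation_scan(self, protease_seq, substrate_seq, targets=None,
                      masked: bool | None = None, block: str = "substrate"):
        self._check_fitted()
        return mutation_scan(
            self.model_, protease_seq, substrate_seq, targets,
            self.masked if masked is None else masked, block,
        )

    def coupling_decomposition(self, pair_a, pair_b, top_k: int = 10,
                               masked: bool | None = None):
        self._check_fitted()
        return coupling_decomposition(
            self.model_, pair_a, pair_b, top_k,
            self.masked if masked is None else masked,
        )

    def align_query(self, raw_seq: str, role: str) -> str:
        self._check_fitted()
        return align_query(self.model_, raw_seq, role)
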