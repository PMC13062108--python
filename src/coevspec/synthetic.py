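"""Synthetic paired alignments from a known Potts ground truth.

The generator plants protease-substrate specificity into a q-state
Potts model: a handful of inter-block position pairs carry
class-structured couplings under which residues from the same
"specificity class" attract (low energy) and residues from different
classes repel.  Gibbs-sampling the model yields a paired alignment
whose rows fall into latent compatibility classes -- an idealized,
fully known stand-in for the coevolved protease-substrate families the
inference pipeline is meant to analyze.  Every stage (reweighting,
frequency counting, coupling inversion, DI ranking, H_spec separation,
mutation-scan signs) can therefore be checked against planted truth
without any external data.

Residue states are assigned to classes round-robin (state index modulo
the number of classes); the gap state belongs to no class and carries
no planted couplings or fields (zero gauge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .alphabet import Alphabet
from .dca import PottsModel
from .msa import AlignedBlock, PairedAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthSpec",
    "SyntheticEnsemble",
    "make_ground_truth",
    "sample_states",
    "sample_alignment",
    "make_ensemble",
    "recovery_report",
]

#: planted inter-block contacts of the default spec (1-based positions)
DEFAULT_COUPLED_PAIRS = ((1, 2), (5, 3), (10, 4), (15, 5), (20, 6), (25, 7))


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of a planted-specificity Potts ground truth.

    ``coupled_pairs`` lists (protease position, substrate position)
    contacts, 1-based within each block; all of them cross the block
    boundary by construction.  ``coupling_scale`` sets the magnitude of
    the class-structured couplings (same-class +s, cross-class -s) and
    ``field_scale`` the standard deviation of the i.i.d. residue fields.
    """

    l_protease: int = 25
    l_substrate: int = 7
    q: int = 8
    n_classes: int = 3
    coupled_pairs: tuple[tuple[int, int], ...] = DEFAULT_COUPLED_PAIRS
    coupling_scale: float = 1.5
    field_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.coupling_scale < 0 or self.field_scale < 0:
            raise ValueError("scales must be >= 0")
        if self.n_classes > self.q - 1:
            raise ValueError("need at least one residue state per class")
        for p, s in self.coupled_pairs:
            if not (1 <= p <= self.l_protease and 1 <= s <= self.l_substrate):
                raise ValueError(f"planted pair ({p}, {s}) outside the blocks")

    @property
    def length(self) -> int:
        return self.l_protease + self.l_substrate

    @property
    def n_classed_states(self) -> int:
        """Residue states carrying a class: the largest multiple of
        n_classes that fits, so every class has the same number of states
        and no class is entropically favored in the sampled mixture."""
        return (self.q - 1) - (self.q - 1) % self.n_classes

    def state_class(self, state: int) -> int:
        """Specificity class of a residue state; -1 for the gap and for
        the classless remainder states (which carry no planted couplings)."""
        if state >= self.n_classed_states:
            return -1
        return state % self.n_classes


def make_ground_truth(spec: GroundTruthSpec) -> PottsModel:
    """Build the planted Potts model (zero gap gauge enforced)."""
    rng = np.random.default_rng(spec.seed)
    L, q = spec.length, spec.q
    fields = np.zeros((L, q))
    fields[:, : q - 1] = rng.normal(0.0, spec.field_scale, size=(L, q - 1))

    # one class-structured table shared by every planted contact
    table = np.zeros((q, q))
    if spec.coupling_scale > 0:
        classes = np.array([spec.state_class(a) for a in range(q - 1)])
        valid = classes >= 0
        both = valid[:, None] & valid[None, :]
        same = classes[:, None] == classes[None, :]
        table[: q - 1, : q - 1] = np.where(
            both, np.where(same, spec.coupling_scale, -spec.coupling_scale), 0.0
        )

    couplings = np.zeros((L, L, q, q))
    for p, s in spec.coupled_pairs:
        i, j = p - 1, spec.l_protease + s - 1
        couplings[i, j] = table
        couplings[j, i] = table.T
    # chain the planted protease positions with the same class-structured
    # table so every row adopts one coherent specificity class; without
    # this the planted contacts would pick their classes independently
    # and "matched pair" would be undefined at the row level
    prot_pos = sorted({p - 1 for p, _ in spec.coupled_pairs})
    for a, b in zip(prot_pos, prot_pos[1:]):
        couplings[a, b] = table
        couplings[b, a] = table.T
    return PottsModel(
        couplings=couplings,
        fields=fields,
        alphabet=Alphabet.reduced(q),
        provenance="ground_truth",
    )


def _row_energies(truth: PottsModel, states: np.ndarray,
                  pairs: list[tuple[int, int]]) -> np.ndarray:
    rows = np.arange(states.shape[0])
    e = np.zeros(states.shape[0])
    for i, j in pairs:
        e -= truth.couplings[i, j][states[:, i], states[:, j]]
    e -= truth.fields[np.arange(truth.length)[None, :], states].sum(axis=1)
    return e


def sample_states(
    truth: PottsModel,
    n_rows: int,
    burn_in: int = 200,
    thin: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Gibbs-sample ``n_rows`` independent chains; returns the state matrix.

    Each row is its own chain: after ``burn_in + thin`` full sweeps
    (one heat-bath update of every position per sweep) the final state
    is taken as the sample, so rows are exactly independent.  The mean
    energy trace is monitored; a drifting tail triggers a convergence
    warning.  Deterministic given the seed.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if burn_in < 1 or thin < 1:
        raise ValueError("burn_in and thin must be >= 1")
    rng = np.random.default_rng(seed)
    L, q = truth.length, truth.q
    states = rng.integers(0, q, size=(n_rows, L))

    # neighbor lists: positions with any nonzero coupling to i
    nonzero = ~np.all(truth.couplings == 0, axis=(2, 3))
    neighbors = [np.flatnonzero(nonzero[i]) for i in range(L)]
    pairs = [(i, j) for i in range(L) for j in neighbors[i] if i < j]

    n_sweeps = burn_in + thin
    trace = np.empty(n_sweeps)
    for sweep in range(n_sweeps):
        for i in range(L):
            cond = np.broadcast_to(truth.fields[i], (n_rows, q)).copy()
            for j in neighbors[i]:
                cond += truth.couplings[i, j][:, states[:, j]].T
            cond -= cond.max(axis=1, keepdims=True)
            p = np.exp(cond)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n_rows)
            states[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        trace[sweep] = _row_energies(truth, states, pairs).mean()

    if n_sweeps >= 8:
        k = n_sweeps // 4
        a, b = trace[-2 * k : -k], trace[-k:]
        se = np.sqrt(a.var(ddof=1) / k + b.var(ddof=1) / k)
        if se > 0 and abs(a.mean() - b.mean()) > 3 * se:
            logger.warning(
                "energy trace still trending after burn-in "
                "(|%.3f - %.3f| > 3 SE); consider more sweeps",
                a.mean(), b.mean(),
            )
    return states


def sample_alignment(
    truth: PottsModel,
    n_rows: int,
    burn_in: int = 200,
    thin: int = 1,
    seed: int = 0,
    l_protease: int | None = None,
    motif_window: tuple[int, int] | None = None,
) -> PairedAlignment:
    """Gibbs-sample a paired alignment (see :func:`sample_states`)."""
    L = truth.length
    if l_protease is None:
        l_protease = L - 7
    if not 0 < l_protease < L:
        raise ValueError("l_protease must split the model into two blocks")
    states = sample_states(truth, n_rows, burn_in, thin, seed)
    alphabet = truth.alphabet
    seqs = ["".join(alphabet.letters[s] for s in row) for row in states]
    ids = [f"org{m:05d}" for m in range(n_rows)]
    l_sub = L - l_protease
    if motif_window is None:
        motif_window = (max(1, l_sub - 6), l_sub)
    protease = AlignedBlock([s[:l_protease] for s in seqs], ids, "protease", alphabet)
    substrate = AlignedBlock([s[l_protease:] for s in seqs], list(ids), "substrate", alphabet)
    return PairedAlignment(protease, substrate, [(m, m) for m in range(n_rows)],
                           motif_window)


@dataclass
class SyntheticEnsemble:
    """Ground truth, sampled alignment and per-row latent class labels."""

    spec: GroundTruthSpec
    truth: PottsModel
    alignment: PairedAlignment
    protease_classes: np.ndarray  # per-row majority class over planted positions
    substrate_classes: np.ndarray


def _majority_class(spec: GroundTruthSpec, states: np.ndarray,
                    positions: np.ndarray) -> np.ndarray:
    """Per-row majority specificity class over the given columns (gap excluded)."""
    n = states.shape[0]
    votes = np.zeros((n, spec.n_classes))
    for pos in positions:
        cls = np.array([spec.state_class(s) for s in states[:, pos]])
        ok = cls >= 0
        votes[np.flatnonzero(ok), cls[ok]] += 1
    return votes.argmax(axis=1)


def make_ensemble(
    spec: GroundTruthSpec = GroundTruthSpec(),
    n_rows: int = 5000,
    burn_in: int = 200,
    seed: int | None = None,
) -> SyntheticEnsemble:
    """Ground truth + sampled alignment + class labels in one call."""
    truth = make_ground_truth(spec)
    aln = sample_alignment(
        truth, n_rows, burn_in=burn_in,
        seed=spec.seed if seed is None else seed,
        l_protease=spec.l_protease,
        motif_window=(max(1, spec.l_substrate - 6), spec.l_substrate),
    )
    X = aln.to_matrix()
    prot_pos = np.unique([p - 1 for p, _ in spec.coupled_pairs])
    sub_pos = np.unique([spec.l_protease + s - 1 for _, s in spec.coupled_pairs])
    return SyntheticEnsemble(
        spec=spec,
        truth=truth,
        alignment=aln,
        protease_classes=_majority_class(spec, X, prot_pos),
        substrate_classes=_majority_class(spec, X, sub_pos),
    )


def recovery_report(
    ensemble: SyntheticEnsemble,
    scorer,
    n_eval: int = 100,
    n_mutation_trials: int = 60,
    rng_seed: int = 1,
) -> dict:
    """How well a fitted scorer recovers the planted structure.

    Returns a dict with

    * ``di_precision`` -- fraction of the top-k inter-block DI pairs
      (k = number of planted contacts) that are planted contacts, from
      the canonical-model direct information;
    * ``matched_auc`` -- AUC of -H_spec separating class-matched from
      class-mismatched protease/substrate row combinations;
    * ``delta_h_sign_agreement`` -- fraction of class-switching
      single-site substrate substitutions whose predicted delta-H sign
      matches the planted direction (toward the protease's class =>
      negative, away => positive).
    """
    spec = ensemble.spec
    aln = ensemble.alignment

    # (a) DI precision at k = number of planted contacts
    di = scorer.dca_.direct_information()
    planted = {(p - 1, spec.l_protease + s - 1) for p, s in spec.coupled_pairs}
    lp = spec.l_protease
    inter = [
        (i, j) for i, j, _ in di.top_pairs if i < lp <= j
    ]
    k = len(planted)
    hits = sum(1 for pair in inter[:k] if pair in planted)
    di_precision = hits / k

    # (b) matched vs mismatched H_spec separation
    rng = np.random.default_rng(rng_seed)
    rows = rng.choice(aln.n_rows, size=min(n_eval, aln.n_rows), replace=False)
    prot_seqs = [aln.protease_block.sequences[aln.pair_index[m][0]] for m in rows]
    sub_seqs = [aln.substrate_block.sequences[aln.pair_index[m][1]] for m in rows]
    H = scorer.score_matrix(prot_seqs, sub_seqs, masked=False)
    pc = ensemble.protease_classes[rows]
    sc = ensemble.substrate_classes[rows]
    matched = (pc[:, None] == sc[None, :]).ravel().astype(int)
    matched_auc = float(roc_auc_score(matched, -H.ravel()))

    # (c) sign of delta-H for class-switching substrate mutations; the
    # planted direction is set by the coupled protease partner position:
    # mutating the substrate residue toward the partner's class lowers
    # the true energy, away from it raises it
    agree = total = 0
    letters = scorer.model_.alphabet.letters
    alphabet = scorer.model_.alphabet
    pair_list = list(spec.coupled_pairs)
    trials = 0
    while total < n_mutation_trials and trials < 50 * n_mutation_trials:
        trials += 1
        m = int(rng.integers(aln.n_rows))
        prot = aln.protease_block.sequences[aln.pair_index[m][0]]
        sub = aln.substrate_block.sequences[aln.pair_index[m][1]]
        p_pos, s_pos = pair_list[int(rng.integers(len(pair_list)))]
        partner_class = spec.state_class(int(alphabet.encode(prot[p_pos - 1])[0]))
        wt_class = spec.state_class(int(alphabet.encode(sub[s_pos - 1])[0]))
        if partner_class < 0 or wt_class < 0:
            continue
        if wt_class == partner_class:
            # mutate away from the partner's class: expect delta-H > 0
            options = [a for a in range(spec.q - 1)
                       if 0 <= spec.state_class(a) != partner_class]
            expected_sign = 1
        else:
            # mutate toward the partner's class: expect delta-H < 0
            options = [a for a in range(spec.q - 1)
                       if spec.state_class(a) == partner_class]
            expected_sign = -1
        to_state = letters[int(rng.choice(options))]
        effects = scorer.mutation_scan(prot, sub, targets=[s_pos], masked=False)
        dh = next(e.delta_h for e in effects if e.to_state == to_state)
        agree += int(np.sign(dh) == expected_sign)
        total += 1
    sign_agreement = agree / total if total else float("nan")

    return {
        "di_precision": di_precision,
        "matched_auc": matched_auc,
        "delta_h_sign_agreement": sign_agreement,
        "n_planted": k,
        "n_eval_rows": len(rows),
        "n_mutation_trials": total,
    }
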