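"""Mean-field direct coupling analysis (mfDCA).

Infers a q-state Potts model -- pairwise couplings e_ij(A, B) and local
fields h_i(A) -- from a multiple sequence alignment by inverting the
connected-correlation matrix of reweighted, pseudocount-regularized
amino-acid frequencies:

    C_ij(A, B) = f_ij(A, B) - f_i(A) f_j(B)
    e_ij(A, B) = -(C^{-1})_ij(A, B)      (on the q-1 non-gauge states)
    h_i(A)     = ln(f_i(A) / f_i(gauge)) - sum_j sum_B e_ij(A, B) f_j(B)

The gauge state is the gap (last alphabet state): every coupling row or
column and every field entry involving the gap is identically zero, so
gap padding contributes nothing to sequence energies.  Sequences are
reweighted by the inverse size of their >= 80% identity neighborhood
(the standard mfDCA scheme) and frequencies are regularized with a
relative pseudocount lambda (default 0.5).

Direct information (DI) ranks position pairs by the mutual information
of the two-site model implied by e_ij alone, with auxiliary fields
iterated so the two-site marginals match the empirical single-site
frequencies; it is the standard contact-map quality check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import PROTEIN, Alphabet
from .msa import AlignedBlock, PairedAlignment

__all__ = [
    "SequenceWeights",
    "FrequencyModel",
    "PottsModel",
    "DirectInformation",
    "MeanFieldDCA",
    "compute_weights",
    "compute_frequencies",
    "fit_potts",
    "direct_information",
]


def _as_matrix(aln) -> tuple[np.ndarray, Alphabet]:
    """Accept a PairedAlignment, AlignedBlock or integer matrix."""
    if isinstance(aln, PairedAlignment):
        return aln.to_matrix(), aln.alphabet
    if isinstance(aln, AlignedBlock):
        return aln.to_matrix(), aln.alphabet
    X = np.asarray(aln)
    if X.ndim != 2:
        raise ValueError("expected a 2-D state matrix")
    return X, None


@dataclass
class SequenceWeights:
    """Per-row identity-based weights; meff is their sum."""

    weights: np.ndarray
    identity_threshold: float

    @property
    def meff(self) -> float:
        return float(self.weights.sum())


@dataclass
class FrequencyModel:
    """Reweighted, pseudocount-regularized single and pairwise frequencies.

    f_i has shape (L, q); f_ij has shape (L, L, q, q) with
    f_ij(A, B) = f_ji(B, A) and the diagonal blocks f_ii(A, B) =
    f_i(A) 1[A = B] (consistent with the pseudocount).
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    pseudocount: float
    q: int


@dataclass
class PottsModel:
    """Couplings and fields of a q-state Potts model in the gap gauge."""

    couplings: np.ndarray  # (L, L, q, q); diagonal blocks zero
    fields: np.ndarray  # (L, q)
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN)
    gauge: str = "gap"
    provenance: str = "canonical"  # canonical | scrambled | ground_truth

    def __post_init__(self):
        L, q = self.fields.shape
        if self.couplings.shape != (L, L, q, q):
            raise ValueError("couplings/fields shape mismatch")
        if q != self.alphabet.q:
            raise ValueError("alphabet size mismatch")

    @property
    def length(self) -> int:
        return self.fields.shape[0]

    @property
    def q(self) -> int:
        return self.fields.shape[1]

    def energy(self, states: np.ndarray) -> float:
        """Full Potts energy H = -sum_{i<j} e_ij(A_i, A_j) - sum_i h_i(A_i).

        Uses every pair of positions; the inter-block restriction used by
        specificity scoring lives in :mod:`coevspec.scoring`.
        """
        states = np.asarray(states)
        L = self.length
        idx = np.arange(L)
        e = self.couplings[idx[:, None], idx[None, :], states[:, None], states[None, :]]
        pair_sum = np.triu(e, k=1).sum()
        return float(-pair_sum - self.fields[idx, states].sum())

    def save(self, path) -> None:
        """Write a .npz container plus a JSON provenance sidecar."""
        path = Path(path)
        np.savez_compressed(
            path,
            couplings=self.couplings,
            fields=self.fields,
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "alphabet": self.alphabet.letters,
                    "gauge": self.gauge,
                    "provenance": self.provenance,
                    "length": self.length,
                    "q": self.q,
                }
            )
        )

    @classmethod
    def load(cls, path) -> "PottsModel":
        path = Path(path)
        data = np.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            couplings=data["couplings"],
            fields=data["fields"],
            alphabet=Alphabet(meta["alphabet"]),
            gauge=meta["gauge"],
            provenance=meta["provenance"],
        )


@dataclass
class DirectInformation:
    """Symmetric DI matrix with a ranked pair list."""

    di: np.ndarray

    @property
    def top_pairs(self) -> list[tuple[int, int, float]]:
        L = self.di.shape[0]
        iu, ju = np.triu_indices(L, k=1)
        order = np.argsort(self.di[iu, ju])[::-1]
        return [(int(iu[k]), int(ju[k]), float(self.di[iu[k], ju[k]])) for k in order]


# ---------------------------------------------------------------------------
# core computations


def compute_weights(aln, identity_threshold: float = 0.8) -> SequenceWeights:
    """Inverse-neighborhood sequence weights.

    w_m = 1 / |{m' : fraction of identical columns(m, m') >= threshold}|,
    where the set includes m itself.  Identity is computed over all
    columns of the concatenated row; the gap counts as a matchable state.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    X, _ = _as_matrix(aln)
    M, L = X.shape
    q = int(X.max()) + 1
    # one-hot matmul gives pairwise identical-column counts in one BLAS call
    onehot = np.zeros((M, L * q), dtype=np.float32)
    onehot[np.arange(M)[:, None], np.arange(L) * q + X] = 1.0
    counts = onehot @ onehot.T
    neighbors = (counts >= identity_threshold * L - 1e-9).sum(axis=1)
    return SequenceWeights(1.0 / neighbors.astype(float), identity_threshold)


def compute_frequencies(
    aln, weights: SequenceWeights | None = None, pseudocount: float = 0.5
) -> FrequencyModel:
    """Weighted frequency counts with a relative pseudocount.

    f_i(A)     = lam/q   + (1 - lam) (1/meff) sum_m w_m 1[A_i^m = A]
    f_ij(A, B) = lam/q^2 + (1 - lam) (1/meff) sum_m w_m 1[A_i^m = A, A_j^m = B]

    for i != j; diagonal blocks are set to f_ii(A, B) = f_i(A) 1[A = B]
    so the connected correlation C_ii is the single-site covariance.
    """
    if not 0 <= pseudocount < 1:
        raise ValueError("pseudocount must be in [0, 1)")
    X, alphabet = _as_matrix(aln)
    M, L = X.shape
    q = alphabet.q if alphabet is not None else int(X.max()) + 1
    if weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(weights.weights, dtype=float)
    meff = w.sum()
    lam = pseudocount

    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    f_i = lam / q + (1 - lam) * np.einsum("m,mia->ia", w, onehot) / meff
    f_ij = lam / q**2 + (1 - lam) * np.einsum(
        "m,mia,mjb->ijab", w, onehot, onehot
    ) / meff
    # diagonal blocks: exact single-site joint, consistent with f_i
    idx = np.arange(L)
    f_ij[idx, idx] = 0.0
    f_ij[idx[:, None], idx[:, None], np.arange(q)[None, :], np.arange(q)[None, :]] = f_i
    return FrequencyModel(f_i=f_i, f_ij=f_ij, pseudocount=lam, q=q)


def fit_potts(
    freqs: FrequencyModel,
    alphabet: Alphabet | None = None,
    provenance: str = "canonical",
) -> PottsModel:
    """Invert the connected-correlation matrix to obtain couplings and fields.

    C is restricted to the first q-1 states of every position (the gap is
    the gauge state) and inverted densely; couplings e_ij = -(C^{-1})_ij
    for i != j are embedded in the gap gauge with zero diagonal blocks.
    Fields follow from the mean-field consistency relation.
    """
    f_i, f_ij, q = freqs.f_i, freqs.f_ij, freqs.q
    L = f_i.shape[0]
    if alphabet is None:
        alphabet = PROTEIN if q == 21 else Alphabet.reduced(q)
    r = q - 1
    C = (
        f_ij[:, :, :r, :r]
        - f_i[:, None, :r, None] * f_i[None, :, None, :r]
    )
    Cm = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        Cinv = np.linalg.inv(Cm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is singular; use a pseudocount > 0"
        ) from exc
    e_small = -Cinv.reshape(L, r, L, r).transpose(0, 2, 1, 3)
    couplings = np.zeros((L, L, q, q))
    couplings[:, :, :r, :r] = e_small
    idx = np.arange(L)
    couplings[idx, idx] = 0.0
    # exact symmetry e_ij(A,B) = e_ji(B,A)
    couplings = 0.5 * (couplings + couplings.transpose(1, 0, 3, 2))

    fields = np.zeros((L, q))
    with np.errstate(divide="ignore"):
        fields[:, :r] = np.log(f_i[:, :r] / f_i[:, -1:])
    mean_coupling = np.einsum("ijab,jb->ia", couplings, f_i)
    fields[:, :r] -= mean_coupling[:, :r]
    return PottsModel(couplings=couplings, fields=fields, alphabet=alphabet,
                      provenance=provenance)


def direct_information(
    model: PottsModel,
    freqs: FrequencyModel,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> DirectInformation:
    """Direct information of every position pair.

    For each pair, the two-site direct distribution
    P^dir(A, B) ∝ exp(e_ij(A, B)) mu_i(A) mu_j(B) is computed with the
    auxiliary single-site factors mu iterated to match the empirical
    marginals f_i, f_j; DI is its Kullback-Leibler divergence from the
    factorized product f_i f_j.
    """
    if model.length != freqs.f_i.shape[0] or model.q != freqs.q:
        raise ValueError("model and frequencies disagree on L or q")
    L, q = model.length, model.q
    f_i = freqs.f_i
    di = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            W = np.exp(model.couplings[i, j])
            mu1 = np.full(q, 1.0 / q)
            mu2 = np.full(q, 1.0 / q)
            for _ in range(max_iter):
                new1 = f_i[i] / (W @ mu2)
                new1 /= new1.sum()
                new2 = f_i[j] / (W.T @ new1)
                new2 /= new2.sum()
                delta = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
                mu1, mu2 = new1, new2
                if delta < tol:
                    break
            else:
                raise RuntimeError(
                    f"two-site marginal matching did not converge for pair ({i}, {j})"
                )
            pdir = W * np.outer(mu1, mu2)
            pdir /= pdir.sum()
            ref = np.outer(f_i[i], f_i[j])
            mask = pdir > 0
            di[i, j] = di[j, i] = float(
                (pdir[mask] * np.log(pdir[mask] / ref[mask])).sum()
            )
    return DirectInformation(di=np.maximum(di, 0.0))


def write_di_table(di: DirectInformation, path) -> None:
    """TSV of (i, j, DI) sorted by DI descending; positions 1-based."""
    with open(path, "w") as fh:
        fh.write("i\tj\tdi\n")
        for i, j, v in di.top_pairs:
            fh.write(f"{i + 1}\t{j + 1}\t{v:.10g}\n")


class MeanFieldDCA(BaseEstimator):
    """Potts-model inference from an alignment by mean-field DCA.

    Parameters
    ----------
    pseudocount : float, default=0.5
        Relative weight lambda of the uniform prior on frequencies.
    identity_threshold : float, default=0.8
        Rows at or above this fractional identity share weight.
    reweight : bool, default=True
        Disable to use uniform sequence weights.

    Attributes
    ----------
    weights_ : SequenceWeights
    meff_ : float
    frequencies_ : FrequencyModel
    model_ : PottsModel
    couplings_, fields_ : ndarray views of the fitted model
    """

    def __init__(self, pseudocount: float = 0.5, identity_threshold: float = 0.8,
                 reweight: bool = True):
        self.pseudocount = pseudocount
        self.identity_threshold = identity_threshold
        self.reweight = reweight

    def fit(self, X, y=None, provenance: str = "canonical"):
        mat, alphabet = _as_matrix(X)
        if self.reweight:
            self.weights_ = compute_weights(mat, self.identity_threshold)
        else:
            self.weights_ = SequenceWeights(np.ones(mat.shape[0]), 1.0)
        self.meff_ = self.weights_.meff
        q = alphabet.q if alphabet is not None else int(mat.max()) + 1
        if alphabet is None:
            alphabet = PROTEIN if q == 21 else Alphabet.reduced(q)
        freqs = compute_frequencies(mat, self.weights_, self.pseudocount)
        freqs.q = q
        if freqs.f_i.shape[1] != q:
            # state matrix may not exercise the full alphabet; re-count with q
            freqs = self._frequencies_with_q(mat, q)
        self.frequencies_ = freqs
        self.model_ = fit_potts(freqs, alphabet, provenance=provenance)
        self.couplings_ = self.model_.couplings
        self.fields_ = self.model_.fields
        return self

    def _frequencies_with_q(self, mat: np.ndarray, q: int) -> FrequencyModel:
        padded = np.vstack([mat, np.full((1, mat.shape[1]), q - 1, dtype=mat.dtype)])
        w = np.concatenate([self.weights_.weights, [0.0]])
        return compute_frequencies(
            padded, SequenceWeights(w, self.weights_.identity_threshold),
            self.pseudocount,
        )

    def direct_information(self) -> DirectInformation:
        return direct_information(self.model_, self.frequencies_)
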