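"""Orthogonality matrices and their comparison with experimental readouts.

A protease x substrate score grid (H_spec predictions or measured
cleavage fluorescence) supports a small set of transforms -- clipping,
sign inversion, cognate (diagonal) normalization -- plus three
comparison statistics:

* Pearson correlation between flattened prediction and readout grids;
* ROC analysis of the predictor against thresholded readout labels
  (trapezoidal AUC, Youden's J optimal cutoff);
* DeltaCon similarity between the bipartite protease-substrate graphs
  induced by two grids (fast-belief-propagation node affinities,
  Matusita distance, similarity = 1 / (1 + d)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "OrthogonalityMatrix",
    "RocResult",
    "DeltaConResult",
    "build_matrix",
    "transform_matrix",
    "cognate_normalize",
    "correlate",
    "roc_analysis",
    "deltacon_similarity",
    "prepare_edge_weights",
    "similarity_from_distance",
]

#: clip range applied to masked H_spec before graph / readout comparison
DEFAULT_CLIP = (-180.0, -80.0)


@dataclass
class OrthogonalityMatrix:
    """P x S score grid with labels and a record of applied transforms."""

    values: np.ndarray
    protease_ids: list[str]
    substrate_ids: list[str]
    kind: str = "h_spec"  # h_spec | fluorescence
    transform_state: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protease_ids), len(self.substrate_ids)):
            raise ValueError("matrix shape does not match id lists")
        if self.kind not in ("h_spec", "fluorescence"):
            raise ValueError(f"kind must be 'h_spec' or 'fluorescence', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protease_ids, columns=self.substrate_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="protease")

    @classmethod
    def from_tsv(cls, path, kind: str = "fluorescence") -> "OrthogonalityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(i) for i in df.index],
                   [str(c) for c in df.columns], kind)


def build_matrix(model, proteases, substrates, masked: bool = True,
                 protease_ids=None, substrate_ids=None) -> OrthogonalityMatrix:
    """H_spec orthogonality matrix for every protease x substrate pair."""
    from .scoring import score_matrix

    proteases = list(proteases)
    substrates = list(substrates)
    values = score_matrix(model, proteases, substrates, masked)
    return OrthogonalityMatrix(
        values,
        list(protease_ids) if protease_ids is not None
        else [f"protease{i + 1}" for i in range(len(proteases))],
        list(substrate_ids) if substrate_ids is not None
        else [f"substrate{j + 1}" for j in range(len(substrates))],
        kind="h_spec",
    )


def transform_matrix(
    m: OrthogonalityMatrix,
    clip: tuple[float, float] | None = None,
    sign_invert: bool = False,
) -> OrthogonalityMatrix:
    """Clip to [lo, hi] and/or multiply by -1 (inversion applied after clipping)."""
    values = m.values.copy()
    state = list(m.transform_state)
    if clip is not None:
        lo, hi = clip
        if lo >= hi:
            raise ValueError(f"clip bounds must satisfy lo < hi, got {clip}")
        values = np.clip(values, lo, hi)
        state.append(f"clipped({lo:g},{hi:g})")
    if sign_invert:
        values = -values
        state.append("sign_inverted")
    return replace(m, values=values, transform_state=state)


def cognate_normalize(m: OrthogonalityMatrix) -> OrthogonalityMatrix:
    """Divide each row by its diagonal (cognate) entry.

    Requires a square grid whose diagonal pairs protease i with its
    putative native substrate; the output diagonal is exactly 1.
    """
    P, S = m.shape
    if P != S:
        raise ValueError(f"cognate normalization needs a square matrix, got {P}x{S}")
    diag = np.diag(m.values)
    zero = np.flatnonzero(diag == 0)
    if zero.size:
        raise ValueError(
            f"zero cognate score for protease {m.protease_ids[zero[0]]!r}"
        )
    values = m.values / diag[:, None]
    return replace(
        m, values=values, transform_state=m.transform_state + ["cognate_normalized"]
    )


def correlate(
    pred: OrthogonalityMatrix, obs: OrthogonalityMatrix, tail: str = "two"
) -> tuple[float, float]:
    """Pearson r between flattened grids with an exact t-based p-value."""
    if pred.shape != obs.shape:
        raise ValueError("matrices must share shape")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    x = pred.values.ravel()
    y = obs.values.ravel()
    if tail == "two":
        r, p = stats.pearsonr(x, y)
    else:
        # one-tailed in the direction of the observed correlation
        r, p2 = stats.pearsonr(x, y)
        p = p2 / 2.0
    return float(r), float(p)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "youden_j": self.youden_j,
            "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        }


def roc_analysis(
    scores: OrthogonalityMatrix,
    readout: OrthogonalityMatrix,
    positive_threshold: float = 0.1,
) -> RocResult:
    """ROC of the score grid against readout-derived cleaving labels.

    Labels are ``readout >= positive_threshold``.  Raw (untransformed)
    H_spec grids are sign-inverted internally so that larger scores mean
    the positive class; already sign-inverted or cognate-normalized
    grids are used as-is.  The Youden-optimal threshold maximizes
    TPR - FPR, ties broken toward the lower FPR.
    """
    if scores.shape != readout.shape:
        raise ValueError("score and readout matrices must share shape")
    y_true = (readout.values.ravel() >= positive_threshold).astype(int)
    if y_true.min() == y_true.max():
        raise ValueError("readout labels are single-class; AUC is undefined")
    x = scores.values.ravel()  # row-major flattening
    raw_h_spec = scores.kind == "h_spec" and not any(
        t == "sign_inverted" or t == "cognate_normalized"
        for t in scores.transform_state
    )
    if raw_h_spec:
        x = -x
    fpr, tpr, thr = _roc_curve(y_true, x, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best = best[np.argmin(fpr[best])]
    cut = float(thr[best])
    pred_pos = x >= cut
    tp = int(np.sum(pred_pos & (y_true == 1)))
    fp = int(np.sum(pred_pos & (y_true == 0)))
    tn = int(np.sum(~pred_pos & (y_true == 0)))
    fn = int(np.sum(~pred_pos & (y_true == 1)))
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=area,
        youden_threshold=cut,
        youden_j=float(j[best]),
        confusion=(tp, fp, tn, fn),
    )


@dataclass
class DeltaConResult:
    similarity: float
    matusita_distance: float
    seed: int
    g: int
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "similarity": self.similarity,
            "matusita_distance": self.matusita_distance,
            "seed": self.seed,
            "g": self.g,
            "epsilon": self.epsilon,
        }


def similarity_from_distance(d: float) -> float:
    """DeltaCon similarity transform: sim = 1 / (1 + d)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + d)


def prepare_edge_weights(
    m: OrthogonalityMatrix,
    clip: tuple[float, float] | None = DEFAULT_CLIP,
    normalization: str = "minmax",
) -> OrthogonalityMatrix:
    """Turn an H_spec grid into non-negative graph edge weights.

    Raw H_spec is clipped (default [-180, -80]), sign-inverted, then
    min-max rescaled to [0, 1].  Fluorescence grids skip the clip and
    inversion.  ``normalization`` is one of {"minmax", "none"}.
    """
    if normalization not in ("minmax", "none"):
        raise ValueError("normalization must be 'minmax' or 'none'")
    if m.kind == "h_spec" and "sign_inverted" not in m.transform_state:
        m = transform_matrix(m, clip=clip, sign_invert=True)
    values = m.values
    state = list(m.transform_state)
    if normalization == "minmax":
        lo, hi = values.min(), values.max()
        if hi > lo:
            values = (values - lo) / (hi - lo)
        else:
            values = np.zeros_like(values)
        state.append("minmax_normalized")
    return replace(m, values=values, transform_state=state)


def deltacon_similarity(
    m1: OrthogonalityMatrix,
    m2: OrthogonalityMatrix,
    seed: int = 42,
    g: int = 20,
    epsilon: float = 0.01,
) -> DeltaConResult:
    """DeltaCon similarity of the bipartite graphs induced by two grids.

    Each protease and substrate is a node (P + S nodes, P*S weighted
    edges).  Node affinities come from fast belief propagation,
    S = (I + eps^2 D - eps A)^{-1} B, where B holds g random node groups
    drawn from the seeded generator (with g >= n this is the exact
    one-hot identity).  The Matusita (root Euclidean) distance between
    the two affinity matrices maps to similarity = 1 / (1 + d).
    """
    if m1.shape != m2.shape:
        raise ValueError("matrices must share shape for graph comparison")
    if m1.protease_ids != m2.protease_ids or m1.substrate_ids != m2.substrate_ids:
        raise ValueError("matrices must share node labels")
    for name, m in (("first", m1), ("second", m2)):
        if (m.values < 0).any():
            raise ValueError(
                f"{name} matrix has negative edge weights; apply "
                "prepare_edge_weights (clip + sign inversion + rescale) first"
            )
    P, S = m1.shape
    n = P + S
    rng = np.random.default_rng(seed)
    if g >= n:
        B = np.eye(n)
        g_eff = n
    else:
        groups = rng.integers(0, g, size=n)
        B = np.zeros((n, g))
        B[np.arange(n), groups] = 1.0
        g_eff = g
    affinities = []
    for m in (m1, m2):
        A = np.zeros((n, n))
        A[:P, P:] = m.values
        A[P:, :P] = m.values.T
        D = np.diag(A.sum(axis=1))
        M = np.eye(n) + epsilon**2 * D - epsilon * A
        affinities.append(np.linalg.solve(M, B))
    S1, S2 = affinities
    # affinities are non-negative for small epsilon; clamp tiny negatives
    S1 = np.clip(S1, 0.0, None)
    S2 = np.clip(S2, 0.0, None)
    d = float(np.sqrt(np.sum((np.sqrt(S1) - np.sqrt(S2)) ** 2)))
    return DeltaConResult(
        similarity=similarity_from_distance(d),
        matusita_distance=d,
        seed=seed,
        g=g_eff,
        epsilon=epsilon,
    )
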