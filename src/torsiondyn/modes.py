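"""Spatiotemporal PCA of angular displacements and activation-pattern analysis.

The displacement matrix X (T-1 frames x n angles) is decomposed by SVD,
X = U S V^T: columns of V are spatial principal components (which angles move
together), columns of U S are temporal scores y_k (when they move), and
lambda_j = S_jj^2 is the variance captured by mode j.  The temporal scores
are thresholded to keep only the largest-amplitude collective events, each
frame is labelled by which modes are active, and the label sequence is
summarized by a transition-frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .torus import DisplacementTrajectory

__all__ = [
    "ModeDecomposition",
    "ActivationSequence",
    "TransitionMatrix",
    "DisplacementPCA",
    "fit_pca",
    "select_component_count",
    "subspace_overlap",
    "threshold_scores",
    "label_activity",
    "transition_frequency_matrix",
    "compare_transition_matrices",
    "subspace_convergence",
]


@dataclass
class ModeDecomposition:
    """Result of the spatiotemporal SVD of a displacement matrix."""

    spatial_components: NDArray[np.float64]  # n x r, orthonormal columns of V
    temporal_scores: NDArray[np.float64]  # (T-1) x r, columns y_k = U S
    variances: NDArray[np.float64]  # lambda_j = S_jj^2, descending
    total_variance: float
    centering_offset: NDArray[np.float64]

    @property
    def explained_ratio(self) -> NDArray[np.float64]:
        if self.total_variance <= 0:
            return np.zeros_like(self.variances)
        return self.variances / self.total_variance


def _as_matrix(X: ArrayLike) -> NDArray[np.float64]:
    if isinstance(X, DisplacementTrajectory):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-d data matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    return X


class DisplacementPCA(TransformerMixin, BaseEstimator):
    """PCA of angular-displacement time series via SVD.

    Parameters
    ----------
    n_components : int or None
        Number of modes to retain; None keeps all min(T-1, n).
    center : bool, default True
        Subtract the column mean before the SVD.  Displacements are
        near-zero-mean by construction, so this is innocuous but makes the
        variance bookkeeping exact.

    Attributes
    ----------
    components_ : (n, r) ndarray
        Orthonormal spatial modes (columns of V).  Sign fixed so the
        largest-magnitude loading of each mode is positive.
    scores_ : (T-1, r) ndarray
        Temporal scores y_k = U S of the training data.
    variances_ : (r,) ndarray
        Squared singular values, descending.
    total_variance_ : float
        Squared Frobenius norm of the centered data.
    mean_ : (n,) ndarray
        Column offset removed before the SVD (zeros when ``center=False``).
    """

    def __init__(self, n_components: int | None = None, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X: ArrayLike, y=None) -> "DisplacementPCA":
        X = _as_matrix(X)
        T, n = X.shape
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(n)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest |loading| of each spatial mode positive
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        U = U * flip[None, :]
        r = min(self.n_components, s.size) if self.n_components else s.size
        self.components_ = Vt[:r].T
        self.scores_ = U[:, :r] * s[:r]
        self.variances_ = s[:r] ** 2
        self.total_variance_ = float(np.sum(Xc**2))
        self.n_features_in_ = n
        return self

    def transform(self, X: ArrayLike) -> NDArray[np.float64]:
        """Project displacements onto the fitted modes: y_t = (chi_t - mean) V."""
        check_is_fitted(self, "components_")
        return (_as_matrix(X) - self.mean_) @ self.components_

    def inverse_transform(self, Y: ArrayLike) -> NDArray[np.float64]:
        """Lift reduced coordinates back to displacement space via V^T."""
        check_is_fitted(self, "components_")
        return np.asarray(Y, dtype=np.float64) @ self.components_.T + self.mean_

    @property
    def explained_variance_ratio_(self) -> NDArray[np.float64]:
        check_is_fitted(self, "variances_")
        if self.total_variance_ <= 0:
            return np.zeros_like(self.variances_)
        return self.variances_ / self.total_variance_

    def to_decomposition(self) -> ModeDecomposition:
        check_is_fitted(self, "components_")
        return ModeDecomposition(
            spatial_components=self.components_,
            temporal_scores=self.scores_,
            variances=self.variances_,
            total_variance=self.total_variance_,
            centering_offset=self.mean_,
        )


def fit_pca(X: ArrayLike, center: bool = True) -> ModeDecomposition:
    """Full-rank spatiotemporal PCA of a displacement matrix (thin wrapper)."""
    return DisplacementPCA(center=center).fit(X).to_decomposition()


def select_component_count(
    decomposition: ModeDecomposition | DisplacementPCA,
    variance_target: float = 0.80,
) -> int:
    """Smallest r whose cumulative variance share reaches ``variance_target``."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    if isinstance(decomposition, DisplacementPCA):
        decomposition = decomposition.to_decomposition()
    shares = np.cumsum(decomposition.explained_ratio)
    idx = np.searchsorted(shares, variance_target - 1e-12)
    return int(min(idx + 1, decomposition.variances.size))


def subspace_overlap(V_partial: ArrayLike, V_full: ArrayLike) -> float:
    """Normalized subspace overlap S = ||V_partial^T V_full||_F^2 / r in [0, 1].

    Equals 1 when the two r-dimensional subspaces coincide, 0 when they are
    mutually orthogonal.
    """
    A = np.asarray(V_partial, dtype=np.float64)
    B = np.asarray(V_full, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("bases must have identical shapes")
    for M, name in ((A, "V_partial"), (B, "V_full")):
        gram = M.T @ M
        if not np.allclose(gram, np.eye(M.shape[1]), atol=1e-8):
            raise ValueError(f"{name} must have orthonormal columns")
    r = A.shape[1]
    return float(np.sum((A.T @ B) ** 2) / r)


def threshold_scores(
    scores: ArrayLike, keep_percent: float | ArrayLike = 5.0
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Keep only the largest-amplitude lambda_k % of each temporal mode.

    Per mode k the threshold eps_k is the (100 - lambda_k)-th percentile of
    |y_k| (linear interpolation); entries with |y| > eps_k are preserved, the
    rest are zeroed.  Returns ``(filtered_scores, thresholds)``.
    """
    Y = _as_matrix(scores)
    keep = np.broadcast_to(
        np.asarray(keep_percent, dtype=np.float64), (Y.shape[1],)
    ).copy()
    if np.any(keep < 0) or np.any(keep > 100):
        raise ValueError("keep_percent must lie in [0, 100]")
    eps = np.array(
        [np.percentile(np.abs(Y[:, k]), 100.0 - keep[k]) for k in range(Y.shape[1])]
    )
    filtered = np.where(np.abs(Y) > eps[None, :], Y, 0.0)
    # keep_percent = 100 keeps everything even when the min |y| ties eps
    filtered[:, keep >= 100.0] = Y[:, keep >= 100.0]
    return filtered, eps


def label_activity(filtered_scores: ArrayLike, r: int | None = None) -> NDArray[np.int64]:
    """Discrete activation label per frame from thresholded scores.

    0 when no mode is active, k (1-based) when exactly mode k is active,
    r+1 when two or more modes are simultaneously active.
    """
    F = _as_matrix(filtered_scores)
    if r is None:
        r = F.shape[1]
    if F.shape[1] != r:
        raise ValueError("filtered scores must have r columns")
    active = F != 0.0
    n_active = active.sum(axis=1)
    labels = np.zeros(F.shape[0], dtype=np.int64)
    one = n_active == 1
    labels[one] = np.argmax(active[one], axis=1) + 1
    labels[n_active >= 2] = r + 1
    return labels


@dataclass
class TransitionMatrix:
    """Row-normalized label-succession frequencies with raw counts."""

    probabilities: NDArray[np.float64]
    counts: NDArray[np.int64]

    @property
    def n_states(self) -> int:
        return self.probabilities.shape[0]

    @property
    def empty_rows(self) -> NDArray[np.bool_]:
        return self.counts.sum(axis=1) == 0


def transition_frequency_matrix(
    labels: ArrayLike, n_states: int | None = None
) -> TransitionMatrix:
    """Count label successions l_t -> l_{t+1} and row-normalize.

    ``n_states`` fixes the matrix size |S| (labels run 0..n_states-1);
    defaults to max(label)+1.  Rows never visited stay all-zero and are
    flagged via :attr:`TransitionMatrix.empty_rows`.
    """
    lab = np.asarray(labels, dtype=np.int64).ravel()
    if lab.size < 2:
        raise ValueError("need at least 2 labels to count transitions")
    if np.any(lab < 0):
        raise ValueError("labels must be non-negative")
    S = int(n_states) if n_states is not None else int(lab.max()) + 1
    if np.any(lab >= S):
        raise ValueError("label exceeds declared state count")
    counts = np.zeros((S, S), dtype=np.int64)
    np.add.at(counts, (lab[:-1], lab[1:]), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return TransitionMatrix(probabilities=probs, counts=counts)


def compare_transition_matrices(
    P_a: TransitionMatrix | ArrayLike,
    P_b: TransitionMatrix | ArrayLike,
    pseudo_count: float = 1e-12,
) -> tuple[float, float, float]:
    """Similarity of two transition matrices: (Frobenius, row-wise KL, Pearson).

    Frobenius distance of the probability matrices; mean over rows of
    KL(row_a || row_b) with pseudo-count regularization (rows empty in either
    matrix are skipped); Pearson correlation of the flattened matrices.
    """
    A = P_a.probabilities if isinstance(P_a, TransitionMatrix) else np.asarray(P_a, float)
    B = P_b.probabilities if isinstance(P_b, TransitionMatrix) else np.asarray(P_b, float)
    if A.shape != B.shape:
        raise ValueError("transition matrices must have the same shape")
    frob = float(np.linalg.norm(A - B))
    kls = []
    for ra, rb in zip(A, B):
        if ra.sum() == 0 or rb.sum() == 0:
            continue
        pa = ra + pseudo_count
        pb = rb + pseudo_count
        pa = pa / pa.sum()
        pb = pb / pb.sum()
        kls.append(float(np.sum(pa * np.log(pa / pb))))
    kl = float(np.mean(kls)) if kls else 0.0
    if A.ravel().std() == 0 or B.ravel().std() == 0:
        pearson = float("nan")  # correlation undefined for a constant matrix
    else:
        pearson = float(stats.pearsonr(A.ravel(), B.ravel())[0])
    return frob, kl, pearson


def subspace_convergence(
    X: ArrayLike,
    r: int = 5,
    n_checkpoints: int = 20,
    min_fraction: float = 0.05,
    center: bool = True,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Overlap S(t) of prefix-PCA subspaces with the full-data subspace.

    Mirrors the convergence diagnostic used to decide whether the dominant
    displacement subspace has stabilized: for growing prefixes of the data
    the leading-r spatial components are compared with those of the full
    matrix.  Returns ``(prefix_lengths, overlaps)``.
    """
    X = _as_matrix(X)
    T = X.shape[0]
    r = min(r, X.shape[1])
    V_full = DisplacementPCA(n_components=r, center=center).fit(X).components_
    lengths = np.unique(
        np.linspace(max(int(min_fraction * T), r + 1, 10), T, n_checkpoints).astype(int)
    )
    overlaps = np.array(
        [
            subspace_overlap(
                DisplacementPCA(n_components=r, center=center).fit(X[:t]).components_,
                V_full,
            )
            for t in lengths
        ]
    )
    return lengths, overlaps
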