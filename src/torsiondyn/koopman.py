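"""Koopman operator estimation and VAMP-2 scoring of observable time series.

The dynamics of a (generally nonlinear) system are approximated linearly in
a chosen observable space zeta (raw angles theta, displacements chi, the
sin-cos embedding, or reduced PCA coordinates y):

    E[zeta_{t+tau}] ~ K^T E[zeta_t]

K is the least-squares solution K = C00^{-1} C01, where C00, C01 and C11 are
the mean-removed instantaneous, time-lagged cross- and lagged covariance
matrices.  The whitened operator C00^{-1/2} C01 C11^{-1/2} has singular
value decomposition U' L V'^T, from which the singular functions
Psi = C00^{-1/2} U' and Phi = C11^{-1/2} V' follow.  The VAMP-2 score
1 + sum_i L_i^2 measures the slow dynamical variance a feature set retains
at the chosen lag (the leading 1 accounts for the constant function).

One-step prediction uses

    zeta_hat_{t+tau} = (Phi^T)^+ L Psi^T (zeta_t - mu0) + mut

with the Moore-Penrose pseudo-inverse at the truncated rank, optionally
rescaled so the Frobenius norm of the prediction matches the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LaggedCovariances",
    "KoopmanModel",
    "KoopmanRegressor",
    "lagged_covariances",
    "estimate_koopman",
    "vamp2_score",
    "predict_one_step",
    "optimal_scale",
    "reduce_to_subspace",
]


@dataclass
class LaggedCovariances:
    """Mean-removed instantaneous and time-lagged covariance matrices."""

    C00: NDArray[np.float64]
    C01: NDArray[np.float64]
    C11: NDArray[np.float64]
    mu0: NDArray[np.float64]
    mut: NDArray[np.float64]
    lag: int
    sample_count: int


@dataclass
class KoopmanModel:
    """Fitted Koopman matrix with its whitened singular decomposition."""

    covariances: LaggedCovariances
    K: NDArray[np.float64]
    singular_values: NDArray[np.float64]
    left_functions: NDArray[np.float64]  # Psi, d x rank
    right_functions: NDArray[np.float64]  # Phi, d x rank
    rank: int
    regularization_floor: float

    @property
    def dim(self) -> int:
        return self.K.shape[0]


def _as_series(Z: ArrayLike) -> NDArray[np.float64]:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.ndim != 2:
        raise ValueError("expected a T x d time series")
    if not np.all(np.isfinite(Z)):
        raise ValueError("series must be finite")
    return Z


def lagged_covariances(Z: ArrayLike, lag: int = 1) -> LaggedCovariances:
    """Empirical C00, C01, C11 from the T - lag (instantaneous, lagged) pairs."""
    Z = _as_series(Z)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if Z.shape[0] <= lag:
        raise ValueError("need more frames than the lag")
    Z0 = Z[:-lag]
    Z1 = Z[lag:]
    mu0 = Z0.mean(axis=0)
    mut = Z1.mean(axis=0)
    A = Z0 - mu0
    B = Z1 - mut
    N = Z0.shape[0]
    C00 = (A.T @ A) / N
    C01 = (A.T @ B) / N
    C11 = (B.T @ B) / N
    C00 = 0.5 * (C00 + C00.T)
    C11 = 0.5 * (C11 + C11.T)
    return LaggedCovariances(
        C00=C00, C01=C01, C11=C11, mu0=mu0, mut=mut, lag=lag, sample_count=N
    )


def _floored_powers(
    C: NDArray[np.float64], floor: float
) -> tuple[NDArray[np.float64], NDArray[np.float64], int]:
    """(C^+, C^{-1/2}) with eigenvalues below ``floor`` truncated; returns rank."""
    w, Q = np.linalg.eigh(C)
    keep = w > floor
    rank = int(keep.sum())
    Qk = Q[:, keep]
    wk = w[keep]
    inv = (Qk / wk) @ Qk.T
    inv_sqrt = (Qk / np.sqrt(wk)) @ Qk.T
    return inv, inv_sqrt, rank


def estimate_koopman(
    cov: LaggedCovariances, floor_scale: float = 1e-10
) -> KoopmanModel:
    """Koopman matrix K = C00^{-1} C01 and its whitened SVD.

    Eigenvalues of C00/C11 below ``floor_scale * trace`` are truncated before
    (pseudo-)inversion; features with zero variance are thereby dropped from
    the singular decomposition with a warning.
    """
    d = cov.C00.shape[0]
    floor0 = floor_scale * max(np.trace(cov.C00), np.finfo(float).tiny)
    floor1 = floor_scale * max(np.trace(cov.C11), np.finfo(float).tiny)
    inv00, inv_sqrt00, rank0 = _floored_powers(cov.C00, floor0)
    _, inv_sqrt11, rank1 = _floored_powers(cov.C11, floor1)
    if rank0 < d or rank1 < d:
        warnings.warn(
            f"covariance rank deficient ({rank0}/{rank1} of {d}); "
            "zero-variance directions dropped",
            stacklevel=2,
        )
    K = inv00 @ cov.C01
    M = inv_sqrt00 @ cov.C01 @ inv_sqrt11
    U, s, Vt = np.linalg.svd(M)
    rank = min(rank0, rank1)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    return KoopmanModel(
        covariances=cov,
        K=K,
        singular_values=s,
        left_functions=inv_sqrt00 @ U,
        right_functions=inv_sqrt11 @ Vt.T,
        rank=rank,
        regularization_floor=floor_scale,
    )


def vamp2_score(Z: ArrayLike, lag: int = 1, floor_scale: float = 1e-10) -> float:
    """VAMP-2 score 1 + sum_i Lambda_i^2 of a feature series at the given lag.

    Computed from mean-removed covariances; the explicit "+1" accounts for
    the constant singular function, so uncorrelated noise scores ~ 1 and d
    perfectly predictable nonconstant features score 1 + d.  Invariant under
    invertible affine re-featurization.
    """
    model = estimate_koopman(lagged_covariances(Z, lag), floor_scale=floor_scale)
    return 1.0 + float(np.sum(model.singular_values**2))


def predict_one_step(model: KoopmanModel, z_t: ArrayLike) -> NDArray[np.float64]:
    """Single-step forecast zeta_hat = (Phi^T)^+ L Psi^T (zeta_t - mu0) + mut.

    ``z_t`` may be a single d-vector or a batch of rows; the output matches.
    """
    check_model = model.rank
    if check_model == 0:
        raise ValueError("degenerate model: rank 0")
    z = np.asarray(z_t, dtype=np.float64)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    if Z.shape[1] != model.dim:
        raise ValueError("input dimension does not match the model")
    cov = model.covariances
    propagator = np.linalg.pinv(model.right_functions.T) @ (
        model.singular_values[:, None] * model.left_functions.T
    )
    out = (Z - cov.mu0) @ propagator.T + cov.mut
    return out[0] if single else out


def optimal_scale(prediction: ArrayLike, reference: ArrayLike) -> float:
    """Scaling alpha = ||reference||_F / ||prediction||_F matching the norms."""
    pred = np.asarray(prediction, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    p = np.linalg.norm(pred)
    if p == 0:
        raise ValueError("prediction has zero norm; scale undefined")
    return float(np.linalg.norm(ref) / p)


def reduce_to_subspace(model: KoopmanModel | ArrayLike, V: ArrayLike) -> NDArray[np.float64]:
    """Induced operator K_y = V^T K V in the reduced PCA subspace.

    For y_t = chi_t V with orthonormal V, a linear model in chi space induces
    a consistent linear model in y space.
    """
    K = model.K if isinstance(model, KoopmanModel) else np.asarray(model, float)
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] != K.shape[0]:
        raise ValueError("V must be n x r with n matching the model dimension")
    if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8):
        raise ValueError("V must have orthonormal columns")
    return V.T @ K @ V


class KoopmanRegressor(BaseEstimator):
    """Scikit-learn-style estimator for linear Koopman one-step prediction.

    Fit on a T x d observable time series; ``predict`` maps observables at
    time t to their forecast at t + lag.

    Parameters
    ----------
    lag : int, default 1
        Lag in frames between instantaneous and future observables.
    floor_scale : float, default 1e-10
        Relative eigenvalue floor (fraction of the covariance trace) for the
        regularized inversions.

    Attributes
    ----------
    model_ : KoopmanModel
        Fitted covariances, Koopman matrix and whitened SVD.
    koopman_matrix_ : (d, d) ndarray
        K = C00^{-1} C01.
    singular_values_ : ndarray
        Whitened singular values, descending.
    """

    def __init__(self, lag: int = 1, floor_scale: float = 1e-10):
        self.lag = lag
        self.floor_scale = floor_scale

    def fit(self, X: ArrayLike, y=None) -> "KoopmanRegressor":
        Z = _as_series(X)
        cov = lagged_covariances(Z, lag=self.lag)
        self.model_ = estimate_koopman(cov, floor_scale=self.floor_scale)
        self.koopman_matrix_ = self.model_.K
        self.singular_values_ = self.model_.singular_values
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        check_is_fitted(self, "model_")
        return predict_one_step(self.model_, X)

    def score(self, X: ArrayLike, y=None) -> float:
        """VAMP-2 score of held-out data under this estimator's lag."""
        return vamp2_score(X, lag=self.lag, floor_scale=self.floor_scale)
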