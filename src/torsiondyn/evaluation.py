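"""Evaluation of angular predictions: torus metrics and structural RMSD.

Predicted angles are compared to reference angles with the geodesic metric
on the n-torus, normalized so that the worst case (every component
antipodal) scores 1.  Structural fidelity is assessed by rebuilding
backbone coordinates from the angles and computing RMSD after optimal
rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .koopman import KoopmanRegressor, optimal_scale, predict_one_step
from .modes import DisplacementPCA
from .torus import AngleTrajectory, displacement, embed_sincos, wrap_to_interval

__all__ = [
    "ErrorReport",
    "angular_distance",
    "frame_relative_error",
    "mean_error_vs_lag",
    "kabsch_superpose",
    "rmsd",
    "RepresentationPredictor",
]


@dataclass
class ErrorReport:
    """Per-frame relative angular errors for one representation and lag."""

    per_frame_error: NDArray[np.float64]
    mean_error: float
    lag: int
    representation_tag: str

    def __post_init__(self) -> None:
        self.per_frame_error = np.asarray(self.per_frame_error, dtype=np.float64)


def angular_distance(a: ArrayLike, b: ArrayLike) -> NDArray[np.float64] | float:
    """Shortest arc between two angles on the circle, degrees in [0, 180]."""
    diff = np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    diff = np.mod(diff, 360.0)
    out = np.minimum(diff, 360.0 - diff)
    if out.ndim == 0:
        return float(out)
    return out


def frame_relative_error(pred: ArrayLike, ref: ArrayLike) -> float:
    """Normalized torus distance e = ||d(theta_j, theta_hat_j)||_2 / (180 sqrt(n)).

    0 for a perfect prediction, 1 when every component is antipodal.
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    ref = np.asarray(ref, dtype=np.float64).ravel()
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must have equal length")
    d = np.asarray(angular_distance(pred, ref))
    n = pred.size
    return float(np.linalg.norm(d) / (180.0 * np.sqrt(n)))


class RepresentationPredictor:
    """One-step angle forecasting through a chosen observable representation.

    Wraps a :class:`~torsiondyn.koopman.KoopmanRegressor` fitted on the
    training segment of a trajectory expressed as ``theta``, ``sincos``,
    ``chi`` or ``y`` (reduced displacement PCA coordinates), and maps the
    forecasts back to wrapped angles so every representation is evaluated on
    the same physical observable.

    For ``chi`` and ``y`` the forecast is a displacement step (or reduced
    step lifted through V^T); the predicted angle is obtained by adding the
    step to the last known angles and re-wrapping.  For ``y`` the reference
    angles are themselves reconstructed through V V^T (the y* trajectory), so
    the score isolates predictive error from projection error.
    """

    def __init__(
        self,
        representation: str = "theta",
        lag: int = 1,
        n_components: int | None = None,
        rescale: bool = False,
    ):
        if representation not in {"theta", "sincos", "chi", "y"}:
            raise ValueError(f"unknown representation {representation!r}")
        self.representation = representation
        self.lag = lag
        self.n_components = n_components
        self.rescale = rescale

    # -- representation plumbing -------------------------------------------
    def _featurize(self, theta: NDArray[np.float64]) -> NDArray[np.float64]:
        if self.representation == "theta":
            return theta
        if self.representation == "sincos":
            return embed_sincos(theta).values
        chi = displacement(theta).values
        if self.representation == "chi":
            return chi
        return self.pca_.transform(chi)

    def fit(self, theta_train: AngleTrajectory | ArrayLike) -> "RepresentationPredictor":
        theta = (
            theta_train.values
            if isinstance(theta_train, AngleTrajectory)
            else np.atleast_2d(np.asarray(theta_train, dtype=np.float64))
        )
        self.train_theta_ = theta
        if self.representation == "y":
            r = self.n_components or min(5, theta.shape[1])
            self.pca_ = DisplacementPCA(n_components=r, center=False).fit(
                displacement(theta).values
            )
        Z = self._featurize(theta)
        self.regressor_ = KoopmanRegressor(lag=self.lag).fit(Z)
        return self

    def predict_angles(
        self, theta_val: NDArray[np.float64]
    ) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """Forecast angles at t + lag from validation data.

        Returns ``(predicted, reference)`` wrapped angle matrices of shape
        (T_val - lag - pad, n), where pad is 1 for displacement-based
        representations (one frame is consumed by differencing).
        """
        theta_val = np.atleast_2d(np.asarray(theta_val, dtype=np.float64))
        lag = self.lag
        rep = self.representation
        Z = self._featurize(theta_val)
        Z0, Z1 = Z[:-lag], Z[lag:]
        pred_feat = predict_one_step(self.regressor_.model_, Z0)
        if self.rescale and np.linalg.norm(pred_feat) > 0:
            pred_feat = pred_feat * optimal_scale(pred_feat, Z1)

        if rep == "theta":
            return np.asarray(wrap_to_interval(pred_feat)), theta_val[lag:]
        if rep == "sincos":
            sin = pred_feat[:, 0::2]
            cos = pred_feat[:, 1::2]
            ang = np.degrees(np.arctan2(sin, cos))
            return np.asarray(wrap_to_interval(ang)), theta_val[lag:]

        # displacement-based: chi rows index steps t-1 -> t; a forecast of
        # step (t+lag-1 -> t+lag) is added to the known angles at t+lag-1.
        if rep == "y":
            step_pred = self.pca_.inverse_transform(pred_feat)
            # reference angles reconstructed through V V^T (y* trajectory)
            chi_val = displacement(theta_val).values
            chi_rec = self.pca_.inverse_transform(self.pca_.transform(chi_val))
            gamma0 = theta_val[0]
            gamma_rec = np.concatenate(
                [gamma0[None, :], gamma0[None, :] + np.cumsum(chi_rec, axis=0)]
            )
            base = np.asarray(wrap_to_interval(gamma_rec))
        else:
            step_pred = pred_feat
            base = theta_val
        base_frames = base[lag:-1]
        pred_angles = wrap_to_interval(base_frames + step_pred)
        ref_angles = base[lag + 1 :]
        return np.asarray(pred_angles), ref_angles


def mean_error_vs_lag(
    theta: AngleTrajectory | ArrayLike,
    lags: ArrayLike = range(1, 11),
    representations: tuple[str, ...] = ("theta", "sincos", "chi", "y"),
    train_fraction: float = 0.8,
    n_components: int | None = None,
    rescale: bool = False,
) -> list[ErrorReport]:
    """Mean relative angular error <e(tau)> on a held-out validation split.

    The trajectory is split contiguously (first ``train_fraction`` fits the
    Koopman model, the remainder validates); for each lag and representation
    single-step predictions are mapped back to wrapped angles and scored with
    :func:`frame_relative_error`, averaged over the validation samples.
    """
    values = (
        theta.values
        if isinstance(theta, AngleTrajectory)
        else np.atleast_2d(np.asarray(theta, dtype=np.float64))
    )
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    split = int(values.shape[0] * train_fraction)
    train, val = values[:split], values[split:]
    if val.shape[0] < max(list(lags)) + 3:
        raise ValueError("validation split too short for the requested lags")
    reports = []
    for rep in representations:
        for lag in lags:
            predictor = RepresentationPredictor(
                representation=rep, lag=int(lag),
                n_components=n_components, rescale=rescale,
            ).fit(train)
            pred, ref = predictor.predict_angles(val)
            errs = np.array(
                [frame_relative_error(p, q) for p, q in zip(pred, ref)]
            )
            reports.append(
                ErrorReport(
                    per_frame_error=errs,
                    mean_error=float(errs.mean()),
                    lag=int(lag),
                    representation_tag=rep if rep != "y" else "y_star",
                )
            )
    return reports


def kabsch_superpose(
    mobile: ArrayLike, target: ArrayLike
) -> NDArray[np.float64]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates.  The rotation is proper
    (determinant +1); degenerate (collinear) point sets are handled
    best-effort.
    """
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be k x 3")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    pc = P - P.mean(axis=0)
    qc = Q - Q.mean(axis=0)
    H = pc.T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return pc @ R.T + Q.mean(axis=0)


def rmsd(a: ArrayLike, b: ArrayLike, superpose: bool = True) -> float:
    """Root-mean-square deviation between matched coordinate sets, Angstrom."""
    A = np.asarray(a, dtype=np.float64)
    B = np.asarray(b, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if superpose:
        A = kabsch_superpose(A, B)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
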