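"""Geometry-aware representations of dihedral time series.

Backbone dihedral angles live on the n-torus: each coordinate is periodic
with period 360 degrees.  Naive arithmetic on the wrapped values produces
spurious jumps (a move from 178 deg to -178 deg looks like -356 deg although
the physical change is +4 deg).  This module provides the reversible chain of
representations used throughout the package:

* ``wrap_to_interval`` -- the modular projection M onto [-180, 180);
* ``unwrap`` -- U, lifting a wrapped series to a continuous path by removing
  360-degree discontinuities;
* ``displacement`` -- the frame-to-frame geodesic step chi, the first
  difference of the unwrapped path (a discrete angular velocity);
* ``integrate_displacement`` -- the inverse of chi, recovering wrapped angles
  from displacements and an anchor frame;
* ``embed_sincos`` -- the (sin, cos) embedding onto the product of circles;
* ``dihedral_angle`` / ``extract_backbone_dihedrals`` -- signed torsions from
  Cartesian coordinates.

All angles are degrees.  Wrapped angles use the half-open convention
[-180, 180); geodesic displacements use (-180, 180], so a jump of exactly
half a turn is counted as +180.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "AngleTrajectory",
    "UnwrappedTrajectory",
    "DisplacementTrajectory",
    "EmbeddedTrajectory",
    "wrap_to_interval",
    "geodesic_step",
    "unwrap",
    "displacement",
    "integrate_displacement",
    "embed_sincos",
    "dihedral_angle",
    "extract_backbone_dihedrals",
    "phi_psi_angle_names",
]


def phi_psi_angle_names(n_residues: int) -> list[str]:
    """Canonical ordering of the 2(m-1) analysis angles of an m-residue chain.

    The N-terminal phi and C-terminal psi are undefined (no preceding C /
    following N atom), so the analysis set runs
    ``psi1, phi2, psi2, phi3, ..., psi(m-1), phi(m)``.
    """
    if n_residues < 2:
        raise ValueError("a chain needs at least 2 residues")
    names = ["psi1"]
    for i in range(2, n_residues):
        names += [f"phi{i}", f"psi{i}"]
    names.append(f"phi{n_residues}")
    return names


def _as_float_array(values: ArrayLike, name: str = "values") -> NDArray[np.float64]:
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class AngleTrajectory:
    """Wrapped dihedral time series on the torus.

    Parameters
    ----------
    values : (T, n) array
        Angles in degrees, each in [-180, 180).
    angle_names : list of str, optional
        Column labels; defaults to ``theta1 .. theta_n``.
    frame_spacing : float
        Picoseconds per frame (the unit of the lag time tau).
    """

    values: NDArray[np.float64]
    angle_names: list[str] = field(default_factory=list)
    frame_spacing: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(_as_float_array(self.values))
        if self.values.ndim != 2:
            raise ValueError("values must be a T x n matrix")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")
        lo, hi = self.values.min(initial=0.0), self.values.max(initial=0.0)
        if lo < -180.0 or hi >= 180.0:
            raise ValueError(
                "angles must lie in [-180, 180); use wrap_to_interval first"
            )
        if not self.angle_names:
            self.angle_names = [f"theta{j + 1}" for j in range(self.n_angles)]
        if len(self.angle_names) != self.n_angles:
            raise ValueError("angle_names length must match the number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]

    def lag_time(self, lag: int) -> float:
        """Physical prediction horizon, ps, of a lag expressed in frames."""
        return lag * self.frame_spacing


@dataclass
class UnwrappedTrajectory:
    """Continuous lift gamma of a wrapped trajectory (degrees, unbounded)."""

    values: NDArray[np.float64]
    anchor: NDArray[np.float64]

    def wrap(self) -> NDArray[np.float64]:
        return wrap_to_interval(self.values)


@dataclass
class DisplacementTrajectory:
    """Frame-to-frame geodesic steps chi, (T-1) x n, degrees per frame."""

    values: NDArray[np.float64]
    anchor: NDArray[np.float64]

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddedTrajectory:
    """Sin-cos embedding, T x 2n, columns alternating (sin, cos) per angle."""

    values: NDArray[np.float64]


def wrap_to_interval(delta: ArrayLike) -> NDArray[np.float64] | float:
    """Modular projection M onto [-180, 180) degrees.

    ``M(x) = ((x + 180) mod 360) - 180``.  Idempotent; preserves the value
    modulo 360.  A scalar input returns a scalar.
    """
    arr = _as_float_array(delta, "delta")
    wrapped = np.mod(arr + 180.0, 360.0) - 180.0
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return float(wrapped)
    return wrapped


def geodesic_step(delta: ArrayLike) -> NDArray[np.float64] | float:
    """Shortest signed arc for a difference of wrapped angles, in (-180, 180].

    Identical to :func:`wrap_to_interval` except that a tie at exactly half a
    turn maps to +180 rather than -180, so a step and its reverse have the
    same magnitude.
    """
    arr = _as_float_array(delta, "delta")
    wrapped = np.mod(arr + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return float(wrapped)
    return wrapped


def unwrap(theta: AngleTrajectory | ArrayLike) -> UnwrappedTrajectory:
    """Lift U: remove 360-degree discontinuities column by column.

    gamma_0 = theta_0 and gamma_t = gamma_{t-1} + geodesic_step(theta_t -
    theta_{t-1}); each column is unwrapped independently.
    """
    values = theta.values if isinstance(theta, AngleTrajectory) else np.atleast_2d(
        _as_float_array(theta)
    )
    if values.shape[0] < 1:
        raise ValueError("cannot unwrap an empty trajectory")
    steps = geodesic_step(np.diff(values, axis=0))
    gamma = np.concatenate(
        [values[:1], values[:1] + np.cumsum(steps, axis=0)], axis=0
    )
    return UnwrappedTrajectory(values=gamma, anchor=values[0].copy())


def displacement(theta: AngleTrajectory | ArrayLike) -> DisplacementTrajectory:
    """Angular displacement chi_t = gamma_t - gamma_{t-1} = M(theta_t - theta_{t-1}).

    The geodesic frame-to-frame step: the true physical change between
    consecutive frames, free of wrapping artifacts.  Acts as a first-difference
    (high-pass) filter on the unwrapped path.
    """
    values = theta.values if isinstance(theta, AngleTrajectory) else np.atleast_2d(
        _as_float_array(theta)
    )
    if values.shape[0] < 2:
        raise ValueError("displacement needs at least 2 frames")
    chi = np.atleast_2d(geodesic_step(np.diff(values, axis=0)))
    return DisplacementTrajectory(values=chi, anchor=values[0].copy())


def integrate_displacement(
    chi: DisplacementTrajectory | ArrayLike,
    anchor: ArrayLike | None = None,
    frame_spacing: float = 4.0,
    angle_names: list[str] | None = None,
) -> AngleTrajectory:
    """Inverse of :func:`displacement`: cumulate chi from the anchor and re-wrap.

    ``integrate_displacement(displacement(theta), theta_0)`` recovers theta.
    """
    if isinstance(chi, DisplacementTrajectory):
        steps = chi.values
        if anchor is None:
            anchor = chi.anchor
    else:
        steps = np.atleast_2d(_as_float_array(chi, "chi"))
    if anchor is None:
        raise ValueError("an anchor frame is required")
    anchor = _as_float_array(anchor, "anchor")
    if anchor.ndim != 1 or anchor.size != steps.shape[1]:
        raise ValueError("anchor length must match the number of angle columns")
    if np.any(anchor < -180.0) or np.any(anchor >= 180.0):
        raise ValueError("anchor must be wrapped to [-180, 180)")
    gamma = np.concatenate(
        [anchor[None, :], anchor[None, :] + np.cumsum(steps, axis=0)], axis=0
    )
    return AngleTrajectory(
        values=np.asarray(wrap_to_interval(gamma)),
        angle_names=angle_names or [],
        frame_spacing=frame_spacing,
    )


def embed_sincos(theta: AngleTrajectory | ArrayLike) -> EmbeddedTrajectory:
    """Embed each angle as the pair (sin, cos), mapping the torus into R^{2n}.

    Removes periodic discontinuities at the price of doubling the feature
    dimension and curving the data manifold.
    """
    values = theta.values if isinstance(theta, AngleTrajectory) else np.atleast_2d(
        _as_float_array(theta)
    )
    rad = np.deg2rad(values)
    out = np.empty((values.shape[0], 2 * values.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    return EmbeddedTrajectory(values=out)


def dihedral_angle(p1: ArrayLike, p2: ArrayLike, p3: ArrayLike, p4: ArrayLike) -> float:
    """Signed torsion angle p1-p2-p3-p4 about the p2-p3 axis, degrees in [-180, 180).

    IUPAC convention: 0 for the cis (eclipsed) arrangement, positive when,
    looking from p2 towards p3, the far bond p3-p4 is rotated clockwise
    (right-hand rule about p2->p3) from the near bond p2-p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: coincident or collinear points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = np.degrees(np.arctan2(y, x))
    return float(wrap_to_interval(ang))


def extract_backbone_dihedrals(structures, frame_spacing: float = 4.0) -> AngleTrajectory:
    """Compute the (psi1, phi2, ..., phim) series from backbone structures.

    Parameters
    ----------
    structures : sequence of BackboneStructure
        One structure per frame, identical residue counts, complete N/CA/C.
    frame_spacing : float
        Picoseconds between consecutive structures.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("need at least one structure")
    m = structures[0].n_residues
    if m < 2:
        raise ValueError("need at least 2 residues")
    rows = []
    for s in structures:
        if s.n_residues != m:
            raise ValueError("all structures must have the same residue count")
        rows.append(s.phi_psi_vector())
    return AngleTrajectory(
        values=np.asarray(rows),
        angle_names=phi_psi_angle_names(m),
        frame_spacing=frame_spacing,
    )
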