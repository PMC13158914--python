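"""Deterministic backbone reconstruction from internal coordinates.

Converts (phi, psi, omega) dihedral angles into Cartesian N/CA/C coordinates
using ideal bond lengths and angles, by sequential natural-extension
(NeRF-style) placement of each atom from the three preceding ones.  The
reconstruction is defined up to a rigid motion; the first residue is seeded
in a canonical frame (N at the origin, CA on +x, C in the xy-plane).

The default geometry is an Engh-Huber-like ideal set.  Side chains, CB and
carbonyl O atoms are not reconstructed: they are not determined by the
backbone torsions alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .torus import dihedral_angle, phi_psi_angle_names

__all__ = [
    "IdealGeometry",
    "BackboneStructure",
    "place_next_atom",
    "build_backbone",
    "build_backbone_trajectory",
]


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal backbone bond lengths (Angstrom) and bond angles (degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7


DEFAULT_GEOMETRY = IdealGeometry()


@dataclass
class BackboneStructure:
    """Per-residue backbone N/CA/C coordinates, Angstrom.

    ``coords`` has shape (m, 3, 3): residue, atom (N, CA, C), xyz.
    """

    coords: NDArray[np.float64]
    geometry: IdealGeometry = field(default_factory=IdealGeometry)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must have shape (m, 3, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> NDArray[np.float64]:
        """Flat (3m, 3) atom array in N, CA, C chain order."""
        return self.coords.reshape(-1, 3)

    def _atom(self, res: int, name: int) -> NDArray[np.float64]:
        return self.coords[res, name]

    def phi_vector(self) -> NDArray[np.float64]:
        """phi_i = C(i-1)-N(i)-CA(i)-C(i) for residues 2..m (m-1 values)."""
        N, CA, C = 0, 1, 2
        return np.array(
            [
                dihedral_angle(
                    self._atom(i - 1, C), self._atom(i, N),
                    self._atom(i, CA), self._atom(i, C),
                )
                for i in range(1, self.n_residues)
            ]
        )

    def psi_vector(self) -> NDArray[np.float64]:
        """psi_i = N(i)-CA(i)-C(i)-N(i+1) for residues 1..m-1 (m-1 values)."""
        N, CA, C = 0, 1, 2
        return np.array(
            [
                dihedral_angle(
                    self._atom(i, N), self._atom(i, CA),
                    self._atom(i, C), self._atom(i + 1, N),
                )
                for i in range(self.n_residues - 1)
            ]
        )

    def omega_vector(self) -> NDArray[np.float64]:
        """omega_i = CA(i-1)-C(i-1)-N(i)-CA(i) for residues 2..m (m-1 values)."""
        N, CA, C = 0, 1, 2
        return np.array(
            [
                dihedral_angle(
                    self._atom(i - 1, CA), self._atom(i - 1, C),
                    self._atom(i, N), self._atom(i, CA),
                )
                for i in range(1, self.n_residues)
            ]
        )

    def phi_psi_vector(self) -> NDArray[np.float64]:
        """The 2(m-1) analysis angles interleaved as psi1, phi2, psi2, ..., phim."""
        phi = self.phi_vector()
        psi = self.psi_vector()
        out = np.empty(2 * (self.n_residues - 1))
        out[0::2] = psi
        out[1::2] = phi
        return out


def place_next_atom(
    p1: ArrayLike,
    p2: ArrayLike,
    p3: ArrayLike,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> NDArray[np.float64]:
    """Place the fourth atom of a dihedral from three reference atoms.

    The returned point D satisfies |D - p3| = bond_length, the angle
    p2-p3-D equals ``bond_angle`` and the torsion p1-p2-p3-D equals
    ``torsion`` (degrees, same sign convention as :func:`dihedral_angle`).
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    bc = p3 - p2
    bc_norm = np.linalg.norm(bc)
    if bc_norm < 1e-12:
        raise ValueError("degenerate geometry: coincident reference atoms")
    bc = bc / bc_norm
    n = np.cross(p2 - p1, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("degenerate geometry: collinear reference atoms")
    n = n / n_norm
    m = np.cross(n, bc)
    theta = np.deg2rad(bond_angle)
    tau = np.deg2rad(torsion)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), np.sin(theta) * np.sin(tau)]
    )
    return p3 + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: ArrayLike,
    psi: ArrayLike,
    omega: ArrayLike | None = None,
    geometry: IdealGeometry = DEFAULT_GEOMETRY,
) -> BackboneStructure:
    """Build N/CA/C coordinates of an m-residue chain from its torsions.

    Parameters
    ----------
    phi : (m-1,) array
        phi of residues 2..m, degrees.
    psi : (m-1,) array
        psi of residues 1..m-1, degrees.
    omega : (m-1,) array, optional
        omega of residues 2..m; defaults to all-trans (180 deg) peptide bonds.
    geometry : IdealGeometry
        Ideal bond lengths and angles used for every residue.
    """
    phi = np.asarray(phi, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    if phi.ndim != 1 or psi.shape != phi.shape:
        raise ValueError("phi and psi must be 1-d arrays of equal length m-1")
    m = phi.size + 1
    if m < 2:
        raise ValueError("need at least 2 residues (one phi/psi pair)")
    if omega is None:
        omega = np.full(m - 1, 180.0)
    omega = np.asarray(omega, dtype=np.float64)
    if omega.shape != phi.shape:
        raise ValueError("omega must have length m-1")

    g = geometry
    coords = np.empty((m, 3, 3))
    # canonical seed frame for residue 1
    coords[0, 0] = (0.0, 0.0, 0.0)  # N1
    coords[0, 1] = (g.n_ca, 0.0, 0.0)  # CA1
    ang = np.deg2rad(180.0 - g.ang_n_ca_c)
    coords[0, 2] = coords[0, 1] + g.ca_c * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, m):
        n_prev, ca_prev, c_prev = coords[i - 1]
        coords[i, 0] = place_next_atom(
            n_prev, ca_prev, c_prev, g.c_n, g.ang_ca_c_n, psi[i - 1]
        )
        coords[i, 1] = place_next_atom(
            ca_prev, c_prev, coords[i, 0], g.n_ca, g.ang_c_n_ca, omega[i - 1]
        )
        coords[i, 2] = place_next_atom(
            c_prev, coords[i, 0], coords[i, 1], g.ca_c, g.ang_n_ca_c, phi[i - 1]
        )
    return BackboneStructure(coords=coords, geometry=geometry)


def build_backbone_trajectory(
    angles: NDArray[np.float64],
    omega: ArrayLike | None = None,
    geometry: IdealGeometry = DEFAULT_GEOMETRY,
) -> list[BackboneStructure]:
    """Build one structure per frame from interleaved (psi1, phi2, ..., phim) rows.

    ``angles`` is a T x 2(m-1) matrix in the canonical analysis ordering
    (see :func:`torsiondyn.torus.phi_psi_angle_names`).
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=np.float64))
    if angles.shape[1] % 2 != 0:
        raise ValueError("angle rows must have even length 2(m-1)")
    psi = angles[:, 0::2]
    phi = angles[:, 1::2]
    return [
        build_backbone(phi[t], psi[t], omega=omega, geometry=geometry)
        for t in range(angles.shape[0])
    ]
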