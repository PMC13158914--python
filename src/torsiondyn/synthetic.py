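"""Synthetic torsional trajectories with planted collective structure.

The generator realizes the drift-plus-noise picture of peptide torsional
dynamics: a small number of latent collective modes evolve as discrete-time
mean-reverting (AR(1)) processes on the unwrapped coordinates, are mapped
into angle space through a planted loading matrix, and are corrupted by
white thermal jitter and occasional large jump events (crankshaft-like
torsional flips).  The result is wrapped to [-180, 180).

Defaults emulate a short peptide sampled every 4 ps: slow modes with
correlation times of hundreds of frames and tens of degrees of amplitude,
a few degrees of thermal noise per frame, and rare ~120-degree jumps.
Because the latent dynamics are linear in the unwrapped coordinates, the
Koopman least-squares problem is exactly solvable on noise-free instances,
which makes these generators usable as oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .torus import AngleTrajectory, phi_psi_angle_names, wrap_to_interval

__all__ = [
    "GeneratorConfig",
    "generate_torsional_trajectory",
    "generate_linear_observable_process",
    "fixture_hexapeptide",
]


def _default_loadings() -> NDArray[np.float64]:
    # two collective modes over 10 angles, concentrated on the central core
    w1 = np.array([0.0, 0.1, 0.3, 0.6, 0.8, 0.8, 0.6, 0.3, 0.1, 0.0])
    w2 = np.array([0.3, 0.6, 0.4, 0.1, -0.2, -0.2, 0.1, 0.4, 0.6, 0.3])
    W = np.stack([w1, w2], axis=1)
    return W / np.linalg.norm(W, axis=0)


@dataclass
class GeneratorConfig:
    """Parameters of the planted-mode torsional trajectory generator.

    Attributes
    ----------
    n_angles, n_frames : int
        Size of the generated angle table.
    loading_matrix : (n_angles, p) array
        Spatial pattern of each planted collective mode (columns normalized
        at generation time).
    mode_timescales : (p,) array
        AR(1) correlation times of the latent modes, frames.
    mode_amplitudes : (p,) array
        Stationary standard deviation of each mode's angular excursion, deg.
    noise_scale : float
        White thermal jitter per angle per frame, degrees.
    jump_rate : float
        Probability per frame of a large collective jump event.
    jump_scale : float
        Typical magnitude of a jump, degrees.
    base_angles : (n_angles,) array or None
        Mean angles; defaults to a reproducible random draw on the torus so
        some columns sit near the +-180 seam (where wrapping artifacts bite).
    frame_spacing : float
        Picoseconds per frame.
    seed : int
        Seed for the single PRNG governing all randomness.
    """

    n_angles: int = 10
    n_frames: int = 2000
    loading_matrix: NDArray[np.float64] = field(default_factory=_default_loadings)
    mode_timescales: NDArray[np.float64] = field(
        default_factory=lambda: np.array([600.0, 200.0])
    )
    mode_amplitudes: NDArray[np.float64] = field(
        default_factory=lambda: np.array([60.0, 40.0])
    )
    noise_scale: float = 3.0
    jump_rate: float = 2e-3
    jump_scale: float = 120.0
    base_angles: NDArray[np.float64] | None = None
    frame_spacing: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=np.float64)
        self.mode_timescales = np.atleast_1d(
            np.asarray(self.mode_timescales, dtype=np.float64)
        )
        self.mode_amplitudes = np.atleast_1d(
            np.asarray(self.mode_amplitudes, dtype=np.float64)
        )
        if self.n_angles < 1 or self.n_frames < 2:
            raise ValueError("need n_angles >= 1 and n_frames >= 2")
        if self.loading_matrix.shape[0] != self.n_angles:
            raise ValueError("loading_matrix must have n_angles rows")
        p = self.loading_matrix.shape[1]
        if self.mode_timescales.shape != (p,) or self.mode_amplitudes.shape != (p,):
            raise ValueError("one timescale and amplitude per planted mode")
        if np.any(self.mode_timescales < 1.0):
            raise ValueError("mode timescales must be >= 1 frame")
        if not 0.0 <= self.jump_rate <= 1.0:
            raise ValueError("jump_rate is a per-frame probability")
        if self.noise_scale < 0 or self.jump_scale < 0:
            raise ValueError("scales must be non-negative")


def generate_torsional_trajectory(config: GeneratorConfig) -> AngleTrajectory:
    """Wrapped angular trajectory with planted low-rank collective modes.

    Latent modes follow a_{t+1} = rho a_t + sigma eps_t with
    rho = exp(-1/timescale) and stationary std ``mode_amplitudes``; angle-space
    motion is ``latent @ W^T`` plus white jitter plus Bernoulli jump events
    that kick a random subset of angles by ~``jump_scale`` degrees (persisting
    thereafter, as a torsional flip does).  Deterministic under ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W = config.loading_matrix
    norms = np.linalg.norm(W, axis=0)
    W = np.where(norms > 0, W / np.where(norms == 0, 1.0, norms), W)
    p = W.shape[1]
    T, n = config.n_frames, config.n_angles

    rho = np.exp(-1.0 / config.mode_timescales)
    innov = config.mode_amplitudes * np.sqrt(1.0 - rho**2)
    latent = np.zeros((T, p))
    latent[0] = config.mode_amplitudes * rng.standard_normal(p)
    shocks = rng.standard_normal((T - 1, p))
    for t in range(1, T):
        latent[t] = rho * latent[t - 1] + innov * shocks[t - 1]

    motion = latent @ W.T
    if config.noise_scale > 0:
        motion = motion + config.noise_scale * rng.standard_normal((T, n))

    if config.jump_rate > 0 and config.jump_scale > 0:
        jump_frames = rng.random(T) < config.jump_rate
        jump_frames[0] = False
        for t in np.flatnonzero(jump_frames):
            hit = rng.random(n) < 0.3
            if not hit.any():
                hit[rng.integers(n)] = True
            kick = config.jump_scale * rng.choice([-1.0, 1.0], size=n)
            motion[t:] += np.where(hit, kick, 0.0)

    if config.base_angles is None:
        base = rng.uniform(-180.0, 180.0, size=n)
    else:
        base = np.asarray(config.base_angles, dtype=np.float64)
        if base.shape != (n,):
            raise ValueError("base_angles must have n_angles entries")
    names = (
        phi_psi_angle_names(n // 2 + 1) if n >= 2 and n % 2 == 0 else []
    )
    return AngleTrajectory(
        values=np.asarray(wrap_to_interval(base + motion)),
        angle_names=names,
        frame_spacing=config.frame_spacing,
    )


def generate_linear_observable_process(
    A: ArrayLike, noise: float, n_frames: int, seed: int = 0
) -> NDArray[np.float64]:
    """Linear observable dynamics zeta_{t+1} = A^T zeta_t + noise * N(0, I).

    Oracle data for Koopman estimation: with ``noise = 0`` and full-rank
    excitation the least-squares Koopman matrix recovers A exactly.
    Warns when the spectral radius of A is >= 1 (non-stationary).
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        warnings.warn("spectral radius >= 1: process is not stationary", stacklevel=2)
    rng = np.random.default_rng(seed)
    d = A.shape[0]
    Z = np.empty((n_frames, d))
    Z[0] = rng.standard_normal(d)
    for t in range(1, n_frames):
        Z[t] = A.T @ Z[t - 1]
        if noise > 0:
            Z[t] += noise * rng.standard_normal(d)
    return Z


def fixture_hexapeptide(
    n_frames: int = 2000, seed: int = 20260101 % (2**31)
) -> tuple[AngleTrajectory, list]:
    """Bundled hexapeptide-like test system (m = 6 residues, n = 10 angles).

    A fixed-seed synthetic trajectory with two slow collective modes
    concentrated on the central angles, mimicking a flexible-core
    disulfide-constrained hexapeptide, plus the backbone structure series
    rebuilt from its angles (trans peptide bonds).  Used by the docs and the
    integration tests.
    """
    from .reconstruction import build_backbone_trajectory

    config = GeneratorConfig(
        n_angles=10,
        n_frames=n_frames,
        base_angles=np.array(
            [140.0, -70.0, 150.0, -65.0, -35.0, -60.0, -40.0, 120.0, 60.0, -80.0]
        ),
        seed=seed,
    )
    traj = generate_torsional_trajectory(config)
    structures = build_backbone_trajectory(traj.values[:: max(n_frames // 50, 1)])
    return traj, structures
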