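# torsiondyn

Analysis of peptide torsional dynamics from molecular-dynamics trajectories,
built around a geometry-aware **angular-displacement representation** of
backbone dihedral angles.

## The problem

Backbone dihedrals (φ, ψ) are the natural coordinates of peptide
conformational dynamics, but they live on a torus: a move from 178° to
−178° is a physical change of only 4°, yet naive arithmetic reports −356°.
These wrapping artifacts corrupt linear analyses (PCA, linear dynamical
models) applied to raw angle time series. `torsiondyn` is for computational
chemists and biophysicists who want to extract collective torsional modes
and short-horizon structural forecasts from dihedral trajectories without
fighting periodicity by hand.

## The method

Given a wrapped angle series θ_t ∈ [−180, 180)ⁿ sampled every Δt ps:

1. **Unwrap** (U): lift θ to a continuous path γ_t by removing ±360°
   discontinuities; the modular projection M(γ) = ((γ+180) mod 360) − 180
   inverts U exactly.
2. **Displacement** χ_t = γ_t − γ_{t−1} = M(θ_t − θ_{t−1}): the geodesic
   frame-to-frame step, a discrete angular velocity. χ is reversible
   (cumulate and re-wrap) and acts as a high-pass filter with gain
   |2 sin(π f Δt)|.
3. **Spatiotemporal PCA**: SVD of the (T−1)×n displacement matrix
   X = UΣVᵀ. Columns of V are spatial modes (which angles move together),
   columns of UΣ are temporal scores y_k, λ_j = Σ_jj² the mode variances;
   the smallest r reaching 80 % cumulative variance is retained.
4. **Activation patterns**: scores are thresholded at the (100−λ_k)-th
   percentile of |y_k|; each frame is labelled 0 (silent), k (only mode k
   active) or r+1 (coactivation), and label successions are counted into a
   row-normalized transition-frequency matrix P.
5. **Koopman/VAMP**: for an observable choice ζ ∈ {θ, (sin θ, cos θ), χ, y},
   the linear propagator K = C00⁻¹C01 is estimated from time-lagged
   covariances; the VAMP-2 score 1 + Σᵢ Λᵢ² of the whitened SVD
   C00^{−1/2} C01 C11^{−1/2} quantifies the slow dynamical variance each
   representation retains. Single-step forecasts use
   ζ̂_{t+τ} = (Φᵀ)⁺ Λ Ψᵀ (ζ_t − μ0) + μt.
6. **Evaluation**: forecasts are mapped back to angles and scored with the
   normalized torus metric e = ‖d(θ, θ̂)‖₂ / (180√n) ∈ [0, 1]; structures
   rebuilt from (φ, ψ, ω) with ideal geometry are compared by RMSD after
   Kabsch superposition.

All of this is exposed as scikit-learn-style estimators
(`DisplacementPCA`, `KoopmanRegressor`) plus functional wrappers, and as a
`torsiondyn` command line (`simulate`, `transform`, `pca`, `spectra`,
`vamp`, `predict`, `pipeline`).

## Worked example

```python
import numpy as np
from torsiondyn import (
    GeneratorConfig, generate_torsional_trajectory, displacement,
    DisplacementPCA, select_component_count, vamp2_score, embed_sincos,
    mean_error_vs_lag,
)

traj = generate_torsional_trajectory(GeneratorConfig(n_frames=4000, seed=0))
chi = displacement(traj)
pca = DisplacementPCA().fit(chi.values)
r = select_component_count(pca, 0.80)
print(f"modes for 80% variance: {r}")
print("explained ratio:", np.round(pca.explained_variance_ratio_[:4], 3))
for rep, Z in [("sincos", embed_sincos(traj).values),
               ("theta", traj.values), ("chi", chi.values)]:
    print(f"VAMP-2 (lag 1) {rep:7s} {vamp2_score(Z, lag=1):6.2f}")
for rep_ in mean_error_vs_lag(traj, lags=[1, 10], representations=("theta", "chi")):
    print(f"<e({rep_.lag:2d})> {rep_.representation_tag:6s} {rep_.mean_error:.3f}")
```

prints

```
modes for 80% variance: 7
explained ratio: [0.217 0.14  0.121 0.095]
VAMP-2 (lag 1) sincos   14.44
VAMP-2 (lag 1) theta     8.21
VAMP-2 (lag 1) chi       2.37
<e( 1)> theta  0.301
<e(10)> theta  0.382
<e( 1)> chi    0.024
<e(10)> chi    0.025
```

The sin–cos embedding keeps the most slow dynamical variance (highest
VAMP-2), raw angles are intermediate, and χ — a high-pass representation by
construction — keeps the least, while its one-step angular forecasts stay
within a few percent of the maximal torus distance. (This trajectory has
angles straddling the ±180° seam, which is exactly where the θ
representation's wrapping artifacts inflate its angular error.)

The full pipeline with CSV artifacts and a manifest:

```bash
torsiondyn pipeline --output-dir run1 --seed 5
```

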