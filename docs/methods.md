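# Methods

## Representations of torsional time series

All angles are handled internally in **degrees** on the half-open interval
[−180, 180); radians are accepted at I/O behind an explicit flag. The choice
of degrees makes the torus metric's normalization constant d_max = 180√n and
all worked numbers directly interpretable.

The transform chain is M ∘ U ∘ χ⁻¹:

* `wrap_to_interval` (M) maps any real angle to [−180, 180) via
  ((x+180) mod 360) − 180.
* `unwrap` (U) lifts a wrapped series to a continuous path by accumulating
  geodesic steps column by column; columns are unwrapped independently even
  when several angles jump in the same frame.
* `displacement` (χ) is the first difference of the unwrapped path,
  equivalently M applied to the wrapped first difference.
* `integrate_displacement` cumulates χ from an anchor frame and re-wraps.

**Tie at half a turn.** A frame-to-frame difference of exactly ±180° has two
equally short geodesic arcs. Displacements resolve the tie to **+180**
(range (−180, 180]), and `unwrap` uses the same step convention so that
χ equals the first difference of γ identically, ties included. Wrapped
*positions* keep the half-open [−180, 180) convention (so a trans torsion
reads −180).

**Numerical exactness of the round trips.** M ∘ U = id and the χ round trip
are exact in exact arithmetic; in floating point they telescope through a
cumulative sum and hold to ~1e−12 per thousand frames. Tests assert 1e−9,
far below any physically meaningful angular scale.

## Spatiotemporal PCA and activation analysis

The displacement matrix is column-mean-centered before the SVD by default.
χ is near-zero-mean by construction, so centering changes nothing
materially, but it makes λ_j = Σ_jj² an exact variance decomposition;
`center=False` disables it. Mode signs are fixed by making the
largest-magnitude loading of each spatial component positive, so heatmaps
and score series are reproducible across platforms.

Component count: the smallest r whose cumulative variance share reaches the
target (default 0.80). For activation labelling the pipeline uses
max(r, 5) modes (capped at full rank), since five temporal modes give a
label alphabet fine enough to resolve coactivation without fragmenting the
statistics.

Thresholding keeps, per mode k, the λ_k % largest |y_k| values (default
λ = 5 % per mode, configurable per mode or globally). The threshold ε_k is
the (100 − λ_k)-th linear-interpolation percentile of |y_k| and survival is
strict (|y| > ε_k); λ = 100 is special-cased to keep everything. Per-mode
thresholds are the default; a single global scalar may be broadcast.

Transition matrices are row-normalized succession counts over the label set
S = {0, 1, …, r, r+1}; rows never visited are all-zero and flagged rather
than imputed. Row-wise Kullback–Leibler comparison adds a 1e−12 pseudo-count
to both rows and renormalizes (KL is undefined on exact zeros); rows empty
in either matrix are skipped, and the Pearson similarity is reported as NaN
if a matrix is constant.

## Koopman estimation and VAMP-2

Covariances are computed over the T − τ instantaneous/lagged pairs with the
two means (μ0, μτ) removed separately; C00 and C11 are symmetrized exactly.
Eigenvalues below 1e−10 × trace are truncated before every inversion and
inverse square root, which silently (with a warning) drops zero-variance
features instead of failing.

The VAMP-2 convention here is **1 + Σ Λᵢ²** over the singular values of the
whitened cross-covariance of *mean-removed* data: the explicit "+1"
accounts for the constant singular function, so iid noise scores ≈ 1 and d
perfectly predictable nonconstant features score 1 + d. Only internal
consistency matters when comparing representations, and the convention is
invariant under invertible affine re-featurization (tested).

The one-step predictor uses the Moore–Penrose pseudo-inverse of Φᵀ at the
truncated rank (Φ is rectangular after truncation). On full-rank data this
propagator collapses algebraically to Kᵀ, so planted linear systems are
forecast exactly. Frobenius-norm rescaling of a batch of predictions
(α = ‖ref‖_F/‖pred‖_F) is available but **off by default**: it needs the
reference magnitude and is a presentation aid, not part of the estimator.

Prediction evaluation uses a contiguous 80/20 split (first 80 % fits, last
20 % validates) — contiguity preserves the temporal correlation structure a
random split would destroy. Lags sweep τ = 1…10 frames by default; with the
default 4 ps frame spacing this is a 4–40 ps horizon. Forecasts in χ or y
space are mapped back to angles (add the predicted step to the last known
frame, re-wrap; lift y through Vᵀ first), and y-space forecasts are scored
against the y* reference — angles rebuilt through V Vᵀ — so the score
isolates predictive error from projection error.

## Spectral characterization

Welch PSD: Hann window, segment length min(1024, T/4) rounded down to a
power of two, 50 % overlap, constant detrend, one-sided density scaling
(trapezoidal integral ≈ variance). The high-frequency energy fraction
R(f_c) is computed by trapezoidal integration with the straddling interval
split at f_c; the DC component enters only through the denominator's first
trapezoid, consistent with reading it as drift rather than reorganization
energy. R(0) = 1 and R(f ≥ Nyquist) = 0 by construction.

## Backbone reconstruction

Sequential natural-extension placement from three reference atoms, seeded
at a canonical first-residue frame (N at origin, CA on +x, C in the
xy-plane); reconstruction is defined up to rigid motion and RMSD is always
Kabsch-superposed (proper rotations only). Ideal geometry (Engh–Huber-like,
configurable): N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.0°,
CA–C–N 116.2°, C–N–CA 121.7°. When only (φ, ψ) are supplied, ω defaults to
trans (180°); when a source trajectory provides ω it can be passed through.
RMSD uses backbone N/CA/C atoms; CB, carbonyl O and side chains are not
determined by the backbone torsions and are omitted.

## Synthetic trajectory generator

The generator realizes drift-plus-noise torsional dynamics: p latent
collective modes follow discrete-time mean-reverting AR(1) processes on the
unwrapped coordinates (the simplest process with the right two-timescale
structure, and one for which the Koopman least-squares problem is exactly
solvable — enabling oracle tests), mapped through a normalized loading
matrix, plus white angular jitter, plus rare persistent jump events
(torsional flips). Output is wrapped to [−180, 180).

Defaults, chosen once as realistic for a short peptide sampled every 4 ps:

| parameter | default | rationale |
|---|---|---|
| n_angles × n_frames | 10 × 2000 | hexapeptide analysis set at desk scale |
| mode timescales | 600, 200 frames | 2.4 ns / 0.8 ns collective relaxations |
| mode amplitudes | 60°, 40° | large-but-bounded collective excursions |
| noise_scale | 3°/frame | thermal jitter of a stiff torsion |
| jump_rate | 2e−3 /frame | a handful of flips per few thousand frames |
| jump_scale | 120° | rotameric-scale barrier crossing |
| base angles | random on the torus | some columns straddle the ±180° seam |

What the generator does **not** emulate: force-field energetics, solvent
friction, correlated φ/ψ Ramachandran structure, or metastable-basin
kinetics with detailed balance. Passing tests therefore demonstrate the
*mathematical* contracts of the pipeline (reversibility, recovery,
ordering, spectral redistribution) on data with the assumed statistical
structure — not fidelity on any particular peptide's MD.

## Problem sizes used in the automated checks

Reversibility: 1000 random trajectories (2–30 frames × 1–5 angles).
Koopman oracle: d = 6, T = 500, noise-free contraction (0.95 × orthogonal).
VAMP-2 baseline: 20 000 iid frames; representation ordering: 6000-frame
two-timescale trajectory, lags 1–10. Spectral gap: 8192 frames, cutoff
0.02 ps⁻¹. Subspace recovery: planted rank-2 loadings, 5000 frames, SNR
≈ 10. Replica transition analysis: two 8000-frame runs of the same
generator. Pipeline integration: the bundled 2000-frame hexapeptide
fixture. These sizes keep every check comfortably inside an interactive
desk-scale run while leaving the stochastic margins wide.

## Known limitations

* Means μ0/μτ of wrapped θ near the ±180° seam are arithmetic, not
  circular; the θ representation consequently degrades there (visible in
  its angular errors), which is itself one of the motivations for χ.
* The Koopman model is linear in the chosen observables; strongly
  metastable systems need either the sin–cos embedding or a richer
  dictionary to be well approximated.
* Multistep recursive forecasting is deliberately unsupported: single-step
  prediction at increasing lag avoids compounding error.
* Transition matrices are activity-pattern summaries, not validated Markov
  state models; no implied-timescale or Chapman–Kolmogorov machinery is
  provided.
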