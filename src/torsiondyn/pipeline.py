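"""End-to-end orchestration of the angular-displacement analysis.

Runs, in order: angle loading (or extraction from PDB models) -> unwrap ->
displacement chi -> spatiotemporal PCA with the variance rule and subspace
convergence diagnostics -> score thresholding, activation labels and the
transition-frequency matrix -> Welch spectra and high-frequency energy
fractions -> VAMP-2 sweep over representations and lags -> single-step
prediction on a held-out split with angular-error and RMSD evaluation.
Every artifact is a CSV in the run directory, listed in a plain-text
manifest together with the configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .evaluation import frame_relative_error, mean_error_vs_lag, rmsd
from .koopman import vamp2_score
from .modes import (
    DisplacementPCA,
    label_activity,
    select_component_count,
    subspace_convergence,
    threshold_scores,
    transition_frequency_matrix,
)
from .reconstruction import build_backbone_trajectory
from .spectral import highpass_comparison
from .torus import AngleTrajectory, displacement, embed_sincos
from .synthetic import fixture_hexapeptide

logger = logging.getLogger("torsiondyn")

__all__ = ["PipelineConfig", "run_pipeline", "frame_spacing_from_integration"]

_FLOAT_FMT = "%.9f"
VALID_REPRESENTATIONS = ("theta", "sincos", "chi", "y")


def frame_spacing_from_integration(n_steps_per_frame: int, timestep_ps: float) -> float:
    """Frame spacing in ps from the integrator stride (e.g. 2000 x 0.002 = 4)."""
    if n_steps_per_frame < 1 or timestep_ps <= 0:
        raise ValueError("need a positive stride and timestep")
    return n_steps_per_frame * timestep_ps


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_path: str | None = None  # angle CSV/TSV or multi-model PDB; None -> fixture
    output_dir: str = "torsiondyn_run"
    representations: tuple[str, ...] = VALID_REPRESENTATIONS
    variance_target: float = 0.80
    keep_percent: float = 5.0
    lags: tuple[int, ...] = tuple(range(1, 11))
    train_fraction: float = 0.8
    cutoff_frequency: float = 0.02  # 1/ps, reference high-pass cutoff
    n_label_modes: int = 5
    rescale_predictions: bool = False
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        unknown = set(self.representations) - set(VALID_REPRESENTATIONS)
        if unknown:
            raise ValueError(f"unknown representation tags: {sorted(unknown)}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 < self.variance_target <= 1.0:
            raise ValueError("variance_target must be in (0, 1]")
        if any(lag < 1 for lag in self.lags):
            raise ValueError("lags must be >= 1 frame")
        if not 0.0 <= self.keep_percent <= 100.0:
            raise ValueError("keep_percent must be in [0, 100]")


def _load_input(config: PipelineConfig) -> AngleTrajectory:
    if config.input_path is None:
        traj, _ = fixture_hexapeptide(seed=config.seed % (2**31))
        return traj
    path = Path(config.input_path)
    if path.suffix.lower() == ".pdb":
        from .torus import extract_backbone_dihedrals

        return extract_backbone_dihedrals(tio.read_backbone_pdb(path))
    return tio.read_angle_table(path)


def _write_csv(df: pd.DataFrame, path: Path, artifacts: list[Path]) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    artifacts.append(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result dict with the manifest path."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    results: dict = {}

    theta = _load_input(config)
    tio.write_angle_table(theta, out / "angles_theta.csv")
    artifacts.append(out / "angles_theta.csv")

    # displacement representation
    chi = displacement(theta)
    pd_chi = pd.DataFrame(chi.values, columns=theta.angle_names)
    _write_csv(pd_chi, out / "displacement_chi.csv", artifacts)

    # spatiotemporal PCA
    pca = DisplacementPCA().fit(chi.values)
    r80 = select_component_count(pca, config.variance_target)
    r_label = min(max(r80, config.n_label_modes), pca.variances_.size)
    results["n_components_variance_rule"] = r80
    results["explained_ratio"] = pca.explained_variance_ratio_
    _write_csv(
        pd.DataFrame(
            {
                "mode": np.arange(1, pca.variances_.size + 1),
                "variance": pca.variances_,
                "explained_ratio": pca.explained_variance_ratio_,
            }
        ),
        out / "pca_variances.csv",
        artifacts,
    )
    _write_csv(
        pd.DataFrame(
            pca.components_,
            columns=[f"PC{k + 1}" for k in range(pca.components_.shape[1])],
        ).assign(angle=theta.angle_names),
        out / "pca_spatial_components.csv",
        artifacts,
    )
    _write_csv(
        pd.DataFrame(
            pca.scores_[:, :r_label],
            columns=[f"y{k + 1}" for k in range(r_label)],
        ),
        out / "pca_temporal_scores.csv",
        artifacts,
    )

    # subspace convergence diagnostic
    lengths, overlaps = subspace_convergence(chi.values, r=min(5, theta.n_angles))
    _write_csv(
        pd.DataFrame({"prefix_frames": lengths, "overlap": overlaps}),
        out / "subspace_convergence.csv",
        artifacts,
    )
    results["final_subspace_overlap"] = float(overlaps[-1])

    # activation labels and transition matrix
    filtered, eps = threshold_scores(pca.scores_[:, :r_label], config.keep_percent)
    labels = label_activity(filtered, r_label)
    tmat = transition_frequency_matrix(labels, n_states=r_label + 2)
    _write_csv(pd.DataFrame({"label": labels}), out / "activation_labels.csv", artifacts)
    _write_csv(
        pd.DataFrame(
            tmat.probabilities,
            columns=[f"to_{j}" for j in range(tmat.n_states)],
        ).assign(from_state=np.arange(tmat.n_states)),
        out / "transition_matrix.csv",
        artifacts,
    )
    results["transition_matrix"] = tmat
    results["thresholds"] = eps

    # spectral characterization (averaged over angles)
    rep_col = theta.values[:, 0]
    hp = highpass_comparison(
        rep_col, chi.values[:, 0], frame_spacing=theta.frame_spacing
    )
    _write_csv(
        pd.DataFrame(
            {
                "cutoff_per_ps": hp["cutoffs"],
                "R_theta": hp["R_theta"],
                "R_chi": hp["R_chi"],
            }
        ),
        out / "highpass_energy_fraction.csv",
        artifacts,
    )
    idx = int(np.argmin(np.abs(hp["cutoffs"] - config.cutoff_frequency)))
    results["highpass_gap_at_reference"] = float(
        hp["R_chi"][idx] - hp["R_theta"][idx]
    )

    # VAMP-2 sweep over representations and lags
    features = {
        "theta": theta.values,
        "sincos": embed_sincos(theta).values,
        "chi": chi.values,
        "y": pca.transform(chi.values)[:, :r_label],
    }
    rows = []
    for rep in config.representations:
        for lag in config.lags:
            rows.append(
                {
                    "representation": rep,
                    "lag_frames": lag,
                    "lag_ps": theta.lag_time(lag),
                    "vamp2": vamp2_score(features[rep], lag=lag),
                }
            )
    vamp_df = pd.DataFrame(rows)
    _write_csv(vamp_df, out / "vamp2_scores.csv", artifacts)
    results["vamp2"] = vamp_df

    # one-step prediction errors on the validation split
    reports = mean_error_vs_lag(
        theta,
        lags=config.lags,
        representations=config.representations,
        train_fraction=config.train_fraction,
        rescale=config.rescale_predictions,
    )
    err_df = pd.DataFrame(
        {
            "representation": [r.representation_tag for r in reports],
            "lag_frames": [r.lag for r in reports],
            "lag_ps": [theta.lag_time(r.lag) for r in reports],
            "mean_error": [r.mean_error for r in reports],
            "q25": [float(np.quantile(r.per_frame_error, 0.25)) for r in reports],
            "q75": [float(np.quantile(r.per_frame_error, 0.75)) for r in reports],
        }
    )
    _write_csv(err_df, out / "prediction_errors.csv", artifacts)
    results["errors"] = err_df

    # structural evaluation at lag 1: rebuild and superpose a few frames
    if theta.n_angles % 2 == 0 and theta.n_angles >= 2:
        from .evaluation import RepresentationPredictor

        split = int(theta.n_frames * config.train_fraction)
        predictor = RepresentationPredictor(representation="theta", lag=1).fit(
            theta.values[:split]
        )
        pred, ref = predictor.predict_angles(theta.values[split:])
        take = np.linspace(0, pred.shape[0] - 1, min(20, pred.shape[0])).astype(int)
        rmsds = [
            rmsd(
                build_backbone_trajectory(pred[t][None, :])[0].atoms,
                build_backbone_trajectory(ref[t][None, :])[0].atoms,
            )
            for t in take
        ]
        _write_csv(
            pd.DataFrame({"frame": take, "rmsd_angstrom": rmsds}),
            out / "reconstruction_rmsd.csv",
            artifacts,
        )
        results["mean_rmsd"] = float(np.mean(rmsds))

    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        fh.write("torsiondyn pipeline run\n")
        for key, value in asdict(config).items():
            fh.write(f"config.{key} = {value}\n")
        for art in artifacts:
            fh.write(f"artifact: {art.name}\n")
    results["manifest"] = manifest
    results["artifacts"] = artifacts
    logger.info("pipeline wrote %d artifacts to %s", len(artifacts), out)
    return results
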