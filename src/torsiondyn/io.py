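"""File I/O: angle tables (CSV/TSV) and multi-model PDB structure series.

Angle tables are one row per frame, a header of angle names in the
canonical psi1, phi2, ..., phim ordering, and an optional leading ``time_ps``
column.  Structures travel as standard multi-model PDB (one MODEL per
frame, backbone N/CA/C ATOM records), read and written through biotite.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .reconstruction import BackboneStructure
from .torus import AngleTrajectory, wrap_to_interval

logger = logging.getLogger("torsiondyn")

__all__ = [
    "read_angle_table",
    "write_angle_table",
    "read_backbone_pdb",
    "write_backbone_pdb",
]

TIME_COLUMN = "time_ps"


def read_angle_table(
    path: str | Path,
    sep: str | None = None,
    frame_spacing: float | None = None,
    radians: bool = False,
) -> AngleTrajectory:
    """Read an angle table from CSV/TSV.

    A ``time_ps`` column, when present, sets the frame spacing.  Angles
    outside [-180, 180) are wrapped with a logged warning.  ``radians=True``
    converts the table from radians on input.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or non-numeric rows")
    spacing = frame_spacing
    if TIME_COLUMN in df.columns:
        times = df.pop(TIME_COLUMN).to_numpy(dtype=float)
        if spacing is None and times.size > 1:
            spacing = float(np.median(np.diff(times)))
    values = df.to_numpy(dtype=float)
    if radians:
        values = np.degrees(values)
    if np.any(values < -180.0) or np.any(values >= 180.0):
        logger.warning("%s: angles outside [-180, 180); wrapping", path)
        values = np.asarray(wrap_to_interval(values))
    return AngleTrajectory(
        values=values,
        angle_names=[str(c) for c in df.columns],
        frame_spacing=spacing or 4.0,
    )


def write_angle_table(
    trajectory: AngleTrajectory,
    path: str | Path,
    sep: str = ",",
    include_time: bool = True,
    float_format: str = "%.9f",
) -> Path:
    """Write an angle table; read_angle_table round-trips within 1e-9 deg."""
    path = Path(path)
    df = pd.DataFrame(trajectory.values, columns=trajectory.angle_names)
    if include_time:
        df.insert(
            0,
            TIME_COLUMN,
            np.arange(trajectory.n_frames) * trajectory.frame_spacing,
        )
    df.to_csv(path, sep=sep, index=False, float_format=float_format)
    return path


_BACKBONE_ATOMS = ("N", "CA", "C")


def write_backbone_pdb(
    structures: list[BackboneStructure], path: str | Path
) -> Path:
    """Write a structure series as a multi-model PDB (backbone ATOM records)."""
    structures = list(structures)
    if not structures:
        raise ValueError("no structures to write")
    m = structures[0].n_residues
    n_atoms = 3 * m
    template = struc.AtomArray(n_atoms)
    template.chain_id = np.full(n_atoms, "A")
    template.res_id = np.repeat(np.arange(1, m + 1), 3)
    template.res_name = np.full(n_atoms, "GLY")
    template.atom_name = np.array(list(_BACKBONE_ATOMS) * m)
    template.element = np.array(["N", "C", "C"] * m)
    template.hetero = np.full(n_atoms, False)

    stack = struc.AtomArrayStack(len(structures), n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    for i, s in enumerate(structures):
        if s.n_residues != m:
            raise ValueError("all structures must have the same residue count")
        stack.coord[i] = s.atoms
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    return Path(path)


def read_backbone_pdb(path: str | Path) -> list[BackboneStructure]:
    """Read backbone N/CA/C coordinates from a multi-model PDB file."""
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    structures = []
    for model in stack:
        res_ids = np.unique(model.res_id)
        coords = np.empty((res_ids.size, 3, 3))
        for ri, rid in enumerate(res_ids):
            for ai, name in enumerate(_BACKBONE_ATOMS):
                sel = (model.res_id == rid) & (model.atom_name == name)
                if sel.sum() != 1:
                    raise ValueError(
                        f"residue {rid}: expected exactly one {name} atom"
                    )
                coords[ri, ai] = model.coord[sel][0]
        structures.append(BackboneStructure(coords=coords))
    return structures
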