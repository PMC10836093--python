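"""Readers/writers and trajectory utilities.

Multi-model PDB is the ensemble exchange format (MODEL/ENDMDL records,
1-based residue numbering, chain A); feature trajectories and link tables
are CSV with a header row; analysis results serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .ensembles import ConformerEnsemble
from .msm_kinetics import FeatureTrajectory

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "subsample_trajectory",
    "write_feature_csv",
    "read_feature_csv",
    "write_json",
]


def write_ensemble(ens: ConformerEnsemble, path) -> None:
    """Write a multi-model PDB (chain A, residue numbering preserved)."""
    n_atoms = ens.n_atoms
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = ens.coords[0].astype(np.float32)
    atoms.chain_id = np.full(n_atoms, "A", dtype="U4")
    atoms.res_id = ens.atoms["res_id"].to_numpy(dtype=int)
    atoms.res_name = ens.atoms["res_name"].to_numpy(dtype="U5")
    atoms.atom_name = ens.atoms["atom_name"].to_numpy(dtype="U6")
    atoms.element = np.full(n_atoms, "C", dtype="U2")
    stack = struc.stack([atoms] * ens.n_frames)
    stack.coord = ens.coords.astype(np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_ensemble(path, fmt: str = "pdb_multimodel") -> ConformerEnsemble:
    """Read a multi-model PDB into a ConformerEnsemble.

    Frames are ordered by MODEL index; an inconsistent atom table across
    models is an error citing the model number.
    """
    if fmt != "pdb_multimodel":
        raise ValueError(f"unsupported format {fmt!r}")
    f = pdb.PDBFile.read(str(path))
    n_models = f.get_model_count()
    ref = None
    coords = []
    for m in range(1, n_models + 1):
        atoms = f.get_structure(model=m)
        table = np.stack([atoms.res_id.astype(str), atoms.res_name,
                          atoms.atom_name], axis=1)
        if ref is None:
            ref = table
            ref_atoms = atoms
        elif table.shape != ref.shape or (table != ref).any():
            raise ValueError(f"MODEL {m}: atom table differs from MODEL 1")
        coords.append(atoms.coord.astype(float))
    atom_df = pd.DataFrame({
        "res_id": ref_atoms.res_id.astype(int),
        "res_name": ref_atoms.res_name,
        "atom_name": ref_atoms.atom_name,
    })
    return ConformerEnsemble(np.stack(coords), atom_df,
                             {"source": str(path), "format": "pdb_multimodel"})


def subsample_trajectory(obj, target_dt: float, source_dt: float | None = None):
    """Subsample to a coarser time grid.

    Keeps frames at times 0, target_dt, 2*target_dt, ...; ``target_dt`` must
    be an integer multiple of the source step.  For a span T that lies on the
    target grid this gives ``floor(T/target_dt) + 1`` frames.  Works on
    ConformerEnsemble (source dt from metadata or ``source_dt``) and
    FeatureTrajectory (dt attribute); units must match between the two dts.
    """
    if isinstance(obj, FeatureTrajectory):
        src = obj.dt
    else:
        src = source_dt if source_dt is not None else obj.metadata.get("dt")
    if src is None:
        raise ValueError("source time step unknown; pass source_dt")
    ratio = target_dt / src
    stride = int(round(ratio))
    if abs(ratio - stride) > 1e-9 or stride < 1:
        raise ValueError(
            f"target_dt={target_dt} is not an integer multiple of source dt={src}")
    if isinstance(obj, FeatureTrajectory):
        return FeatureTrajectory(obj.values[::stride], obj.feature_labels,
                                 dt=target_dt)
    out = ConformerEnsemble(obj.coords[::stride], obj.atoms.copy(),
                            dict(obj.metadata))
    out.metadata["dt"] = target_dt
    return out


def write_feature_csv(ft: FeatureTrajectory, path) -> None:
    df = pd.DataFrame(ft.values, columns=ft.feature_labels)
    df.insert(0, "time", np.arange(len(df)) * ft.dt)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> FeatureTrajectory:
    df = pd.read_csv(path)
    dt = float(df["time"].iloc[1] - df["time"].iloc[0]) if len(df) > 1 else 1.0
    cols = [c for c in df.columns if c != "time"]
    return FeatureTrajectory(df[cols].to_numpy(), cols, dt)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))
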