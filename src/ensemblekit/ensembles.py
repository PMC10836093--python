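"""Conformer ensembles: the core in-memory container for multi-frame coordinates.

A :class:`ConformerEnsemble` holds an ordered stack of frames over a fixed
atom table.  Coordinates are stored in Angstrom throughout the package;
nanometre values are converted at I/O and configuration boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConformerEnsemble", "concatenate"]


@dataclass
class ConformerEnsemble:
    """Ordered frames of labelled atomic coordinates for one chain.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atoms
        DataFrame with one row per atom and columns ``res_id`` (1-based
        residue index), ``res_name`` and ``atom_name``.  The atom table is
        shared by every frame.
    metadata
        Free-form provenance (source, seed, time step in ps, ...).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but frames carry "
                f"{self.coords.shape[1]} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        for col in ("res_id", "res_name", "atom_name"):
            if col not in self.atoms.columns:
                raise ValueError(f"atom table missing required column {col!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique 1-based residue indices present in the atom table."""
        return np.unique(self.atoms["res_id"].to_numpy())

    def select(self, atom_names=None, res_ids=None) -> np.ndarray:
        """Boolean mask over atoms matching the given names and/or residues."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            names = {atom_names} if isinstance(atom_names, str) else set(atom_names)
            mask &= self.atoms["atom_name"].isin(names).to_numpy()
        if res_ids is not None:
            ids = {res_ids} if np.isscalar(res_ids) else set(int(r) for r in res_ids)
            mask &= self.atoms["res_id"].isin(ids).to_numpy()
        return mask

    def atom_indices(self, atom_names=None, res_ids=None) -> np.ndarray:
        return np.flatnonzero(self.select(atom_names=atom_names, res_ids=res_ids))

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i``, shape ``(n_atoms, 3)``."""
        return self.coords[i]

    def ca_positions(self, res_id: int) -> np.ndarray:
        """Per-frame Cα position of one residue, shape ``(n_frames, 3)``."""
        idx = self.atom_indices(atom_names="CA", res_ids=res_id)
        if idx.size != 1:
            raise ValueError(f"residue {res_id} has {idx.size} CA atoms, expected 1")
        return self.coords[:, idx[0], :]


def concatenate(*ensembles: ConformerEnsemble) -> ConformerEnsemble:
    """Stack ensembles frame-wise; atom tables must be identical."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    ref = ensembles[0]
    for e in ensembles[1:]:
        same = (
            len(e.atoms) == len(ref.atoms)
            and (e.atoms[["res_id", "res_name", "atom_name"]].to_numpy()
                 == ref.atoms[["res_id", "res_name", "atom_name"]].to_numpy()).all()
        )
        if not same:
            raise ValueError("cannot concatenate ensembles with differing atom tables")
    coords = np.concatenate([e.coords for e in ensembles], axis=0)
    meta = {"source": "concatenate",
            "parts": [e.metadata.get("source", "?") for e in ensembles]}
    return ConformerEnsemble(coords, ref.atoms.copy(), meta)
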