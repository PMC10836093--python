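"""Distance-map, group-distance, RMSD, clustering and turn-register analyses
of conformer ensembles.

The turn-register statistic classifies a beta-hairpin's strand register from
three marker residues (roles "4", "7" and "12" in the 18-residue peptide
frame): rho = d(Ca_4, Ca_12) / d(Ca_7, Ca_12).  A turn centred on the
conserved PGGG motif gives rho near 1; a left-shifted (N-terminally shifted)
turn gives rho < 0.75 and a right-shifted turn rho > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .ensembles import ConformerEnsemble

__all__ = [
    "DistanceMap",
    "ClusterResult",
    "RegisterProfile",
    "LEFT_THRESHOLD",
    "RIGHT_THRESHOLD",
    "min_distance_map",
    "group_com_distance",
    "turn_register",
    "rmsd",
    "pairwise_rmsd",
    "gromos_cluster",
]

# register classification bounds on rho = d(4,12)/d(7,12)
LEFT_THRESHOLD = 0.75
RIGHT_THRESHOLD = 1.0


@dataclass
class DistanceMap:
    """Mean minimum inter-residue distance matrix (Angstrom)."""

    residues: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residues, columns=self.residues)


@dataclass
class ClusterResult:
    """GROMOS clustering output; clusters ordered by decreasing size."""

    cutoff: float  # nm, as conventionally quoted
    assignments: np.ndarray  # frame -> cluster label
    populations: np.ndarray  # per-cluster frame fraction, non-increasing
    centers: np.ndarray  # central frame index per cluster


@dataclass
class RegisterProfile:
    """Per-frame turn-register ratio and classification."""

    ratio: np.ndarray
    classification: np.ndarray  # 'left' | 'centered' | 'right' per frame
    index_map: dict  # which absolute residues play roles 4, 7, 12
    n_degenerate: int = 0  # frames excluded for a zero denominator

    def summary(self) -> dict:
        ok = np.isfinite(self.ratio)
        counts = pd.Series(self.classification[ok]).value_counts()
        return {
            "mean_ratio": float(np.mean(self.ratio[ok])) if ok.any() else float("nan"),
            "fractions": {k: float(counts.get(k, 0) / max(ok.sum(), 1))
                          for k in ("left", "centered", "right")},
            "n_degenerate": self.n_degenerate,
        }


def _resolve_selection(ens: ConformerEnsemble, selection) -> np.ndarray:
    """Selection -> atom index array.  Accepts None (all atoms), an atom-name
    string or iterable of names, or a precomputed boolean mask / index array."""
    if selection is None:
        return np.arange(ens.n_atoms)
    if isinstance(selection, str) or (
        hasattr(selection, "__iter__") and all(isinstance(s, str) for s in selection)
    ):
        return ens.atom_indices(atom_names=selection)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        return np.flatnonzero(sel)
    return sel.astype(int)


def min_distance_map(ens: ConformerEnsemble, selection=None) -> DistanceMap:
    """Mean over frames of the minimum atom–atom distance between residues.

    Entry (i, j) is the frame-average of ``min_{a in i, b in j} |r_a - r_b|``
    over atoms in the selection, the quantity a residue-level contact map
    ("mdmat"-style) reports.
    """
    idx = _resolve_selection(ens, selection)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    res = np.unique(ens.atoms["res_id"].to_numpy()[idx])
    if res.size < 2:
        raise ValueError("selection must span at least 2 residues")
    if ens.n_frames < 1:
        raise ValueError("ensemble has no frames")

    groups = [idx[ens.atoms["res_id"].to_numpy()[idx] == r] for r in res]
    n = res.size
    acc = np.zeros((n, n))
    for f in range(ens.n_frames):
        xyz = ens.coords[f]
        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(xyz[groups[i]], xyz[groups[j]]).min()
                acc[i, j] += d
                acc[j, i] += d
    acc /= ens.n_frames
    return DistanceMap(res, acc, {"units": "angstrom", "n_frames": ens.n_frames})


def group_com_distance(ens: ConformerEnsemble, groupA, groupB,
                       selection=None, masses=None) -> np.ndarray:
    """Per-frame distance between the centroids of two residue groups.

    Centroids are unweighted by default; pass per-atom ``masses`` for a true
    centre of mass.  Groups must be disjoint, non-empty residue sets.
    """
    groupA, groupB = set(int(r) for r in groupA), set(int(r) for r in groupB)
    if not groupA or not groupB:
        raise ValueError("groups must be non-empty")
    if groupA & groupB:
        raise ValueError(f"groups overlap: {sorted(groupA & groupB)}")
    sel = _resolve_selection(ens, selection)
    res_ids = ens.atoms["res_id"].to_numpy()
    ia = sel[np.isin(res_ids[sel], list(groupA))]
    ib = sel[np.isin(res_ids[sel], list(groupB))]
    if ia.size == 0 or ib.size == 0:
        raise ValueError("a group selects no atoms")

    def centroid(idx):
        pts = ens.coords[:, idx, :]
        if masses is not None:
            m = np.asarray(masses, dtype=float)[idx]
            return (pts * m[None, :, None]).sum(axis=1) / m.sum()
        return pts.mean(axis=1)

    return np.linalg.norm(centroid(ia) - centroid(ib), axis=1)


def turn_register(ens: ConformerEnsemble,
                  role_indices: tuple = (4, 7, 12)) -> RegisterProfile:
    """Per-frame register ratio rho = d(Ca_i4, Ca_i12) / d(Ca_i7, Ca_i12).

    Frames with a vanishing denominator are flagged as degenerate (NaN ratio)
    and excluded from the summary with a warning count.  The ratio is
    invariant under rigid motion and uniform scaling of coordinates.
    """
    i4, i7, i12 = role_indices
    if len({i4, i7, i12}) != 3:
        raise ValueError("role indices must be three distinct residues")
    p4 = ens.ca_positions(i4)
    p7 = ens.ca_positions(i7)
    p12 = ens.ca_positions(i12)
    num = np.linalg.norm(p4 - p12, axis=1)
    den = np.linalg.norm(p7 - p12, axis=1)
    degenerate = den < 1e-12
    ratio = np.where(degenerate, np.nan, num / np.where(degenerate, 1.0, den))
    cls = np.full(ens.n_frames, "centered", dtype=object)
    cls[ratio < LEFT_THRESHOLD] = "left"
    cls[ratio > RIGHT_THRESHOLD] = "right"
    cls[degenerate] = "degenerate"
    n_bad = int(degenerate.sum())
    if n_bad:
        warnings.warn(f"{n_bad} frame(s) with coincident Ca positions excluded")
    return RegisterProfile(ratio, np.asarray(cls),
                           {"role4": i4, "role7": i7, "role12": i12}, n_bad)


def _kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Least-squares superposition RMSD via the Kabsch algorithm."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    m = mobile - mu_m
    r = reference - mu_r
    rot, _ = Rotation.align_vectors(r, m)
    diff = m @ rot.as_matrix().T - r
    return float(np.sqrt((diff**2).sum() / len(mobile)))


def rmsd(mobile, reference, selection=None, ens: ConformerEnsemble = None) -> float:
    """RMSD after optimal rigid superposition (fit and measure on the same
    selection, matching standard trajectory-tool behaviour).

    ``mobile``/``reference`` are coordinate arrays of shape (n_atoms, 3); if
    ``ens`` is given with a selection, the selection is resolved on its atom
    table and applied to both frames.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ens is not None and selection is not None:
        idx = _resolve_selection(ens, selection)
        mobile, reference = mobile[idx], reference[idx]
    if mobile.shape != reference.shape:
        raise ValueError(f"atom count mismatch: {mobile.shape} vs {reference.shape}")
    if len(mobile) == 0:
        raise ValueError("empty selection")
    return _kabsch_rmsd(mobile, reference)


def pairwise_rmsd(ens: ConformerEnsemble, stride: int = 1,
                  selection=None) -> np.ndarray:
    """Symmetric matrix of fitted RMSD between strided frames (Angstrom)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = _resolve_selection(ens, selection)
    frames = ens.coords[::stride, idx, :]
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _kabsch_rmsd(frames[i], frames[j])
    return mat


def gromos_cluster(ens: ConformerEnsemble, cutoff_nm: float,
                   selection=None, stride: int = 1) -> ClusterResult:
    """GROMOS conformational clustering under an RMSD cutoff.

    Iteratively, the frame with the most neighbours within ``cutoff_nm``
    (fitted RMSD) becomes a cluster centre; it and its neighbours are removed
    and the search repeats on the remainder.  Ties on neighbour count break
    to the lowest frame index for deterministic output.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be > 0")
    if ens.n_frames == 0:
        raise ValueError("empty ensemble")
    cutoff_a = cutoff_nm * 10.0  # nm -> Angstrom
    dmat = pairwise_rmsd(ens, stride=stride, selection=selection)
    n = dmat.shape[0]
    neighbor = dmat <= cutoff_a
    np.fill_diagonal(neighbor, True)

    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers, sizes = [], []
    label = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining)
        assignments[members] = label
        centers.append(center)
        sizes.append(members.size)
        remaining[members] = False
        label += 1

    order = np.argsort(-np.asarray(sizes), kind="stable")
    relabel = np.empty(label, dtype=int)
    relabel[order] = np.arange(label)
    assignments = relabel[assignments]
    centers = np.asarray(centers)[order]
    populations = np.asarray(sizes, dtype=float)[order] / n
    return ClusterResult(cutoff_nm, assignments, populations, centers)
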