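"""Chemical-shift secondary-structure propensity and ensemble NOE distances.

Secondary Hα shifts (observed minus random coil) carry secondary-structure
information: upfield (negative) deviations indicate helix, downfield
(positive) deviations indicate β-extension.  The neighbour-corrected
propensity averages the normalized deviation over a sliding window so that
values near +1 mean fully helical and near -1 fully extended.

NOE cross-peak intensities scale as r^-6, so the ensemble-effective distance
for a proton pair is ``r_eff = <r^-6>^(-1/6)``, which is dominated by the
closest-approach frames; pairs with ``r_eff`` below ~4 A are expected to be
observable for a small peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble

__all__ = [
    "RANDOM_COIL_HA",
    "HELIX_DEV_HA",
    "SHEET_DEV_HA",
    "ShiftSeries",
    "PropensityProfile",
    "secondary_shifts",
    "ncsp",
    "noe_effective_distances",
]

# Random-coil Halpha chemical shifts (ppm), standard random-coil scale.
RANDOM_COIL_HA = {
    "A": 4.32, "R": 4.34, "N": 4.74, "D": 4.64, "C": 4.55,
    "Q": 4.34, "E": 4.35, "G": 3.96, "H": 4.63, "I": 4.17,
    "L": 4.38, "K": 4.32, "M": 4.48, "F": 4.62, "P": 4.42,
    "S": 4.47, "T": 4.35, "W": 4.66, "Y": 4.55, "V": 4.12,
}

# Full-structure Halpha secondary deviations (ppm): mean shift change on
# going from coil to fully formed helix / sheet.
HELIX_DEV_HA = -0.38
SHEET_DEV_HA = +0.38


@dataclass
class ShiftSeries:
    """Observed, random-coil and secondary Hα shifts per residue."""

    residues: np.ndarray  # 1-based indices, monotonic
    aa: np.ndarray  # one-letter codes
    delta_obs: np.ndarray
    delta_rc: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def secondary(self) -> np.ndarray:
        return self.delta_obs - self.delta_rc


@dataclass
class PropensityProfile:
    """Neighbour-corrected secondary-structure propensity per residue.

    Positive values indicate helical propensity, negative β-extended;
    magnitude ~1 corresponds to a fully formed structure element.
    """

    residues: np.ndarray
    ncSP: np.ndarray
    window: int
    n_clamped: int = 0


def secondary_shifts(obs: pd.DataFrame,
                     rc_table: dict | None = None) -> ShiftSeries:
    """Secondary shifts Δδ = δ_obs - δ_rc from an observed-shift table.

    ``obs`` needs columns ``res_id``, ``aa`` and ``shift_ppm`` (Hα).  The
    random-coil reference is looked up per amino-acid type; a missing type is
    an error naming the residue.
    """
    rc_table = rc_table or RANDOM_COIL_HA
    obs = obs.sort_values("res_id")
    res = obs["res_id"].to_numpy()
    aa = obs["aa"].astype(str).to_numpy()
    shifts = obs["shift_ppm"].to_numpy(dtype=float)
    if not np.isfinite(shifts).all():
        raise ValueError("observed shifts must be finite")
    rc = np.empty_like(shifts)
    for i, (r, a) in enumerate(zip(res, aa)):
        if a not in rc_table:
            raise ValueError(f"no random-coil reference for residue {r} (type {a!r})")
        rc[i] = rc_table[a]
    return ShiftSeries(res, aa, shifts, rc, {"reference": "random-coil Halpha"})


def ncsp(series: ShiftSeries, window: int = 3,
         clamp: float = 1.5) -> PropensityProfile:
    """Neighbour-corrected secondary-structure propensity from Hα shifts.

    Each residue's score is the uniform-weight average over the window
    (residue ± window, truncated at the termini) of its neighbours'
    normalized secondary shifts ``-Δδ / |ref|`` where ``ref`` is the
    full-helix deviation for negative Δδ and the full-sheet deviation
    otherwise.  The leading sign makes positive = helical for Hα (full-helix
    Hα deviations are negative).  Values are clamped to ``[-clamp, clamp]``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    dd = series.secondary
    ref = np.where(dd < 0, abs(HELIX_DEV_HA), abs(SHEET_DEV_HA))
    norm = -dd / ref
    n = len(norm)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        out[i] = norm[lo:hi].mean()
    clipped = np.abs(out) > clamp
    out = np.clip(out, -clamp, clamp)
    return PropensityProfile(series.residues.copy(), out, window,
                             int(clipped.sum()))


@dataclass
class EffectiveDistanceMap:
    """Ensemble-averaged NOE effective distances per atom pair."""

    pairs: list  # (label1, label2)
    r_eff: np.ndarray  # Angstrom
    observable: np.ndarray  # r_eff < threshold
    threshold: float


def noe_effective_distances(ens: ConformerEnsemble, pair_list,
                            threshold: float = 4.0) -> EffectiveDistanceMap:
    """Effective NOE distances ``r_eff = <r^-6>^(-1/6)`` per atom pair.

    ``pair_list`` entries are ``((res_i, atom_i), (res_j, atom_j))``.  The
    r^-6 weighting makes r_eff sit between the per-frame minimum and the
    arithmetic mean distance, biased toward close approach as NOESY
    intensities are.  A zero inter-atomic distance in any frame is a
    nonphysical overlap and raises.
    """
    r_eff = np.empty(len(pair_list))
    labels = []
    for k, ((ri, ai), (rj, aj)) in enumerate(pair_list):
        ii = ens.atom_indices(atom_names=ai, res_ids=ri)
        jj = ens.atom_indices(atom_names=aj, res_ids=rj)
        if ii.size != 1 or jj.size != 1:
            raise ValueError(f"pair ({ri}:{ai}, {rj}:{aj}) not uniquely resolvable")
        r = np.linalg.norm(ens.coords[:, ii[0], :] - ens.coords[:, jj[0], :], axis=1)
        if (r <= 0).any():
            raise ValueError(f"zero distance for pair ({ri}:{ai}, {rj}:{aj}); "
                             "nonphysical atomic overlap")
        r_eff[k] = float(np.mean(r ** -6.0) ** (-1.0 / 6.0))
        labels.append((f"{ri}:{ai}", f"{rj}:{aj}"))
    return EffectiveDistanceMap(labels, r_eff, r_eff < threshold, threshold)
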