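"""Ground-truth generators: idealized peptide ensembles, Markov trajectories
with known kinetics, and replicate cross-link tables.

Every generator is a deterministic function of (spec, seed).  The geometric
fixtures are Cα-only: downstream distance operations accept arbitrary atom
selections, so the Cα trace stands in for backbone/proton atoms in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble

__all__ = [
    "CA_CA_BOND",
    "HairpinSpec",
    "MarkovEmissionSpec",
    "SyntheticLinkSpec",
    "make_hairpin_ensemble",
    "make_extended_ensemble",
    "simulate_markov_trajectory",
    "make_crosslink_tables",
    "hairpin_pairing",
]

# Virtual Ca-Ca bond length of a trans peptide unit (Angstrom).
CA_CA_BOND = 3.8


def _atom_table(n_res: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "res_id": np.arange(1, n_res + 1),
            "res_name": ["GLY"] * n_res,
            "atom_name": ["CA"] * n_res,
        }
    )


# ---------------------------------------------------------------------------
# Hairpin / extended ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinSpec:
    """Idealized antiparallel beta-hairpin of Cα pseudo-atoms.

    ``apex`` is the residue immediately N-terminal of the turn apex
    (1-based); residue ``i`` is cross-strand paired with residue
    ``2*apex + 1 - i``.  ``strand_sep`` is the cross-strand Cα–Cα distance
    and ``rise`` the per-residue strand rise, both in Angstrom.
    """

    n_res: int
    apex: int
    strand_sep: float = 4.8
    rise: float = CA_CA_BOND
    noise_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_res < 4:
            raise ValueError(f"n_res must be >= 4, got {self.n_res}")
        if not (2 <= self.apex <= self.n_res - 2):
            raise ValueError(f"apex must be in [2, n_res-2], got {self.apex}")
        if self.strand_sep <= 0:
            raise ValueError(f"strand_sep must be > 0, got {self.strand_sep}")
        if self.rise <= 0:
            raise ValueError(f"rise must be > 0, got {self.rise}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        # the apex pinch requires |strand_sep - bond| < 2*bond
        if abs(self.strand_sep - CA_CA_BOND) / 2 >= CA_CA_BOND:
            raise ValueError("strand_sep too far from the 3.8 A virtual bond "
                             "for a closable turn")


def hairpin_pairing(apex: int, i: int) -> int:
    """Cross-strand partner of residue ``i`` for a turn at ``apex``."""
    return 2 * apex + 1 - i


def hairpin_template(spec: HairpinSpec) -> np.ndarray:
    """Noiseless Cα template, shape (n_res, 3).

    Two antiparallel straight strands parallel to x, separated by
    ``strand_sep`` along y.  Strand residues sit exactly opposite their
    cross-strand partner.  The two apex residues are pinched toward each
    other (and advanced along x) so that every consecutive Cα–Cα distance,
    including the bond across the turn, is exactly 3.8 A; the apex pair is
    therefore the one pair not at ``strand_sep``.
    """
    spec.validate()
    a, ss, rise = spec.apex, spec.strand_sep, spec.rise
    xyz = np.zeros((spec.n_res, 3))
    # pinch of the two apex residues toward each other along y
    delta = (ss - CA_CA_BOND) / 2.0
    t = np.sqrt(CA_CA_BOND**2 - delta**2)  # x-advance keeping the 3.8 A bond
    for r in range(1, spec.n_res + 1):
        if r < a:  # N-strand
            xyz[r - 1] = (r * rise, 0.0, 0.0)
        elif r == a:
            xyz[r - 1] = ((a - 1) * rise + t, delta, 0.0)
        elif r == a + 1:
            xyz[r - 1] = ((a - 1) * rise + t, ss - delta, 0.0)
        else:  # C-strand, runs back antiparallel; partner p may be <= 0 for tails
            p = hairpin_pairing(a, r)
            xyz[r - 1] = (p * rise, ss, 0.0)
    return xyz


def make_hairpin_ensemble(spec: HairpinSpec) -> ConformerEnsemble:
    """Generate ``n_frames`` noisy copies of the idealized hairpin template."""
    template = hairpin_template(spec)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, spec.n_res, 3)) \
        if spec.noise_sd > 0 else np.zeros((spec.n_frames, spec.n_res, 3))
    coords = template[None, :, :] + noise
    meta = {"source": "make_hairpin_ensemble", "seed": spec.seed,
            "apex": spec.apex, "strand_sep": spec.strand_sep,
            "noise_sd": spec.noise_sd}
    return ConformerEnsemble(coords, _atom_table(spec.n_res), meta)


def make_extended_ensemble(n_res: int, noise_sd: float = 0.0,
                           n_frames: int = 1, seed: int = 0) -> ConformerEnsemble:
    """Straight-line Cα chain with 3.8 A spacing plus isotropic noise."""
    if n_res < 2:
        raise ValueError(f"n_res must be >= 2, got {n_res}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    template = np.zeros((n_res, 3))
    template[:, 0] = np.arange(n_res) * CA_CA_BOND
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(n_frames, n_res, 3)) \
        if noise_sd > 0 else np.zeros((n_frames, n_res, 3))
    coords = template[None, :, :] + noise
    meta = {"source": "make_extended_ensemble", "seed": seed, "noise_sd": noise_sd}
    return ConformerEnsemble(coords, _atom_table(n_res), meta)


# ---------------------------------------------------------------------------
# Markov trajectories with Gaussian emissions
# ---------------------------------------------------------------------------

@dataclass
class MarkovEmissionSpec:
    """Macrostate chain with per-state Gaussian feature emissions.

    ``T_true`` is row-stochastic; ``means``/``covs`` give one emission
    centre/covariance per state; ``lag_unit`` is the physical time per step
    in ns.
    """

    T_true: np.ndarray
    means: np.ndarray
    covs: np.ndarray | None = None
    n_steps: int = 100_000
    lag_unit: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        T = np.asarray(self.T_true, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("T_true must be square")
        if (T < 0).any():
            raise ValueError("T_true entries must be non-negative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of T_true must sum to 1 within 1e-12")
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if means.shape[0] != T.shape[0]:
            raise ValueError("means count must equal state count")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def n_states(self) -> int:
        return np.asarray(self.T_true).shape[0]


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_markov_trajectory(spec: MarkovEmissionSpec):
    """Simulate a state sequence and Gaussian feature emissions.

    The chain starts from the stationary distribution of ``T_true``.
    Returns ``(states, features)`` where ``states`` has shape (n_steps,)
    and ``features`` shape (n_steps, n_features); both are reproducible for
    a fixed seed.
    """
    spec.validate()
    T = np.asarray(spec.T_true, dtype=float)
    means = np.atleast_2d(np.asarray(spec.means, dtype=float))
    n_states, n_feat = means.shape
    covs = spec.covs
    if covs is None:
        covs = np.stack([np.eye(n_feat)] * n_states)
    else:
        covs = np.asarray(covs, dtype=float)
        if covs.ndim == 1:  # per-state isotropic variances
            covs = np.stack([v * np.eye(n_feat) for v in covs])

    rng = np.random.default_rng(spec.seed)
    pi = stationary_distribution(T)
    states = np.empty(spec.n_steps, dtype=np.int64)
    states[0] = rng.choice(n_states, p=pi)
    # vectorized chain stepping via inverse-CDF lookup per state
    cum = np.cumsum(T, axis=1)
    u = rng.random(spec.n_steps - 1)
    for k in range(1, spec.n_steps):
        states[k] = np.searchsorted(cum[states[k - 1]], u[k - 1], side="right")
    chols = np.stack([np.linalg.cholesky(c) for c in covs])
    z = rng.standard_normal((spec.n_steps, n_feat))
    features = means[states] + np.einsum("nij,nj->ni", chols[states], z)
    return states, features


# ---------------------------------------------------------------------------
# Replicate cross-link tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLinkSpec:
    """Replicate cross-link tables with a known contact-order distribution.

    ``class_weights`` are sampling weights for (local, intermediate, long)
    residue-separation classes; quality fields are drawn from the stated
    per-field distributions so that the generator knows, per record, whether
    it passes the identification filters.

    Each ``*_dist`` entry is ``(lo, hi)`` for a uniform draw.
    """

    n_res: int
    lysines: tuple
    class_weights: tuple = (1.0, 1.0, 1.0)
    n_replicates: int = 5
    n_links_per_rep: int = 100
    score_dist: tuple = (10.0, 50.0)
    fdr_dist: tuple = (0.0, 0.10)
    ppm_dist: tuple = (-5.0, 5.0)
    tic_dist: tuple = (0.0, 40.0)
    pep_len_dist: tuple = (4, 20)
    seed: int = 0

    def validate(self) -> None:
        lys = np.asarray(self.lysines)
        if lys.size == 0 or (lys < 1).any() or (lys > self.n_res).any():
            raise ValueError("lysines must lie within [1, n_res]")
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("class_weights must be 3 non-negative weights, not all zero")
        if self.n_links_per_rep > 0 and lys.size < 2:
            raise ValueError("need at least 2 lysines to generate cross-links")


# contact-order class bounds on |pos2 - pos1|
_CLASS_BOUNDS = {"local": (1, 10), "intermediate": (11, 39), "long": (40, None)}


def make_crosslink_tables(spec: SyntheticLinkSpec,
                          thresholds: dict | None = None) -> pd.DataFrame:
    """Generate replicate-tagged cross-link records with ground truth.

    Returns a DataFrame in the package's standard link-table layout
    (kind, pos1, pos2, score, fdr, mass_error_ppm, tic_pct, pep_len,
    replicate, nseen) plus bookkeeping columns ``true_class`` and
    ``true_pass`` (evaluated against ``thresholds``, default the standard
    identification filter set).
    """
    from .xlms_contacts import DEFAULT_THRESHOLDS, record_passes

    spec.validate()
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    rng = np.random.default_rng(spec.seed)
    lys = np.sort(np.asarray(spec.lysines, dtype=int))
    # enumerate candidate pairs per class
    pairs_by_class: dict[str, list] = {c: [] for c in _CLASS_BOUNDS}
    for i in range(lys.size):
        for j in range(i + 1, lys.size):
            s = lys[j] - lys[i]
            for cls, (lo, hi) in _CLASS_BOUNDS.items():
                if s >= lo and (hi is None or s <= hi):
                    pairs_by_class[cls].append((lys[i], lys[j]))
    classes = ("local", "intermediate", "long")
    w = np.asarray(spec.class_weights, dtype=float)
    avail = np.array([len(pairs_by_class[c]) > 0 for c in classes])
    w = np.where(avail, w, 0.0)
    if w.sum() == 0:
        raise ValueError("no lysine pair realizes any class with positive weight")
    w = w / w.sum()

    rows = []
    for rep in range(1, spec.n_replicates + 1):
        cls_idx = rng.choice(3, size=spec.n_links_per_rep, p=w)
        for ci in cls_idx:
            cls = classes[ci]
            pool = pairs_by_class[cls]
            p1, p2 = pool[rng.integers(len(pool))]
            rec = {
                "kind": "crosslink",
                "pos1": int(p1),
                "pos2": int(p2),
                "score": rng.uniform(*spec.score_dist),
                "fdr": rng.uniform(*spec.fdr_dist),
                "mass_error_ppm": rng.uniform(*spec.ppm_dist),
                "tic_pct": rng.uniform(*spec.tic_dist),
                "pep_len": int(rng.integers(spec.pep_len_dist[0],
                                            spec.pep_len_dist[1] + 1)),
                "replicate": f"rep{rep}",
                "nseen": int(rng.integers(1, 20)),
            }
            rec["true_class"] = cls
            rec["true_pass"] = record_passes(rec, thr)
            rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    df.attrs["class_weights"] = tuple(np.asarray(spec.class_weights, float))
    return df
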