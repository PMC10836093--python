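"""Post-search cross-link mass-spectrometry analysis.

Takes replicate tables of identified mono-links / loop-links / cross-links
(xQuest-style columns) and applies the downstream analysis: identification
filters, replicate consensus, within-replicate frequency normalization,
contact-order classification (local / intermediate / long by residue
separation), repeat-domain binning, hierarchical clustering of link
patterns across constructs, and peptide-level modification fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_REPEAT_BINS",
    "CONTACT_CLASSES",
    "record_passes",
    "filter_ids",
    "consensus",
    "normalize_frequency",
    "classify_contact_order",
    "bin_by_repeat",
    "cluster_link_patterns",
    "modification_fractions",
]

# Identification filter thresholds: xQuest score > 25, FDR < 0.05,
# mass error in [-2.2, +3.8] ppm, %TIC > 10, peptide length >= 6 aa.
DEFAULT_THRESHOLDS = {
    "score_min": 25.0,      # strict: score must exceed this
    "fdr_max": 0.05,        # strict: fdr must be below this
    "ppm_low": -2.2,        # inclusive
    "ppm_high": 3.8,        # inclusive
    "tic_min": 10.0,        # strict
    "pep_len_min": 6,       # inclusive
}

# tauRD repeat bounds in 2N4R numbering (1-based, inclusive)
DEFAULT_REPEAT_BINS = {
    "R1": (244, 274),
    "R2": (275, 305),
    "R3": (306, 336),
    "R4": (337, 368),
    "R'": (369, 380),
}

# contact-order classes on residue separation s = |pos2 - pos1|
CONTACT_CLASSES = (("local", 0, 10), ("intermediate", 11, 39),
                   ("long", 40, None))

# DSS mono-link mass shifts (Da), d0/d12 isotope pair; metadata constants
# used for input validation only.
DSS_MONOLINK_MASSES = (156.0786442, 155.0964278)

REQUIRED_COLUMNS = ["kind", "pos1", "score", "fdr", "mass_error_ppm",
                    "tic_pct", "pep_len", "replicate", "nseen"]


def record_passes(rec: dict, thresholds: dict | None = None) -> bool:
    """Evaluate one record against the identification filter set."""
    t = thresholds or DEFAULT_THRESHOLDS
    return bool(
        rec["score"] > t["score_min"]
        and rec["fdr"] < t["fdr_max"]
        and t["ppm_low"] <= rec["mass_error_ppm"] <= t["ppm_high"]
        and rec["tic_pct"] > t["tic_min"]
        and rec["pep_len"] >= t["pep_len_min"]
    )


def filter_ids(records: pd.DataFrame, thresholds: dict | None = None):
    """Apply the identification filters; returns (retained, rejection_log).

    ``rejection_log`` counts, per criterion, how many records failed it
    (a record can fail several); malformed rows (NaN in a filter field) are
    skipped and counted under ``malformed``.
    """
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"link table missing columns: {missing}")

    fields = ["score", "fdr", "mass_error_ppm", "tic_pct", "pep_len"]
    ok_rows = records[fields].notna().all(axis=1)
    log = {"malformed": int((~ok_rows).sum())}
    df = records[ok_rows]

    crit = {
        "score": df["score"] > t["score_min"],
        "fdr": df["fdr"] < t["fdr_max"],
        "mass_error_ppm": df["mass_error_ppm"].between(t["ppm_low"], t["ppm_high"]),
        "tic_pct": df["tic_pct"] > t["tic_min"],
        "pep_len": df["pep_len"] >= t["pep_len_min"],
    }
    keep = np.ones(len(df), dtype=bool)
    for name, mask in crit.items():
        m = mask.to_numpy()
        log[f"rejected_{name}"] = int((~m).sum())
        keep &= m
    retained = df[keep].copy()
    log["retained"] = len(retained)
    log["input"] = len(records)
    return retained, log


def consensus(tables, n_required: int | None = None) -> pd.DataFrame:
    """Unique (pos1, pos2) pairs present in at least ``n_required`` replicates.

    ``tables`` is one concatenated DataFrame (with a ``replicate`` column) or
    a list of per-replicate DataFrames.  Default ``n_required`` is the number
    of replicates (all-of-all consensus).  Returns one row per retained link
    with the replicate count and per-replicate total nseen.
    """
    if isinstance(tables, (list, tuple)):
        parts = []
        for i, tdf in enumerate(tables):
            tdf = tdf.copy()
            if "replicate" not in tdf.columns:
                tdf["replicate"] = f"rep{i + 1}"
            parts.append(tdf)
        df = pd.concat(parts, ignore_index=True)
    else:
        df = tables.copy()
    reps = sorted(df["replicate"].unique())
    if n_required is None:
        n_required = len(reps)
    pos2 = df["pos2"] if "pos2" in df.columns else np.nan
    key = pd.DataFrame({"pos1": df["pos1"], "pos2": pos2,
                        "replicate": df["replicate"],
                        "nseen": df.get("nseen", 1)})
    grouped = (key.groupby(["pos1", "pos2"], dropna=False)
               .agg(n_replicates=("replicate", "nunique"),
                    total_nseen=("nseen", "sum"))
               .reset_index())
    out = grouped[grouped["n_replicates"] >= n_required].reset_index(drop=True)
    out.attrs["n_required"] = n_required
    out.attrs["replicates"] = reps
    return out


def normalize_frequency(tables, mode: str = "replicate_total") -> pd.DataFrame:
    """Normalized link frequencies with per-link mean and SD across replicates.

    ``mode='replicate_total'`` (default) divides each record's nseen by its
    replicate's total nseen, so values within a replicate sum to 1;
    ``mode='raw'`` keeps raw nseen.  Returns one row per (pos1, pos2) with
    columns ``mean_freq`` and ``sd_freq`` plus the per-replicate values.
    """
    if isinstance(tables, (list, tuple)):
        df = pd.concat(tables, ignore_index=True)
    else:
        df = tables.copy()
    if mode not in ("replicate_total", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    df = df.copy()
    if mode == "replicate_total":
        totals = df.groupby("replicate")["nseen"].transform("sum")
        if (df.groupby("replicate")["nseen"].sum() <= 0).any():
            raise ValueError("a replicate has zero total nseen")
        df["freq"] = df["nseen"] / totals
    else:
        df["freq"] = df["nseen"].astype(float)
    pos2 = df["pos2"] if "pos2" in df.columns else np.nan
    df["_pos2"] = pos2
    wide = (df.groupby(["pos1", "_pos2", "replicate"], dropna=False)["freq"]
            .sum().unstack("replicate", fill_value=0.0))
    out = wide.reset_index().rename(columns={"_pos2": "pos2"})
    rep_cols = list(wide.columns)
    out["mean_freq"] = wide.mean(axis=1).to_numpy()
    out["sd_freq"] = wide.std(axis=1, ddof=0).to_numpy()
    out.attrs["replicate_columns"] = rep_cols
    out.attrs["mode"] = mode
    return out


def classify_contact_order(pos1: int, pos2: int) -> str:
    """Contact-order class from residue separation: local (<=10),
    intermediate (11-39) or long (>=40)."""
    if pos1 is None or pos2 is None or (isinstance(pos2, float) and np.isnan(pos2)):
        raise ValueError("contact order requires both link positions (not a monolink)")
    s = abs(int(pos2) - int(pos1))
    for name, lo, hi in CONTACT_CLASSES:
        if s >= lo and (hi is None or s <= hi):
            return name
    raise AssertionError("unreachable")


def contact_class_summary(links: pd.DataFrame,
                          weight_col: str | None = None) -> pd.Series:
    """Normalized per-class totals over a link table (optionally weighted)."""
    classes = [classify_contact_order(p1, p2)
               for p1, p2 in zip(links["pos1"], links["pos2"])]
    w = links[weight_col].to_numpy(float) if weight_col else np.ones(len(links))
    out = pd.Series(0.0, index=[c for c, _, _ in CONTACT_CLASSES])
    for c, wi in zip(classes, w):
        out[c] += wi
    return out / out.sum()


def bin_by_repeat(position: int, bins: dict | None = None) -> str:
    """Repeat-domain label for a residue position; 'outside' if in no bin."""
    bins = bins or DEFAULT_REPEAT_BINS
    prev_hi = None
    for name, (lo, hi) in bins.items():
        if lo > hi or (prev_hi is not None and lo <= prev_hi):
            raise ValueError("repeat bins must be ordered, non-overlapping intervals")
        prev_hi = hi
        if lo <= position <= hi:
            return name
    return "outside"


@dataclass
class LinkClustering:
    labels: np.ndarray  # group label per link column, 1..n_groups
    linkage_matrix: np.ndarray
    columns: list
    n_groups: int
    tree: dict = field(default_factory=dict)  # nested dendrogram


def _linkage_tree(Z: np.ndarray, labels: list) -> dict:
    """Serialize a scipy linkage matrix as a nested dict (newick-like)."""
    n = len(labels)
    nodes = {i: {"name": str(labels[i]), "height": 0.0} for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        nodes[n + k] = {"children": [nodes[int(a)], nodes[int(b)]],
                        "height": float(h)}
    return nodes[n + len(Z) - 1] if len(Z) else nodes[0]


def cluster_link_patterns(matrix: pd.DataFrame, n_groups: int = 4) -> LinkClustering:
    """Average-linkage hierarchical clustering of link columns.

    ``matrix`` is constructs x links of normalized frequency.  Euclidean
    distances between link columns feed average linkage; the dendrogram is
    cut to ``n_groups``.  A constant matrix collapses to one group with a
    warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 links to cluster")
    X = matrix.to_numpy(dtype=float).T  # one row per link
    if np.allclose(X, X[0]):
        warnings.warn("constant link matrix; returning a single group")
        Z = linkage(X, method="average", metric="euclidean")
        labels = np.ones(X.shape[0], dtype=int)
        return LinkClustering(labels, Z, list(matrix.columns), 1,
                              _linkage_tree(Z, list(matrix.columns)))
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return LinkClustering(labels, Z, list(matrix.columns), n_groups,
                          _linkage_tree(Z, list(matrix.columns)))


def modification_fractions(peak_areas: dict) -> dict:
    """Fraction of total peak area per modification state.

    ``peak_areas`` maps state names (e.g. unmodified, monolink1, monolink2,
    looplink) to non-negative areas; fractions sum to 1.
    """
    vals = {k: float(v) for k, v in peak_areas.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("peak areas must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("total peak area must be positive")
    return {k: v / total for k, v in vals.items()}
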