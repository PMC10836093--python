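"""Markov-state-model kinetics: featurization, tICA, discretization, MSM
estimation and validation, PCCA+ coarse-graining and transition path theory.

The estimation chain mirrors standard MSM practice: minimum inter-residue
distances as features, tICA to isolate slow collective coordinates, k-means
microstates, a transition matrix at a chosen lag validated by implied
timescales and the Chapman-Kolmogorov test, PCCA+ macrostates, and committor
/ flux analysis between chosen end states.

Conventions
-----------
* Lag times and trajectory indices are in frames; physical time enters only
  through ``dt`` (ns per frame) at reporting.
* The reversible estimator symmetrizes the count matrix, ``C_bar = (C+C')/2``
  then row-normalizes, so detailed balance holds in closed form and the
  stationary distribution equals the normalized row sums of ``C_bar``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .ensembles import ConformerEnsemble

__all__ = [
    "FeatureTrajectory",
    "TICAModel",
    "Discretization",
    "MarkovModel",
    "CoarseGraining",
    "TPTResult",
    "featurize_min_distances",
    "tica_fit",
    "kmeans_discretize",
    "estimate_msm",
    "markov_model_from_matrix",
    "implied_timescales",
    "vamp2_score",
    "ck_test",
    "pcca",
    "mfpt",
    "tpt",
    "free_energy_surface",
    "state_distance_profiles",
]


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrajectory:
    """Frames x features matrix with residue-pair labels; dt in ns/frame."""

    values: np.ndarray
    feature_labels: list
    dt: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("label count must match feature column count")


def featurize_min_distances(ens: ConformerEnsemble, groupA, groupB,
                            dt: float = 1.0) -> FeatureTrajectory:
    """Per-frame minimum atom–atom distance for every residue pair (a, b)
    with a in groupA and b in groupB; |A|*|B| feature columns."""
    groupA, groupB = [int(r) for r in groupA], [int(r) for r in groupB]
    if not groupA or not groupB:
        raise ValueError("groups must be non-empty")
    if set(groupA) & set(groupB):
        raise ValueError("groups must be disjoint")
    res_ids = ens.atoms["res_id"].to_numpy()
    present = set(np.unique(res_ids))
    for r in groupA + groupB:
        if r not in present:
            raise ValueError(f"residue {r} absent from ensemble")
    idx = {r: np.flatnonzero(res_ids == r) for r in set(groupA) | set(groupB)}
    pairs = [(a, b) for a in groupA for b in groupB]
    vals = np.empty((ens.n_frames, len(pairs)))
    for f in range(ens.n_frames):
        xyz = ens.coords[f]
        for c, (a, b) in enumerate(pairs):
            vals[f, c] = cdist(xyz[idx[a]], xyz[idx[b]]).min()
    labels = [f"{a}-{b}" for a, b in pairs]
    return FeatureTrajectory(vals, labels, dt)


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    """Time-lagged independent component analysis solution.

    Components solve the generalized eigenproblem of the symmetrized
    time-lagged covariance against the instantaneous covariance of mean-free
    data; eigenvalues are lag-tau autocorrelations of the projections.
    """

    lag: int
    components: np.ndarray  # (n_features, n_components), column = tIC loading
    eigenvalues: np.ndarray  # sorted descending
    mean: np.ndarray

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        X = _feature_matrix(X)
        W = self.components if n_components is None else self.components[:, :n_components]
        return (X - self.mean) @ W


def _feature_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureTrajectory):
        return X.values
    return np.asarray(X, dtype=float)


def tica_fit(data, lag: int) -> TICAModel:
    """Fit tICA at the given lag (frames).

    Singular instantaneous covariance is regularized by adding
    ``eps*I, eps = 1e-10 * trace/dim`` with a warning; covariances are
    symmetrized to enforce a real spectrum.
    """
    X = _feature_matrix(data)
    n, d = X.shape
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n <= lag:
        raise ValueError("need more frames than the lag")
    mean = X.mean(axis=0)
    Xc = X - mean
    A, B = Xc[:-lag], Xc[lag:]
    m = n - lag
    C0 = 0.5 * (A.T @ A + B.T @ B) / m
    Ct = 0.5 * (A.T @ B + B.T @ A) / m
    # regularize if C0 is (near-)singular
    if np.linalg.matrix_rank(C0, tol=1e-12 * max(np.trace(C0), 1.0)) < d:
        eps = 1e-10 * np.trace(C0) / d
        warnings.warn(f"singular instantaneous covariance; adding {eps:.3e} ridge")
        C0 = C0 + eps * np.eye(d)
    vals, vecs = eigh(Ct, C0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return TICAModel(lag=lag, components=vecs, eigenvalues=vals, mean=mean)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    centers: np.ndarray
    dtrajs: list  # list of integer label arrays, one per trajectory
    seed: int = 0


def kmeans_discretize(projected, k: int, seed: int = 0) -> Discretization:
    """k-means (k-means++ init, fixed seed) over reduced coordinates.

    ``projected`` may be one matrix or a list of per-trajectory matrices.
    """
    trajs = projected if isinstance(projected, (list, tuple)) else [projected]
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs]
    trajs = [t.T if t.shape[0] == 1 and t.shape[1] > 1 else t for t in trajs]
    X = np.concatenate(trajs, axis=0)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available frames")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    dtrajs, at = [], 0
    for t in trajs:
        dtrajs.append(km.labels_[at:at + len(t)].astype(np.int64))
        at += len(t)
    return Discretization(km.cluster_centers_, dtrajs, seed)


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Discrete-state, discrete-lag Markov model over the active set."""

    lag: int  # frames
    C: np.ndarray  # count matrix (active set)
    T: np.ndarray  # row-stochastic transition matrix
    pi: np.ndarray  # stationary distribution
    eigenvalues: np.ndarray  # sorted by decreasing magnitude, real
    eigenvectors_right: np.ndarray  # columns, matching eigenvalues
    active_set: np.ndarray  # original microstate labels retained
    reversible: bool = True
    dt: float = 1.0  # ns per frame
    discarded_fraction: float = 0.0

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_time(self) -> float:
        """Physical lag time in ns."""
        return self.lag * self.dt

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied relaxation timescales -tau/ln(lambda_i) in ns, skipping the
        unit eigenvalue; NaN marks eigenvalues outside (0, 1)."""
        lam = self.eigenvalues[1:]
        if n is not None:
            lam = lam[:n]
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where((lam > 0) & (lam < 1.0 - 1e-12),
                          -self.lag_time / np.log(lam), np.nan)
        return ts


def _as_dtraj_list(dtrajs) -> list:
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        return [dtrajs.astype(np.int64)]
    if isinstance(dtrajs, (list, tuple)):
        return [np.asarray(d, dtype=np.int64) for d in dtrajs]
    return [np.asarray(dtrajs, dtype=np.int64)]


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag."""
    dtrajs = _as_dtraj_list(dtrajs)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        if len(d) > lag:
            np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    graph = csr_matrix((C > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # weight components by total counts so the data-rich component wins
    best, best_w = 0, -1.0
    for c in range(n_comp):
        w = C[np.ix_(labels == c, labels == c)].sum()
        if w > best_w:
            best, best_w = c, w
    return np.flatnonzero(labels == best)


def estimate_msm(dtrajs, lag: int, reversible: bool = True,
                 dt: float = 1.0) -> MarkovModel:
    """Estimate a Markov state model from discrete trajectories.

    Counts use a sliding window at the lag; the model is restricted to the
    largest strongly connected set.  The reversible estimate symmetrizes
    counts before row-normalization, which enforces detailed balance exactly.
    """
    C_full = count_matrix(dtrajs, lag)
    if C_full.sum() == 0:
        raise ValueError("no transitions observed at this lag")
    active = _largest_scc(C_full)
    if active.size == 0:
        raise ValueError("count graph has no connected states")
    if active.size == 1 and C_full[active[0], active[0]] == 0:
        raise ValueError("count graph is all-singleton; cannot estimate a model")
    C = C_full[np.ix_(active, active)]
    discarded = 1.0 - C.sum() / C_full.sum()

    if reversible:
        Cs = 0.5 * (C + C.T)
        rows = Cs.sum(axis=1)
        T = Cs / rows[:, None]
        pi = rows / rows.sum()
        # symmetric similarity transform gives a real spectrum
        s = np.sqrt(pi)
        Sym = (s[:, None] * T) / s[None, :]
        Sym = 0.5 * (Sym + Sym.T)
        vals, vecs = np.linalg.eigh(Sym)
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        right = vecs[:, order] / s[:, None]
        # normalize sign so the first right eigenvector is +1
        right[:, 0] = np.abs(right[:, 0])
    else:
        rows = C.sum(axis=1)
        if (rows == 0).any():
            raise ValueError("state with no outgoing counts in the active set")
        T = C / rows[:, None]
        vals_c, vecs_c = np.linalg.eig(T)
        order = np.argsort(-np.abs(vals_c))
        vals = np.real(vals_c[order])
        right = np.real(vecs_c[:, order])
        lv, lvec = np.linalg.eig(T.T)
        i = np.argmin(np.abs(lv - 1.0))
        pi = np.abs(np.real(lvec[:, i]))
        pi = pi / pi.sum()

    return MarkovModel(lag=lag, C=C, T=T, pi=pi, eigenvalues=vals,
                       eigenvectors_right=right, active_set=active,
                       reversible=reversible, dt=dt,
                       discarded_fraction=float(discarded))


def markov_model_from_matrix(T, lag: int = 1, dt: float = 1.0) -> MarkovModel:
    """Wrap a known transition matrix as a MarkovModel (e.g. ground truth).

    The stationary distribution is computed from the matrix; the spectral
    decomposition uses the symmetric similarity transform when the matrix
    satisfies detailed balance and a general eigendecomposition otherwise.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be square")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10) or (T < 0).any():
        raise ValueError("T must be row-stochastic")
    from .synthetic_data import stationary_distribution
    pi = stationary_distribution(T)
    reversible = np.allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-10)
    if reversible and (pi <= 0).any():
        # degenerate stationary vector (reducible chain): the similarity
        # transform is ill-defined, fall back to the general decomposition
        reversible = False
    if reversible:
        s = np.sqrt(pi)
        Sym = 0.5 * ((s[:, None] * T) / s[None, :]
                     + ((s[:, None] * T) / s[None, :]).T)
        vals, vecs = np.linalg.eigh(Sym)
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        right = vecs[:, order] / s[:, None]
        right[:, 0] = np.abs(right[:, 0])
    else:
        vals_c, vecs_c = np.linalg.eig(T)
        order = np.argsort(-np.abs(vals_c))
        vals = np.real(vals_c[order])
        right = np.real(vecs_c[:, order])
    return MarkovModel(lag=lag, C=pi[:, None] * T, T=T, pi=pi,
                       eigenvalues=vals, eigenvectors_right=right,
                       active_set=np.arange(T.shape[0]),
                       reversible=bool(reversible), dt=dt)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def implied_timescales(dtrajs, lags, n: int = 5, reversible: bool = True,
                       dt: float = 1.0) -> pd.DataFrame:
    """Implied timescale table t_i(tau) = -tau/ln lambda_i(tau).

    One row per lag; columns ``t1..tn`` (ns).  Eigenvalues outside (0, 1)
    yield NaN markers rather than exceptions.
    """
    rows = []
    for lag in lags:
        if lag < 1:
            raise ValueError("all lags must be >= 1")
        m = estimate_msm(dtrajs, lag=int(lag), reversible=reversible, dt=dt)
        ts = m.timescales(n)
        ts = np.concatenate([ts, np.full(max(0, n - ts.size), np.nan)])
        rows.append([lag * dt] + list(ts[:n]))
    return pd.DataFrame(rows, columns=["lag"] + [f"t{i+1}" for i in range(n)])


def vamp2_score(model: MarkovModel, k: int) -> float:
    """Sum of squares of the top-k transition-matrix eigenvalues (includes
    the unit eigenvalue); higher means slower resolved processes."""
    if k > model.n_states:
        raise ValueError("k exceeds state count")
    return float(np.sum(model.eigenvalues[:k] ** 2))


def _coarse_grain_T(T: np.ndarray, pi: np.ndarray, sets: list) -> np.ndarray:
    """Pi-weighted projection of a microstate matrix onto crisp macrostates."""
    m = len(sets)
    P = np.zeros((m, m))
    for I, si in enumerate(sets):
        wi = pi[si]
        Z = wi.sum()
        for J, sj in enumerate(sets):
            P[I, J] = (wi[:, None] * T[np.ix_(si, sj)]).sum() / Z
    return P


def ck_test(dtrajs, model: MarkovModel, factors, n_macro: int) -> pd.DataFrame:
    """Chapman-Kolmogorov test on a fixed PCCA+ macrostate partition.

    For each lag multiple f, compares the macrostate self-transition
    probabilities predicted by propagating the base model, ``T(tau)^f``,
    against a model re-estimated from the data at lag ``f*tau`` and
    coarse-grained on the same partition.
    """
    cg = pcca(model, n_macro)
    # crisp sets in original microstate labels
    sets_labels = [model.active_set[cg.crisp == I] for I in range(n_macro)]
    max_len = max(len(d) for d in _as_dtraj_list(dtrajs))
    rows = []
    for f in factors:
        f = int(f)
        if f < 1:
            raise ValueError("factors must be >= 1")
        if f * model.lag >= max_len:
            raise ValueError(f"lag {f * model.lag} exceeds trajectory length")
        # predicted: propagate the base model
        Tf = np.linalg.matrix_power(model.T, f)
        sets_base = [np.flatnonzero(np.isin(model.active_set, s)) for s in sets_labels]
        pred = _coarse_grain_T(Tf, model.pi, sets_base)
        # estimated: re-estimate at the longer lag, same partition
        m2 = estimate_msm(dtrajs, lag=f * model.lag, reversible=model.reversible,
                          dt=model.dt)
        sets_est = [np.flatnonzero(np.isin(m2.active_set, s)) for s in sets_labels]
        if any(s.size == 0 for s in sets_est):
            raise ValueError("a macrostate vanished from the active set at "
                             f"lag factor {f}")
        est = _coarse_grain_T(m2.T, m2.pi, sets_est)
        for I in range(n_macro):
            rows.append({"macrostate": I, "factor": f,
                         "predicted": pred[I, I], "estimated": est[I, I]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining
# ---------------------------------------------------------------------------

@dataclass
class CoarseGraining:
    """Fuzzy microstate -> macrostate memberships from PCCA+."""

    n_macro: int
    memberships: np.ndarray  # (n_micro, n_macro), rows sum to 1
    crisp: np.ndarray  # argmax macrostate per microstate
    macro_populations: np.ndarray
    model: MarkovModel = field(repr=False, default=None)

    def coarse_transition_matrix(self) -> np.ndarray:
        """Crisp-set, pi-weighted macrostate transition matrix."""
        sets = [np.flatnonzero(self.crisp == I) for I in range(self.n_macro)]
        return _coarse_grain_T(self.model.T, self.model.pi, sets)


def _inner_simplex(evecs: np.ndarray) -> np.ndarray:
    """Deuflhard-Weber index search: rows of ``evecs`` spanning the largest
    simplex in eigenvector space; returns the vertex row indices."""
    n, m = evecs.shape
    index = np.zeros(m, dtype=int)
    ortho = evecs.copy()
    norms = np.linalg.norm(ortho, axis=1)
    index[0] = int(np.argmax(norms))
    ortho = ortho - ortho[index[0]]
    for j in range(1, m):
        temp = ortho[index[j - 1]].copy()
        tn = np.linalg.norm(temp)
        if tn > 0:
            temp /= tn
        ortho = ortho - np.outer(ortho @ temp, temp)
        dists = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(dists))
        if dists[index[j]] > 0:
            ortho = ortho / dists[index[j]]
    return index


def pcca(model: MarkovModel, n_macro: int) -> CoarseGraining:
    """PCCA+ lumping of microstates into metastable macrostates.

    Applies the inner-simplex transformation to the top ``n_macro`` right
    eigenvectors of a reversible model; memberships are the simplex
    coordinates, clipped to [0, 1] and row-renormalized; crisp labels by
    argmax; macro populations sum stationary weight over crisp members.
    """
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible model (real spectrum); "
                         "re-estimate with reversible=True")
    if not (2 <= n_macro <= model.n_states):
        raise ValueError("n_macro must be in [2, n_states]")
    evecs = model.eigenvectors_right[:, :n_macro].copy()
    # scale the constant eigenvector to exactly 1
    evecs = evecs / evecs[0, 0]
    evecs[:, 0] = 1.0
    idx = _inner_simplex(evecs)
    A = np.linalg.inv(evecs[idx])
    chi = evecs @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    pops = np.array([model.pi[crisp == I].sum() for I in range(n_macro)])
    return CoarseGraining(n_macro, chi, crisp, pops, model)


# ---------------------------------------------------------------------------
# MFPT and transition path theory
# ---------------------------------------------------------------------------

def _model_T_pi(model):
    if isinstance(model, CoarseGraining):
        T = model.coarse_transition_matrix()
        pi = model.macro_populations
        lag_time = model.model.lag_time
    else:
        T, pi, lag_time = model.T, model.pi, model.lag_time
    return np.asarray(T), np.asarray(pi), lag_time


def mfpt(model, source, target) -> float:
    """Mean first-passage time from source to target states (physical time).

    Solves ``m_i = tau + sum_j T_ij m_j`` with ``m = 0`` on the target; the
    reported value is the stationary-weighted average over source states.
    """
    T, pi, lag_time = _model_T_pi(model)
    n = T.shape[0]
    source = np.asarray(sorted({int(s) for s in source}))
    target = np.asarray(sorted({int(s) for s in target}))
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise ValueError("source and target must be disjoint")
    keep = np.setdiff1d(np.arange(n), target)
    A = np.eye(keep.size) - T[np.ix_(keep, keep)]
    try:
        m_keep = np.linalg.solve(A, np.full(keep.size, lag_time))
    except np.linalg.LinAlgError as e:
        raise ValueError("target unreachable from some states") from e
    if (m_keep < -1e-9).any() or not np.isfinite(m_keep).all():
        raise ValueError("target unreachable from some states")
    m = np.zeros(n)
    m[keep] = m_keep
    w = pi[source] / pi[source].sum()
    return float(w @ m[source])


@dataclass
class TPTResult:
    """Committors, reactive fluxes and pathway decomposition between two
    macrostate sets A (source) and B (sink)."""

    A: np.ndarray
    B: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    F: np.ndarray  # gross flux
    f_net: np.ndarray  # net flux
    total_flux: float
    pathways: list  # [(state tuple, flux), ...] in decreasing flux order
    mfpt_matrix: np.ndarray | None = None

    @property
    def pathway_fractions(self) -> list:
        return [(p, f / self.total_flux) for p, f in self.pathways]


def _committor(T: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = T.shape[0]
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if inter.size:
        M = np.eye(inter.size) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        q[inter] = np.linalg.solve(M, rhs)
    return q


def _widest_path(f: np.ndarray, A: set, B: set):
    """Max-bottleneck path from any state in A to any state in B on the
    positive-flux digraph; Dijkstra with a max-heap on bottleneck capacity."""
    n = f.shape[0]
    best = np.zeros(n)
    prev = np.full(n, -1)
    heap = []
    for a in A:
        best[a] = np.inf
        heapq.heappush(heap, (-np.inf, a))
    visited = np.zeros(n, dtype=bool)
    while heap:
        negcap, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in B:
            bottleneck = best[u]
            path = [u]
            while prev[u] != -1:
                u = prev[u]
                path.append(u)
            return path[::-1], float(bottleneck)
        for v in np.flatnonzero(f[u] > 0):
            cap = min(best[u], f[u, v])
            if cap > best[v]:
                best[v] = cap
                prev[v] = u
                heapq.heappush(heap, (-cap, v))
    return None, 0.0


def tpt(model, A, B) -> TPTResult:
    """Transition path theory between disjoint state sets A and B.

    Computes forward/backward committors, gross flux
    ``F_ij = pi_i q-_i T_ij q+_j``, net flux ``max(0, F_ij - F_ji)``, the
    total reactive flux out of A, and a pathway decomposition by iterative
    removal of the widest (max-bottleneck) path.
    """
    T, pi, lag_time = _model_T_pi(model)
    n = T.shape[0]
    A = np.asarray(sorted({int(s) for s in A}))
    B = np.asarray(sorted({int(s) for s in B}))
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")

    q_plus = _committor(T, A, B)
    # backward committor from the time-reversed chain; for reversible
    # models this is exactly 1 - q_plus
    T_rev = (pi[None, :] * T.T) / pi[:, None]
    q_minus = _committor(T_rev, B, A)

    F = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(F, 0.0)
    f_net = np.clip(F - F.T, 0.0, None)
    notA = np.setdiff1d(np.arange(n), A)
    total = float(f_net[np.ix_(A, notA)].sum())

    # pathway decomposition on a working copy of the net flux
    pathways = []
    residual = f_net.copy()
    Aset, Bset = set(A.tolist()), set(B.tolist())
    remaining = total
    while remaining > 1e-8 * max(total, 1e-300):
        path, bottleneck = _widest_path(residual, Aset, Bset)
        if path is None or bottleneck <= 0:
            break
        for u, v in zip(path[:-1], path[1:]):
            residual[u, v] -= bottleneck
        pathways.append((tuple(path), float(bottleneck)))
        remaining -= bottleneck

    # per-step flux is probability per lag; convert to rate-like per ns
    return TPTResult(A=A, B=B, q_plus=q_plus, q_minus=q_minus, F=F,
                     f_net=f_net, total_flux=total, pathways=pathways)


def mfpt_matrix(model, sets: list) -> np.ndarray:
    """Pairwise MFPT (ns) between macrostate sets; diagonal zero."""
    m = len(sets)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                out[i, j] = mfpt(model, sets[i], sets[j])
    return out


# ---------------------------------------------------------------------------
# Landscapes and per-state geometry
# ---------------------------------------------------------------------------

def free_energy_surface(projected: np.ndarray, n_bins: int = 50,
                        weights=None):
    """-ln(histogram) over the first two reduced coordinates, shifted so the
    minimum is 0; empty bins are +inf (unreachable)."""
    X = np.asarray(projected, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("projected data must have at least 2 columns")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=n_bins, weights=weights)
    with np.errstate(divide="ignore"):
        F = -np.log(H / H.sum())
    F = F - F[np.isfinite(F)].min()
    return F, xe, ye


# default marker distances of the 18-residue peptide frame, all Ca-Ca
_DEFAULT_PAIRS = {
    "n_to_c": [(1, 18)],
    "mid": [(3, 17), (4, 16), (5, 15)],
    "c_term": [(7, 18)],
    "n_term": [(1, 12)],
}


def state_distance_profiles(ens: ConformerEnsemble, macro_labels,
                            pairs: dict | None = None,
                            register_roles=(4, 7, 12)) -> pd.DataFrame:
    """Per-macrostate mean +/- SD of marker Ca distances and the
    turn-register ratio; states with no frames are omitted with a warning.

    Multi-pair entries (e.g. the mid-register markers) are averaged per frame
    before the state statistics.
    """
    from .ensemble_metrics import turn_register

    pairs = pairs or _DEFAULT_PAIRS
    labels = np.asarray(macro_labels)
    if labels.shape[0] != ens.n_frames:
        raise ValueError("one macrostate label per frame required")

    per_frame = {}
    for name, plist in pairs.items():
        d = np.zeros(ens.n_frames)
        for (a, b) in plist:
            d += np.linalg.norm(ens.ca_positions(a) - ens.ca_positions(b), axis=1)
        per_frame[name] = d / len(plist)
    per_frame["register_ratio"] = turn_register(ens, register_roles).ratio

    rows = []
    for state in np.unique(labels):
        mask = labels == state
        if not mask.any():
            warnings.warn(f"macrostate {state} has no frames; omitted")
            continue
        row = {"state": state, "n_frames": int(mask.sum())}
        for name, d in per_frame.items():
            row[f"{name}_mean"] = float(np.nanmean(d[mask]))
            row[f"{name}_sd"] = float(np.nanstd(d[mask]))
        rows.append(row)
    return pd.DataFrame(rows)
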