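"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: quaternion (Horn)
superposition for RMSD, a literal greedy neighbour-count clustering, and
Monte-Carlo first-passage / reactive-trajectory counters for Markov chains.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    Sxx, Sxy, Sxz = (x[:, 0] * y[:, 0]).sum(), (x[:, 0] * y[:, 1]).sum(), (x[:, 0] * y[:, 2]).sum()
    Syx, Syy, Syz = (x[:, 1] * y[:, 0]).sum(), (x[:, 1] * y[:, 1]).sum(), (x[:, 1] * y[:, 2]).sum()
    Szx, Szy, Szz = (x[:, 2] * y[:, 0]).sum(), (x[:, 2] * y[:, 1]).sum(), (x[:, 2] * y[:, 2]).sum()
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    msd = ((x**2).sum() + (y**2).sum() - 2.0 * lam) / len(x)
    return float(np.sqrt(max(msd, 0.0)))


def greedy_cluster_oracle(dmat: np.ndarray, cutoff: float):
    """Literal greedy rule: repeatedly take the frame with the most
    neighbours within cutoff (lowest index on ties) and remove its set."""
    n = dmat.shape[0]
    remaining = set(range(n))
    assignments = {}
    clusters = []
    while remaining:
        best, best_members = None, None
        for i in sorted(remaining):
            members = {j for j in remaining if dmat[i, j] <= cutoff}
            if best is None or len(members) > len(best_members):
                best, best_members = i, members
        clusters.append((best, sorted(best_members)))
        for j in best_members:
            assignments[j] = len(clusters) - 1
        remaining -= best_members
    return clusters, assignments


def mc_mfpt(T: np.ndarray, source: int, target: set, n_runs: int, seed: int) -> float:
    """Monte-Carlo mean first-passage time (in steps) from one state."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    total = 0
    for _ in range(n_runs):
        s, t = source, 0
        while s not in target:
            s = int(np.searchsorted(cum[s], rng.random(), side="right"))
            t += 1
        total += t
    return total / n_runs


def mc_reactive_flux(T: np.ndarray, A: set, B: set, n_steps: int, seed: int):
    """Count reactive A->B passages in one long trajectory.

    Returns (flux_per_step, path_counts) where path_counts maps the tuple of
    distinct intermediate-visited state sequences (loops pruned to last exit
    from A / first entry to B, with immediate revisits collapsed) to counts.
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    pi0 = np.linalg.matrix_power(T, 1000)[0]
    s = int(rng.choice(len(T), p=pi0 / pi0.sum()))
    last_label = "A" if s in A else ("B" if s in B else None)
    segment = [s]
    n_reactive = 0
    path_counts = {}
    for _ in range(n_steps):
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        segment.append(s)
        if s in A:
            last_label, segment = "A", [s]
        elif s in B:
            if last_label == "A":
                n_reactive += 1
                # the reactive piece: from the last A state to this B state
                path = []
                for x in segment:
                    if not path or path[-1] != x:
                        path.append(x)
                key = tuple(path)
                path_counts[key] = path_counts.get(key, 0) + 1
            last_label, segment = "B", [s]
    return n_reactive / n_steps, path_counts
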