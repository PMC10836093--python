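import numpy as np
import pandas as pd
import pytest

from ensemblekit import msm_kinetics as mk
from ensemblekit.synthetic_data import (
    MarkovEmissionSpec,
    simulate_markov_trajectory,
    stationary_distribution,
)

from .oracles import mc_mfpt, mc_reactive_flux


def two_state(a, b):
    return np.array([[1 - a, a], [b, 1 - b]])


def symmetric_walk(n):
    T = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            T[i, i - 1] = 0.5
        if i < n - 1:
            T[i, i + 1] = 0.5
    T[0, 0] = 0.5
    T[-1, -1] = 0.5
    return T


class TestFeaturize:
    def test_pair_count_is_product_of_group_sizes(self, hairpin18):
        ft = mk.featurize_min_distances(hairpin18, range(1, 8), range(12, 19))
        assert ft.values.shape[1] == 49
        ft2 = mk.featurize_min_distances(hairpin18, [1, 2], [5, 6, 7])
        assert ft2.values.shape[1] == 6

    def test_single_atom_residues_give_plain_distances(self, hairpin18):
        ft = mk.featurize_min_distances(hairpin18, [1], [18])
        x = hairpin18.coords[0]
        assert ft.values[0, 0] == pytest.approx(np.linalg.norm(x[0] - x[17]))

    def test_absent_residue_named_in_error(self, hairpin18):
        with pytest.raises(ValueError, match="99"):
            mk.featurize_min_distances(hairpin18, [1, 99], [12])


class TestTica:
    def ar1(self, phi, n, seed, sd=1.0):
        rng = np.random.default_rng(seed)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, sd, n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        return x

    def test_ar1_eigenvalue_is_autocorrelation(self):
        x = self.ar1(0.8, 100_000, seed=1)[:, None]
        model = mk.tica_fit(x, lag=1)
        assert model.eigenvalues[0] == pytest.approx(0.8, abs=0.02)

    def test_recovers_slow_direction_under_mixing(self):
        slow = self.ar1(0.99, 100_000, seed=2)
        fast = self.ar1(0.5, 100_000, seed=3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        X = np.stack([slow, fast], axis=1) @ R.T
        model = mk.tica_fit(X, lag=1)
        # first tIC projection should correlate with the slow signal
        proj = model.transform(X, 1)[:, 0]
        c = np.corrcoef(proj, slow)[0, 1]
        assert abs(c) > 0.95

    def test_white_noise_has_no_slow_modes(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100_000, 3))
        model = mk.tica_fit(X, lag=1)
        assert np.abs(model.eigenvalues).max() < 0.05

    def test_singular_covariance_regularized_with_warning(self):
        x = self.ar1(0.9, 5000, seed=5)
        X = np.stack([x, 2 * x], axis=1)  # rank-1 covariance
        with pytest.warns(UserWarning):
            model = mk.tica_fit(X, lag=1)
        assert np.isfinite(model.eigenvalues).all()


class TestKmeans:
    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 2))
        disc = mk.kmeans_discretize(X, 1, seed=0)
        assert np.allclose(disc.centers[0], X.mean(axis=0), atol=1e-9)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(7)
        X = np.concatenate([rng.normal(0, 0.1, (400, 2)),
                            rng.normal(5, 0.1, (400, 2))])
        truth = np.repeat([0, 1], 400)
        disc = mk.kmeans_discretize(X, 2, seed=0)
        lab = disc.dtrajs[0]
        agree = max((lab == truth).mean(), (lab == 1 - truth).mean())
        assert agree > 0.99

    def test_seed_determinism_and_k_bounds(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 2))
        a = mk.kmeans_discretize(X, 5, seed=3)
        b = mk.kmeans_discretize(X, 5, seed=3)
        assert np.array_equal(a.centers, b.centers)
        with pytest.raises(ValueError):
            mk.kmeans_discretize(X, 101, seed=0)


class TestEstimateMsm:
    def test_alternating_trajectory(self):
        d = np.array([0, 1] * 50)
        m = mk.estimate_msm(d, lag=1)
        assert np.allclose(m.T, [[0, 1], [1, 0]], atol=1e-12)

    def test_recovers_true_matrix(self):
        T = np.array([[0.90, 0.05, 0.05],
                      [0.05, 0.90, 0.05],
                      [0.10, 0.10, 0.80]])
        states, _ = simulate_markov_trajectory(
            MarkovEmissionSpec(T, means=np.zeros((3, 1)), n_steps=1_000_000, seed=9))
        m = mk.estimate_msm(states, lag=1)
        assert np.abs(m.T - T).max() < 0.01

    def test_row_stochastic_detailed_balance_and_pi(self):
        states, _ = simulate_markov_trajectory(MarkovEmissionSpec(
            two_state(0.2, 0.4), means=np.zeros((2, 1)), n_steps=50_000, seed=10))
        m = mk.estimate_msm(states, lag=1)
        assert np.allclose(m.T.sum(axis=1), 1, atol=1e-10)
        assert np.allclose(m.pi @ m.T, m.pi, atol=1e-8)
        assert np.allclose(m.pi[:, None] * m.T, (m.pi[:, None] * m.T).T, atol=1e-8)
        # pi of the symmetrized estimator = normalized row sums of C_bar
        Cs = 0.5 * (m.C + m.C.T)
        assert np.allclose(m.pi, Cs.sum(axis=1) / Cs.sum(), atol=1e-12)

    def test_ergodic_trimming(self):
        # states 0/1 communicate; state 2 appears once and never returns
        d = np.array([0, 1, 0, 1, 0, 1, 2, 2, 2])
        m = mk.estimate_msm(d, lag=1)
        assert set(m.active_set) <= {0, 1, 2}
        assert m.discarded_fraction > 0


class TestImpliedTimescales:
    def test_two_state_hand_spectrum(self):
        # lambda_2 = 1 - a - b = 0.8 -> t2 = -1/ln(0.8)
        m = mk.markov_model_from_matrix(two_state(0.1, 0.1))
        assert m.timescales(1)[0] == pytest.approx(-1 / np.log(0.8), abs=1e-10)

    def test_flat_in_lag_for_markovian_input(self):
        states, _ = simulate_markov_trajectory(MarkovEmissionSpec(
            two_state(0.05, 0.05), means=np.zeros((2, 1)),
            n_steps=1_000_000, seed=11))
        tbl = mk.implied_timescales(states, lags=[1, 2, 5, 10], n=1)
        t2 = tbl["t1"].to_numpy()
        assert np.abs(t2 / t2[0] - 1).max() < 0.10

    def test_unit_eigenvalue_gives_nan_marker(self):
        m = mk.markov_model_from_matrix(np.eye(2))
        assert np.isnan(m.timescales(1)[0])


class TestVamp2:
    def test_identity_and_two_state(self):
        assert mk.vamp2_score(mk.markov_model_from_matrix(np.eye(2)), 2) == \
            pytest.approx(2.0)
        m = mk.markov_model_from_matrix(two_state(0.1, 0.1))
        assert mk.vamp2_score(m, 2) == pytest.approx(1 + 0.8**2, abs=1e-12)

    def test_non_increasing_in_smaller_k(self):
        m = mk.markov_model_from_matrix(two_state(0.3, 0.2))
        assert mk.vamp2_score(m, 1) <= mk.vamp2_score(m, 2)


class TestCkTest:
    def test_factor_one_is_exact(self):
        states, _ = simulate_markov_trajectory(MarkovEmissionSpec(
            two_state(0.1, 0.2), means=np.zeros((2, 1)), n_steps=50_000, seed=12))
        m = mk.estimate_msm(states, lag=1)
        tbl = mk.ck_test(states, m, factors=[1], n_macro=2)
        assert np.allclose(tbl["predicted"], tbl["estimated"], atol=1e-12)

    def test_markovian_data_consistent(self):
        T = np.array([[0.95, 0.04, 0.01],
                      [0.04, 0.95, 0.01],
                      [0.02, 0.02, 0.96]])
        states, _ = simulate_markov_trajectory(MarkovEmissionSpec(
            T, means=np.zeros((3, 1)), n_steps=1_000_000, seed=13))
        m = mk.estimate_msm(states, lag=1)
        tbl = mk.ck_test(states, m, factors=[1, 2, 3, 4, 5], n_macro=2)
        assert (tbl["predicted"] - tbl["estimated"]).abs().max() < 0.05

    def test_hidden_state_merging_breaks_markovianity(self):
        # hidden 3-state chain observed with states 1 and 2 merged: the
        # merged state mixes a fast-exchanging and a metastable hidden state,
        # so the lag-1 Markov prediction fails at longer lags
        Th = np.array([
            [0.99, 0.01, 0.0],
            [0.30, 0.40, 0.3],
            [0.0, 0.01, 0.99],
        ])
        hidden, _ = simulate_markov_trajectory(MarkovEmissionSpec(
            Th, means=np.zeros((3, 1)), n_steps=500_000, seed=14))
        observed = (hidden != 0).astype(int)  # merge hidden 1 and 2
        m = mk.estimate_msm(observed, lag=1)
        tbl = mk.ck_test(observed, m, factors=[1, 25, 50], n_macro=2)
        assert (tbl["predicted"] - tbl["estimated"]).abs().max() > 0.05


class TestPcca:
    def block_model(self, eps=1e-6):
        T = np.array([
            [0.9, 0.1 - eps, eps / 2, eps / 2],
            [0.1 - eps, 0.9, eps / 2, eps / 2],
            [eps / 2, eps / 2, 0.9, 0.1 - eps],
            [eps / 2, eps / 2, 0.1 - eps, 0.9],
        ])
        return mk.markov_model_from_matrix(T / T.sum(axis=1, keepdims=True))

    def test_two_block_recovery(self):
        cg = mk.pcca(self.block_model(), 2)
        labels = cg.crisp
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_memberships_row_stochastic(self):
        cg = mk.pcca(self.block_model(), 2)
        assert np.allclose(cg.memberships.sum(axis=1), 1, atol=1e-8)
        assert (cg.memberships >= 0).all()

    def test_three_well_populations(self):
        # 9 microstates in 3 weakly coupled blocks of unequal weight
        rng = np.random.default_rng(15)
        blocks = [slice(0, 3), slice(3, 6), slice(6, 9)]
        T = np.full((9, 9), 1e-5)
        for b in blocks:
            sub = rng.uniform(0.5, 1.0, (3, 3))
            T[b, b] = sub
        T = T / T.sum(axis=1, keepdims=True)
        # symmetrize into a reversible chain
        pi = stationary_distribution(T)
        flux = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
        T = flux / flux.sum(axis=1, keepdims=True)
        m = mk.markov_model_from_matrix(T)
        cg = mk.pcca(m, 3)
        for b in blocks:
            members = cg.crisp[b]
            assert len(set(members)) == 1
        block_pi = sorted(m.pi[b].sum() for b in blocks)
        assert np.allclose(sorted(cg.macro_populations), block_pi, atol=1e-3)

    def test_nonreversible_rejected(self):
        T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        m = mk.markov_model_from_matrix(T)
        with pytest.raises(ValueError, match="reversible"):
            mk.pcca(m, 2)


class TestMfpt:
    def test_two_state_geometric_waiting_time(self):
        for a in (0.1, 0.25, 0.5):
            m = mk.markov_model_from_matrix(two_state(a, 0.3))
            assert mk.mfpt(m, [0], [1]) == pytest.approx(1 / a, abs=1e-10)

    def test_hand_solved_absorbing_walk(self):
        # symmetric walk on 5 states, ends absorbing; from state 2 (middle):
        # m1 = 1 + 0.5 m2, m2 = 1 + 0.5 m1 + 0.5 m3, m3 = 1 + 0.5 m2
        # -> m2 = 4, m1 = m3 = 3
        T = np.eye(5)
        for i in (1, 2, 3):
            T[i] = 0
            T[i, i - 1] = T[i, i + 1] = 0.5
        q = np.linalg.solve(np.eye(3) - T[1:4, 1:4], np.ones(3))
        assert np.allclose(q, [3, 4, 3])

    def test_matches_monte_carlo_oracle(self):
        T = symmetric_walk(5)
        model = mk.markov_model_from_matrix(T)
        est = mk.mfpt(model, [0], [4])
        sim = mc_mfpt(T, 0, {4}, n_runs=20_000, seed=16)
        assert est == pytest.approx(sim, rel=0.02)

    def test_pi_weighted_source_average(self):
        T = symmetric_walk(4)
        model = mk.markov_model_from_matrix(T)
        m0 = mk.mfpt(model, [0], [3])
        m1 = mk.mfpt(model, [1], [3])
        both = mk.mfpt(model, [0, 1], [3])
        w = model.pi[[0, 1]] / model.pi[[0, 1]].sum()
        assert both == pytest.approx(w[0] * m0 + w[1] * m1, abs=1e-9)


class TestTpt:
    def test_three_state_one_step_committor(self):
        T = np.array([[0.8, 0.15, 0.05],
                      [0.3, 0.4, 0.3],
                      [0.1, 0.2, 0.7]])
        # make reversible for clean q- = 1 - q+
        pi = stationary_distribution(T)
        flux = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
        T = flux / flux.sum(axis=1, keepdims=True)
        model = mk.markov_model_from_matrix(T)
        res = mk.tpt(model, [0], [2])
        assert res.q_plus[1] == pytest.approx(T[1, 2] / (T[1, 0] + T[1, 2]))
        assert np.allclose(res.q_minus, 1 - res.q_plus, atol=1e-8)

    def test_linear_committor_on_symmetric_walk(self):
        model = mk.markov_model_from_matrix(symmetric_walk(5))
        res = mk.tpt(model, [0], [4])
        assert np.allclose(res.q_plus, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-10)

    def test_flux_conservation(self):
        model = mk.markov_model_from_matrix(symmetric_walk(6))
        res = mk.tpt(model, [0, 1], [5])
        n = 6
        A, B = res.A, res.B
        notA = np.setdiff1d(np.arange(n), A)
        notB = np.setdiff1d(np.arange(n), B)
        out_A = res.f_net[np.ix_(A, notA)].sum()
        into_B = res.f_net[np.ix_(notB, B)].sum()
        assert out_A == pytest.approx(into_B, abs=1e-10)
        assert out_A == pytest.approx(res.total_flux, abs=1e-10)

    def test_pathway_decomposition_sums_to_total(self):
        model = mk.markov_model_from_matrix(symmetric_walk(5))
        res = mk.tpt(model, [0], [4])
        assert sum(f for _, f in res.pathways) == pytest.approx(
            res.total_flux, rel=1e-6)
        assert all(f >= 0 for _, f in res.pathways)

    def parallel_channel_chain(self):
        """5 states: A=0, B=4; channel 0-1-4 and channel 0-2-3-4."""
        T = np.array([
            [0.70, 0.20, 0.10, 0.00, 0.00],
            [0.25, 0.50, 0.00, 0.00, 0.25],
            [0.20, 0.00, 0.60, 0.20, 0.00],
            [0.00, 0.00, 0.20, 0.60, 0.20],
            [0.30, 0.30, 0.00, 0.40, 0.00],
        ])
        assert np.allclose(T.sum(axis=1), 1)
        return T

    def test_flux_and_channel_split_match_monte_carlo(self):
        T = self.parallel_channel_chain()
        model = mk.markov_model_from_matrix(T)
        res = mk.tpt(model, [0], [4])
        mc_flux, paths = mc_reactive_flux(T, {0}, {4}, n_steps=400_000, seed=17)
        assert res.total_flux == pytest.approx(mc_flux, rel=0.03)
        # fraction of reactive events entering B through state 1 (upper
        # channel) equals the net flux into B carried by edge 1->4
        upper_mc = sum(c for p, c in paths.items() if p[-2] == 1)
        frac_mc = upper_mc / sum(paths.values())
        frac_tpt = res.f_net[1, 4] / res.total_flux
        assert frac_tpt == pytest.approx(frac_mc, abs=0.03)


class TestFreeEnergySurface:
    def test_single_occupied_bin_and_min_zero(self):
        X = np.zeros((100, 2))
        F, _, _ = mk.free_energy_surface(X, n_bins=1)
        assert F.shape == (1, 1) and F[0, 0] == 0.0

    def test_two_blob_energy_gap(self):
        rng = np.random.default_rng(18)
        n = 100_000
        pick = rng.random(n) < 0.9
        X = np.where(pick[:, None], rng.normal(0, 0.05, (n, 2)),
                     rng.normal(5, 0.05, (n, 2)))
        F, _, _ = mk.free_energy_surface(X, n_bins=2)
        finite = np.sort(F[np.isfinite(F)])
        assert finite[0] == 0.0
        assert finite[-1] == pytest.approx(np.log(9), abs=0.1)


class TestStateDistanceProfiles:
    def test_identical_frames_zero_sd(self, hairpin18):
        import numpy as np
        from ensemblekit import ConformerEnsemble
        ens = ConformerEnsemble(np.repeat(hairpin18.coords, 3, axis=0),
                                hairpin18.atoms.copy())
        tbl = mk.state_distance_profiles(ens, [0, 0, 0])
        assert (tbl.filter(like="_sd") == 0).all().all()

    def test_extended_template_values(self, extended18):
        tbl = mk.state_distance_profiles(extended18, [0])
        row = tbl.iloc[0]
        assert row["n_to_c_mean"] == pytest.approx(64.6)
        # mid = mean of |3-17|, |4-16|, |5-15| gaps * 3.8
        assert row["mid_mean"] == pytest.approx(np.mean([14, 12, 10]) * 3.8)
        assert row["c_term_mean"] == pytest.approx(11 * 3.8)
        assert row["n_term_mean"] == pytest.approx(11 * 3.8)


class TestPipelineRecovery:
    def test_macrostate_populations_and_slowest_timescale(self):
        """Full chain: simulate known 3-state kinetics with Gaussian emissions,
        then tICA -> k-means -> MSM -> PCCA+ recovers populations and the
        slowest implied timescale."""
        T_true = np.array([
            [0.98, 0.01, 0.01],
            [0.02, 0.96, 0.02],
            [0.01, 0.01, 0.98],
        ])
        means = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        spec = MarkovEmissionSpec(T_true, means=means, covs=[0.25, 0.25, 0.25],
                                  n_steps=500_000, seed=19)
        states, feats = simulate_markov_trajectory(spec)
        model_t = mk.tica_fit(feats, lag=5)
        Y = model_t.transform(feats, 2)
        disc = mk.kmeans_discretize(Y, k=15, seed=0)
        m = mk.estimate_msm(disc.dtrajs[0], lag=5)
        cg = mk.pcca(m, 3)
        pi_true = stationary_distribution(T_true)
        assert np.allclose(sorted(cg.macro_populations), sorted(pi_true),
                           atol=0.03)
        lam2 = np.sort(np.linalg.eigvals(T_true).real)[-2]
        t2_true = -1 / np.log(lam2)
        t2_est = m.timescales(1)[0] / 1.0  # dt = 1 frame
        assert t2_est == pytest.approx(t2_true, rel=0.15)
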