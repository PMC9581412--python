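"""MSM estimation: counting, reversible MLE, validation, weighted statistics."""

import numpy as np
import pytest

import ligandmsm as lm
from ligandmsm import ConnectivityError, DataError, ParameterError
from ligandmsm.msm import _gmrq_score, reversible_mle

from conftest import TWO_STATE_T


class TestCountTransitions:
    def test_enumerated_examples(self):
        seq = np.array([0, 0, 1, 1, 0])
        assert np.array_equal(lm.count_transitions(seq, 1), [[1, 1], [1, 1]])
        assert np.array_equal(lm.count_transitions(seq, 2), [[0, 2], [1, 0]])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        seqs = [rng.integers(0, 5, size=n) for n in (37, 53, 11)]
        for lag in (1, 3, 7):
            C = lm.count_transitions(seqs, lag, n_states=5)
            brute = np.zeros((5, 5), dtype=int)
            for s in seqs:
                for t in range(len(s) - lag):
                    brute[s[t], s[t + lag]] += 1
            assert np.array_equal(C, brute)

    def test_short_trajectory_warns_and_contributes_nothing(self):
        with pytest.warns(UserWarning, match="shorter than lag"):
            C = lm.count_transitions([np.array([0, 1]), np.array([0])], lag=1)
        assert C.sum() == 1


class TestReversibleEstimation:
    def test_symmetric_counts_row_normalize(self):
        C = np.array([[8, 2], [2, 8]])
        model = lm.estimate_reversible_msm(C, lag=1)
        assert np.allclose(model.T, [[0.8, 0.2], [0.2, 0.8]])
        assert np.allclose(model.pi, 0.5)

    def test_model_invariants(self, block_chain_sample):
        model = lm.estimate_msm_from_assignments(block_chain_sample, lag=1, n_states=12)
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(model.pi @ model.T, model.pi, atol=1e-8)
        flux = model.pi[:, None] * model.T
        assert np.allclose(flux, flux.T, atol=1e-8)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        assert model.eigenvalues[0] == 1.0
        # π-orthonormality of right eigenvectors
        G = model.right_eigenvectors.T @ np.diag(model.pi) @ model.right_eigenvectors
        assert np.allclose(G, np.eye(12), atol=1e-8)

    def test_two_state_recovery(self):
        (traj,) = lm.sample_discrete_trajectories(TWO_STATE_T, 1, 100_000, seed=1)
        model = lm.estimate_msm_from_assignments(traj, lag=1, n_states=2)
        assert np.allclose(model.pi, [2 / 3, 1 / 3], atol=0.01)

    def test_disconnected_counts_keep_heavier_block(self):
        C = np.zeros((4, 4), dtype=int)
        C[:2, :2] = [[5, 2], [2, 5]]          # light block
        C[2:, 2:] = [[50, 20], [20, 50]]      # heavy block
        model = lm.estimate_reversible_msm(C, lag=1)
        assert np.array_equal(model.active_set, [2, 3])

    def test_mle_beats_reversible_projection_likelihood(self):
        """The fixed point maximizes Σ C_ij log T_ij among reversible models."""
        rng = np.random.default_rng(2)
        def loglik(C, T):
            mask = C > 0
            return float((C[mask] * np.log(T[mask])).sum())

        for _ in range(100):
            n = rng.integers(2, 6)
            C = rng.integers(1, 30, size=(n, n)).astype(float)
            T_mle, pi_mle = reversible_mle(C)
            # baseline: detailed-balance projection of the row-normalized matrix
            T_row = C / C.sum(axis=1, keepdims=True)
            pi_row = lm.stationary_distribution(T_row)
            flux = (pi_row[:, None] * T_row + (pi_row[:, None] * T_row).T) / 2
            T_proj = flux / flux.sum(axis=1, keepdims=True)
            assert loglik(C, T_mle) >= loglik(C, T_proj) - 1e-9


class TestMicrostateClustering:
    def test_zero_inertia_with_k_equal_points(self):
        pts = np.array([[0.0, 0], [5, 5], [9, 0], [2, 7]])
        micro = lm.cluster_microstates([pts], k=4, seed=0)
        assert micro.inertia < 1e-12

    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.3, size=(100, 2))
        b = rng.normal(10, 0.3, size=(100, 2))
        micro = lm.cluster_microstates([np.vstack([a, b])], k=2, seed=0)
        lab = micro.assignments[0]
        assert len(set(lab[:100])) == 1 and len(set(lab[100:])) == 1
        assert lab[0] != lab[-1]

    def test_inertia_beats_random_restarts(self):
        """k-means++ inertia is no worse than a 10-restart Lloyd baseline."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, size=(100, 2))
        micro = lm.cluster_microstates([X], k=5, seed=0)
        best = np.inf
        for rep in range(10):
            idx = rng.choice(100, 5, replace=False)
            centers = X[idx]
            for _ in range(50):
                d = ((X[:, None] - centers[None]) ** 2).sum(-1)
                lab = d.argmin(1)
                new = np.array([
                    X[lab == j].mean(0) if (lab == j).any() else centers[j]
                    for j in range(5)
                ])
                if np.allclose(new, centers):
                    break
                centers = new
            inertia = (((X - centers[lab]) ** 2).sum())
            best = min(best, inertia)
        assert micro.inertia <= best * 1.0001

    def test_k_exceeding_frames_rejected(self):
        with pytest.raises(ParameterError):
            lm.cluster_microstates([np.zeros((3, 2))], k=5, seed=0)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        (traj,) = lm.sample_discrete_trajectories(TWO_STATE_T, 1, 200_000, seed=5)
        table = lm.implied_timescales(traj, lags=[1], n_timescales=1)
        expected = -1 / np.log(0.7)
        assert np.isclose(table.timescale_ns.iloc[0], expected, rtol=0.05)

    def test_flat_across_lags_for_markovian_data(self, block_chain, block_chain_sample):
        _, _, _, gt = block_chain
        table = lm.implied_timescales(block_chain_sample, lags=[1, 2, 4, 8],
                                      n_timescales=2)
        slowest = table[table.process == 2].timescale_ns.values
        assert np.all(np.abs(slowest - gt.timescales_true[0]) / gt.timescales_true[0] < 0.15)

    def test_white_noise_below_lag_line(self):
        rng = np.random.default_rng(6)
        seqs = [rng.integers(0, 4, size=5000) for _ in range(2)]
        table = lm.implied_timescales(seqs, lags=[5, 10], n_timescales=2)
        assert table.below_lag.all()


class TestGMRQ:
    def test_train_equals_test_matches_spectrum(self):
        import scipy.linalg
        T = np.array([[0.90, 0.08, 0.02], [0.08, 0.88, 0.04], [0.02, 0.04, 0.94]])
        labels = lm.sample_discrete_trajectories(T, 1, 100_000, seed=7)
        model = lm.estimate_msm_from_assignments(labels, 1, n_states=3)
        score = _gmrq_score(model, [np.asarray(l) for l in labels], 2, 1)
        assert np.isclose(score, 1 + model.eigenvalues[1], atol=1e-6)
        lam = np.sort(np.real(scipy.linalg.eigvals(T)))[::-1]
        assert np.isclose(score, 1 + lam[1], atol=0.02)

    def test_single_process_scores_one(self, block_chain_sample):
        model = lm.estimate_msm_from_assignments(block_chain_sample, 1, n_states=12)
        s = _gmrq_score(model, [np.asarray(l) for l in block_chain_sample], 1, 1)
        assert np.isclose(s, 1.0, atol=1e-8)

    def test_cross_validated_table(self, two_state_features):
        _, _, fs, _ = two_state_features
        coords = [m[:5000, :3] for m in fs.matrices]
        table = lm.gmrq_cv(coords, k_values=[3, 6], n_processes=2, folds=4,
                           lag=1, seed=0)
        assert set(table.k) == {3, 6}
        assert (table["mean"] <= 2.0 + 1e-9).all()


class TestCKTest:
    def test_k1_identity_and_markovian_agreement(self, block_chain_sample):
        sets = [[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]]
        table = lm.ck_test(block_chain_sample, sets, lag=1, k_multiples=[1, 2, 4],
                           n_bootstrap=10, seed=0)
        k1 = table[table.k == 1]
        assert np.allclose(k1.predicted, k1.estimated, atol=1e-12)
        later = table[table.k > 1]
        assert np.all(np.abs(later.predicted - later.estimated) < 0.02)
        # estimated curve inside its bootstrap interval (expanded slightly)
        assert np.all(later.predicted >= later.ci_low - 0.02)
        assert np.all(later.predicted <= later.ci_high + 0.02)

    def test_detects_second_order_memory(self):
        """A hidden second-order process violates Chapman-Kolmogorov."""
        rng = np.random.default_rng(8)
        # hidden state = (current, previous); observed = current symbol.
        # The walk cycles 0→0→1→1→0… with small escape noise, so the observed
        # process has strong period-2 memory invisible to a first-order model.
        n = 40_000
        obs = np.empty(n, dtype=int)
        cur, prev = 0, 0
        for t in range(n):
            obs[t] = cur
            if rng.random() < 0.02:
                nxt = rng.integers(0, 2)
            else:
                nxt = 1 - cur if prev == cur else cur
            prev, cur = cur, nxt
        table = lm.ck_test([obs], [[0], [1]], lag=1, k_multiples=[1, 2, 3])
        dev = np.abs(table[table.k > 1].predicted - table[table.k > 1].estimated)
        assert dev.max() > 0.1


class TestWeightedStatistics:
    def test_weighted_mean(self):
        assert lm.weighted_mean(np.array([1.0, 3.0]), np.array([0.25, 0.75])) == 2.5

    def test_uniform_weights_match_numpy_percentiles(self):
        v = np.arange(1.0, 101.0)
        w = np.ones(100)
        for q in (5, 50, 95):
            ours = lm.weighted_percentile(v, w, q)
            ref = np.percentile(v, q, method="midpoint")
            assert abs(ours - ref) <= 1.0

    def test_all_equal_values(self):
        v = np.full(10, 7.0)
        assert lm.weighted_percentile(v, np.ones(10), 5) == 7.0
        assert lm.weighted_percentile(v, np.ones(10), 95) == 7.0

    def test_matches_weighted_cdf_scan(self):
        """Interpolated percentile agrees with a brute-force CDF scan."""
        rng = np.random.default_rng(9)
        v = rng.normal(0, 1, 500)
        w = rng.uniform(0.1, 2.0, 500)
        order = np.argsort(v)
        vs, ws = v[order], w[order]
        cdf = np.cumsum(ws) / ws.sum()
        for q in (5, 50, 95):
            ours = lm.weighted_percentile(v, w, q)
            # brute: first value whose CDF reaches q (step function, no interp)
            step = vs[np.searchsorted(cdf, q / 100.0)]
            gap = np.diff(vs).max()
            assert abs(ours - step) <= gap

    def test_free_energy_single_occupied_bin(self):
        coords = np.full(50, 0.5)
        out = lm.free_energy_surface(coords, np.ones(50), bins=4, extent=[(0, 1)])
        F = out["free_energy"]
        assert F.min() == 0.0
        assert np.isinf(F[F > 0]).all()

    def test_zero_weights_rejected(self):
        with pytest.raises(DataError):
            lm.weighted_mean(np.ones(3), np.zeros(3))


class TestFrameWeights:
    def test_weights_sum_to_one_and_flag_excluded(self):
        # state 3 is only reachable one-way: excluded from the active set
        seqs = [np.array([0, 0, 1, 1, 0, 1, 3, 3]), np.array([1, 0, 1, 0, 1])]
        C = lm.count_transitions(seqs, 1)
        model = lm.estimate_reversible_msm(C, lag=1)
        w = lm.compute_frame_weights(model, seqs)
        assert np.isclose(w.concatenated().sum(), 1.0)
        flat = np.concatenate(seqs)
        assert np.array_equal(w.included_mask(), np.isin(flat, model.active_set))
        assert (w.concatenated()[~w.included_mask()] == 0).all()

    def test_pi_recovery_through_weights(self, block_chain, block_chain_sample):
        """Frame weights aggregate back to π per microstate."""
        _, _, _, gt = block_chain
        model = lm.estimate_msm_from_assignments(block_chain_sample, 1, n_states=12)
        w = lm.compute_frame_weights(model, block_chain_sample)
        flat_w = w.concatenated()
        flat_s = np.concatenate(block_chain_sample)
        agg = np.array([flat_w[flat_s == i].sum() for i in range(12)])
        assert np.allclose(agg, gt.pi_true, atol=0.02)
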