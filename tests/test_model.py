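"""Unit and oracle tests for the piecewise-linear z-score mixture model."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau, norm

from sustain_psp.model import (EventGrid, SubtypeSequence, SuStaInFit,
                               dataset_loglik, fit_mixture,
                               log_stage_likelihood, mcmc_uncertainty,
                               optimize_sequence_greedy, stage_likelihood,
                               subject_marginal, trajectory_matrix,
                               trajectory_value)
from sustain_psp.synthetic import sample_zscores


class TestEventGrid:
    def test_event_count_is_total_thresholds(self, toy_grid):
        assert toy_grid.n_events == 3
        assert toy_grid.n_stages == 4

    def test_can_configure_41_stages_over_20_rois(self):
        # one region with three thresholds, nineteen with two
        ths = [[1.0, 2.0, 3.0]] + [[1.0, 2.0]] * 19
        grid = EventGrid([f"r{i}" for i in range(20)], ths, [5.0] * 20)
        assert grid.n_events == 41

    @pytest.mark.parametrize("thresholds,z_max", [
        ([[2.0, 1.0]], [3.0]),       # not increasing
        ([[1.0, 1.0]], [3.0]),       # not strictly increasing
        ([[1.0, 2.0]], [1.5]),       # z_max below last threshold
        ([[]], [1.0]),               # no events
    ])
    def test_invalid_grids_rejected(self, thresholds, z_max):
        with pytest.raises(ValueError):
            EventGrid(["A"], thresholds, z_max)


class TestSequenceValidity:
    def test_threshold_order_enforced(self, toy_grid):
        # A2 before A1 is physically impossible
        with pytest.raises(ValueError):
            SubtypeSequence(np.array([1, 0, 2])).validate(toy_grid)

    def test_non_permutation_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            SubtypeSequence(np.array([0, 0, 1])).validate(toy_grid)

    def test_positions_inverse_of_order(self, toy_sequence):
        pos = toy_sequence.positions()
        assert pos[0] == 1 and pos[2] == 2 and pos[1] == 3


class TestTrajectory:
    def test_origin_anchor(self, toy_grid, toy_sequence):
        for b in ("A", "B"):
            assert trajectory_value(toy_sequence, toy_grid, b, 0) == 0.0

    def test_hand_interpolated_values(self, toy_grid, toy_sequence):
        # S = [A1, B1, A2]: A anchors (0,0),(1,1),(3,2),(4,3); B (0,0),(2,1),(4,2)
        assert trajectory_value(toy_sequence, toy_grid, "A", 2) == pytest.approx(1.5)
        assert trajectory_value(toy_sequence, toy_grid, "B", 3) == pytest.approx(1.5)

    def test_stage_out_of_range(self, toy_grid, toy_sequence):
        with pytest.raises(ValueError):
            trajectory_value(toy_sequence, toy_grid, "A", 4)
        with pytest.raises(ValueError):
            trajectory_value(toy_sequence, toy_grid, "A", -1)

    def test_monotone_nondecreasing_for_random_valid_sequences(self):
        rng = np.random.default_rng(0)
        grid = EventGrid(["a", "b", "c"], [[1, 2], [0.5, 1.5, 2.5], [2]],
                         [3.0, 3.0, 2.0])
        from sustain_psp.model import _random_valid_order
        for _ in range(25):
            G = trajectory_matrix(grid, _random_valid_order(grid, rng))
            assert np.all(np.diff(G, axis=1) >= -1e-12)


class TestStageLikelihood:
    def test_density_at_mode_is_gaussian_normalizer(self, toy_grid, toy_sequence):
        G = trajectory_matrix(toy_grid, toy_sequence.order)
        for k in range(toy_grid.n_stages):
            val = stage_likelihood(G[:, k], toy_sequence, toy_grid, k)
            assert val == pytest.approx((2 * np.pi) ** (-toy_grid.n_biomarkers / 2))

    def test_symmetric_decay_from_mode(self, toy_grid, toy_sequence):
        G = trajectory_matrix(toy_grid, toy_sequence.order)
        x = G[:, 2].copy()
        base = log_stage_likelihood(x, toy_sequence, toy_grid, 2)
        prev_hi = base
        for delta in (0.5, 1.0, 2.0):
            up, down = x.copy(), x.copy()
            up[0] += delta
            down[0] -= delta
            lu = log_stage_likelihood(up, toy_sequence, toy_grid, 2)
            ld = log_stage_likelihood(down, toy_sequence, toy_grid, 2)
            assert lu == pytest.approx(ld, abs=1e-12)
            assert lu < prev_hi
            prev_hi = lu

    def test_matches_product_of_scalar_normals(self, toy_grid, toy_sequence):
        rng = np.random.default_rng(1)
        G = trajectory_matrix(toy_grid, toy_sequence.order)
        for _ in range(20):
            x = rng.normal(0, 2, toy_grid.n_biomarkers)
            k = rng.integers(toy_grid.n_stages)
            oracle = np.prod(norm.pdf(x, loc=G[:, k], scale=toy_grid.sigma))
            assert stage_likelihood(x, toy_sequence, toy_grid, int(k)) == \
                pytest.approx(oracle, rel=1e-12)

    def test_missing_value_rejected(self, toy_grid, toy_sequence):
        with pytest.raises(ValueError):
            stage_likelihood([np.nan, 0.0], toy_sequence, toy_grid, 0)


class TestSubjectMarginal:
    def test_two_term_hand_value(self):
        # one biomarker, threshold {1}, z_max 1, x = 0:
        # (phi(0) + phi(1)) / 2 with phi the standard normal pdf
        grid = EventGrid(["A"], [[1.0]], [1.0])
        seq = SubtypeSequence(np.array([0]))
        expected = (norm.pdf(0.0) + norm.pdf(1.0)) / 2
        assert subject_marginal([0.0], seq, grid) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_biomarker_storage_order(self):
        grid1 = EventGrid(["A", "B"], [[1.0], [2.0]], [2.0, 3.0])
        grid2 = EventGrid(["B", "A"], [[2.0], [1.0]], [3.0, 2.0])
        seq1 = SubtypeSequence(np.array([0, 1]))   # A1 then B1
        seq2 = SubtypeSequence(np.array([1, 0]))   # same events, B stored first
        x = np.array([0.4, 1.1])
        assert subject_marginal(x, seq1, grid1) == \
            pytest.approx(subject_marginal(x[::-1], seq2, grid2), rel=1e-12)

    def test_monte_carlo_stage_average(self, toy_grid, toy_sequence):
        rng = np.random.default_rng(2)
        x = np.array([0.7, 0.3])
        ks = rng.integers(toy_grid.n_stages, size=200_000)
        draws = np.array([
            stage_likelihood(x, toy_sequence, toy_grid, k)
            for k in range(toy_grid.n_stages)
        ])
        mc = draws[ks].mean()
        exact = subject_marginal(x, toy_sequence, toy_grid)
        se = draws[ks].std(ddof=1) / np.sqrt(ks.size)
        assert abs(mc - exact) < 4 * se


def _brute_force_mixture_loglik(X, fit):
    """Triple loop over subjects x subtypes x stages, scalar normal pdfs."""
    grid = fit.grid
    total = 0.0
    for x in np.atleast_2d(X):
        subject = 0.0
        for f, seq in zip(fit.fractions, fit.sequences):
            G = trajectory_matrix(grid, seq.order)
            for k in range(grid.n_stages):
                dens = np.prod(norm.pdf(x, loc=G[:, k], scale=grid.sigma))
                subject += f * dens / grid.n_stages
        total += np.log(subject)
    return total


class TestDatasetLoglik:
    def _toy_fit(self, toy_grid):
        s1 = SubtypeSequence(np.array([0, 2, 1]))
        s2 = SubtypeSequence(np.array([2, 0, 1]))
        return SuStaInFit(toy_grid, [s1, s2], np.array([0.6, 0.4]), -1.0)

    def test_single_subtype_collapses_to_marginal(self, toy_grid, toy_sequence):
        fit = SuStaInFit(toy_grid, [toy_sequence], np.array([1.0]), -1.0)
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (5, 2))
        expected = sum(np.log(subject_marginal(x, toy_sequence, toy_grid))
                       for x in X)
        assert dataset_loglik(X, fit) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_enumeration(self, toy_grid):
        fit = self._toy_fit(toy_grid)
        rng = np.random.default_rng(4)
        X = rng.normal(0.5, 1.5, (10, 2))
        assert dataset_loglik(X, fit) == pytest.approx(
            _brute_force_mixture_loglik(X, fit), abs=1e-10)

    def test_duplicating_subjects_doubles_loglik(self, toy_grid):
        fit = self._toy_fit(toy_grid)
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (6, 2))
        assert dataset_loglik(np.vstack([X, X]), fit) == \
            pytest.approx(2 * dataset_loglik(X, fit), rel=1e-12)

    def test_label_permutation_invariance(self, toy_grid):
        fit = self._toy_fit(toy_grid)
        swapped = SuStaInFit(toy_grid, fit.sequences[::-1],
                             fit.fractions[::-1], -1.0)
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (8, 2))
        assert dataset_loglik(X, fit) == \
            pytest.approx(dataset_loglik(X, swapped), rel=1e-12)


class TestGreedyOptimization:
    def test_single_event_grid_returns_only_sequence(self):
        grid = EventGrid(["A"], [[1.0]], [2.0])
        seq, ll = optimize_sequence_greedy(np.array([[0.5]]), grid,
                                           n_starts=1, seed=0)
        assert seq.order.tolist() == [0]
        assert np.isfinite(ll)

    def test_exact_recovery_on_near_noiseless_data(self):
        grid = EventGrid([f"b{i}" for i in range(6)], [[1.0]] * 6,
                         [2.0] * 6, sigma=[0.05] * 6)
        truth = SubtypeSequence(np.array([3, 0, 5, 1, 4, 2]))
        X, _, _ = sample_zscores(grid, [truth], [1.0], 200,
                                 noise_sd=0.05, seed=7)
        seq, _ = optimize_sequence_greedy(X, grid, n_starts=8, seed=8)
        assert seq.order.tolist() == truth.order.tolist()

    def test_returned_loglik_at_least_generating_sequence(self, flat_grid):
        truth = SubtypeSequence(np.arange(10))
        X, _, _ = sample_zscores(flat_grid, [truth], [1.0], 150,
                                 noise_sd=1.0, seed=9)
        seq, ll = optimize_sequence_greedy(X, flat_grid, n_starts=4, seed=10)
        fit_truth = SuStaInFit(flat_grid, [truth], np.array([1.0]), -1.0)
        assert ll >= dataset_loglik(X, fit_truth) - 1e-9

    def test_empty_data_rejected(self, flat_grid):
        with pytest.raises(ValueError):
            optimize_sequence_greedy(np.empty((0, 10)), flat_grid, seed=0)


class TestFitMixture:
    def test_guard_on_subject_count(self, flat_grid):
        X = np.zeros((15, 10))
        with pytest.raises(ValueError):
            fit_mixture(X, flat_grid, 2, seed=0)

    def test_c1_matches_greedy(self, flat_grid):
        truth = SubtypeSequence(np.arange(10))
        X, _, _ = sample_zscores(flat_grid, [truth], [1.0], 80,
                                 noise_sd=1.0, seed=11)
        fit = fit_mixture(X, flat_grid, 1, seed=12, n_starts=4)
        assert fit.n_subtypes == 1
        assert fit.fractions[0] == pytest.approx(1.0)
        assert fit.log_likelihood == pytest.approx(
            dataset_loglik(X, fit), rel=1e-12)

    def test_two_subtype_recovery_single_seed(self, flat_grid):
        s1 = SubtypeSequence(np.arange(10))
        s2 = SubtypeSequence(np.arange(10)[::-1])
        X, subt, stages = sample_zscores(flat_grid, [s1, s2], [0.75, 0.25],
                                         400, 1.0, seed=13)
        fit = fit_mixture(X, flat_grid, 2, seed=14, n_starts=8,
                          split_starts=2)
        fr = np.sort(fit.fractions)
        assert abs(fr[1] - 0.75) <= 0.10
        taus = np.array([[abs(kendalltau(s.positions(), t.positions()).statistic)
                          for t in (s1, s2)] for s in fit.sequences])
        # matched assignment: each truth sequence well recovered by one cluster
        assert max(taus[0, 0] + taus[1, 1], taus[0, 1] + taus[1, 0]) >= 1.6


class TestSerialization:
    def test_json_round_trip(self, toy_grid, toy_sequence):
        fit = SuStaInFit(toy_grid, [toy_sequence], np.array([1.0]), -12.5,
                         seed=3)
        restored = SuStaInFit.from_json(fit.to_json())
        assert restored.sequences[0].order.tolist() == \
            toy_sequence.order.tolist()
        assert restored.fractions.tolist() == [1.0]
        assert restored.log_likelihood == -12.5
        assert restored.grid.biomarkers == toy_grid.biomarkers
        assert restored.grid.n_events == toy_grid.n_events


class TestMCMC:
    def _small_fit(self, seed=20):
        grid = EventGrid([f"b{i}" for i in range(5)], [[1.0]] * 5, [3.0] * 5)
        truth = SubtypeSequence(np.array([2, 0, 4, 1, 3]))
        X, _, _ = sample_zscores(grid, [truth], [1.0], 120, 1.0, seed=seed)
        fit = fit_mixture(X, grid, 1, seed=seed + 1, n_starts=4)
        return X, fit

    def test_chains_identical_under_same_seed(self):
        X, fit = self._small_fit()
        r1 = mcmc_uncertainty(X, fit, iterations=500, seed=5)
        r2 = mcmc_uncertainty(X, fit, iterations=500, seed=5)
        assert np.array_equal(r1.log_likelihoods, r2.log_likelihoods)
        assert np.array_equal(r1.positional_variance[0].matrix,
                              r2.positional_variance[0].matrix)

    def test_positional_variance_rows_are_distributions(self):
        X, fit = self._small_fit(seed=22)
        res = mcmc_uncertainty(X, fit, iterations=400, seed=6)
        for pv in res.positional_variance:
            rows = pv.matrix.sum(axis=1)
            assert np.allclose(rows, 1.0, atol=1e-9)
            assert np.all((pv.matrix >= 0) & (pv.matrix <= 1))

    def test_low_noise_data_concentrates_on_ml_positions(self):
        grid = EventGrid([f"b{i}" for i in range(5)], [[1.0]] * 5,
                         [3.0] * 5, sigma=[0.05] * 5)
        truth = SubtypeSequence(np.array([0, 1, 2, 3, 4]))
        X, _, _ = sample_zscores(grid, [truth], [1.0], 150,
                                 noise_sd=0.05, seed=23)
        fit = fit_mixture(X, grid, 1, seed=24, n_starts=4)
        res = mcmc_uncertainty(X, fit, iterations=2000, seed=7)
        pv = res.positional_variance[0].matrix
        pos = fit.sequences[0].positions() - 1
        ml_mass = pv[np.arange(grid.n_events), pos]
        assert np.all(ml_mass >= 0.9)

    def test_iteration_guard(self):
        X, fit = self._small_fit(seed=25)
        with pytest.raises(ValueError):
            mcmc_uncertainty(X, fit, iterations=0, seed=0)
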