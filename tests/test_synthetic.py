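import numpy as np
import pytest

import mcrigor as mr


class TestSimulateDataset:
    def test_sizes_mean_is_exact(self, sim_bundle):
        truth = sim_bundle["truth"]
        sizes = np.array(list(truth.sizes.values()))
        assert sizes.mean() == sim_bundle["config"].gamma_star
        assert sizes.min() >= 20 and sizes.max() <= 80

    def test_ground_truth_partition_is_pure(self, sim_bundle):
        truth = sim_bundle["truth"]
        pur = mr.purity(truth.partition(), truth.metacell_of)
        assert all(v == 1.0 for v in pur.values())

    def test_lambda_rows_are_distributions(self, sim_bundle):
        lam = sim_bundle["truth"].lambda_matrix
        assert lam.shape[0] == len(sim_bundle["truth"].metacell_ids)
        assert lam.sum(axis=1) == pytest.approx(np.ones(lam.shape[0]))

    def test_theta_mean_one_over_metacells(self):
        # biological multipliers are Gamma(sigma, 1/sigma): relative
        # abundances averaged over many metacells recover the mean profile
        config = mr.GeneratorConfig(
            p=50, gamma_star=20, size_range=(20, 20), sigma=5.0,
            base_sdlog=0.0, de_fraction=0.02, seed=3,
        )
        _, truth = mr.simulate_dataset(config, 4000)
        lam = truth.lambda_matrix
        # with a flat baseline and tiny DE fraction, E[lambda_j] ~ 1/p
        assert lam.mean(axis=0) == pytest.approx(np.full(50, 1 / 50), rel=0.25)

    def test_infeasible_gamma_star_rejected(self):
        with pytest.raises(ValueError, match="size_range"):
            mr.GeneratorConfig(gamma_star=10, size_range=(20, 80))


class TestMultinomialSampler:
    def test_row_sums_match_library_sizes(self):
        rng = np.random.default_rng(0)
        lam = np.array([0.2, 0.3, 0.5])
        block = mr.sample_trustworthy_metacell(lam, [7, 11, 100], rng)
        assert list(block.sum(axis=1)) == [7, 11, 100]

    def test_p2_correlation_is_exactly_minus_one(self):
        rng = np.random.default_rng(1)
        block = mr.sample_trustworthy_metacell(
            np.array([0.5, 0.5]), [50] * 40, rng
        ).astype(float)
        r = np.corrcoef(block, rowvar=False)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_sample_correlations_match_closed_form(self):
        # within-metacell correlation under the multinomial null has the
        # closed form -sqrt(l_j/(1-l_j))sqrt(l_l/(1-l_l))
        rng = np.random.default_rng(2)
        p = 10
        lam = np.full(p, 0.1)
        block = mr.sample_trustworthy_metacell(lam, [200] * 5000, rng).astype(float)
        r = np.corrcoef(block, rowvar=False)
        off = r[np.triu_indices(p, 1)]
        expected = mr.theoretical_within_correlation(0.1, 0.1)
        assert off.mean() == pytest.approx(expected, abs=0.005)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            mr.sample_trustworthy_metacell(np.array([0.5, 0.6]), [10], np.random.default_rng(0))


class TestMixedPartition:
    def test_zero_fraction_returns_ground_truth(self, sim_bundle):
        part, flags = mr.make_mixed_partition(
            sim_bundle["truth"], 0.0, np.random.default_rng(0)
        )
        assert not any(flags.values())
        assert sum(part.sizes().values()) == sim_bundle["counts"].n_cells

    def test_mixed_metacells_have_half_purity(self):
        config = mr.GeneratorConfig(p=40, gamma_star=40, size_range=(40, 40), seed=5)
        _, truth = mr.simulate_dataset(config, 400)
        part, flags = mr.make_mixed_partition(truth, 0.4, np.random.default_rng(5))
        pur = mr.purity(part, truth.metacell_of)
        for mc_id, dubious in flags.items():
            assert pur[mc_id] == (0.5 if dubious else 1.0)

    def test_cell_count_conserved(self, sim_bundle):
        part, _ = mr.make_mixed_partition(
            sim_bundle["truth"], 0.3, np.random.default_rng(1)
        )
        assert sum(part.sizes().values()) == sim_bundle["counts"].n_cells


class TestOraclePartitioner:
    def test_at_true_granularity_returns_ground_truth(self, sim_bundle):
        truth = sim_bundle["truth"]
        part = mr.oracle_partitioner(truth, 50, np.random.default_rng(0))
        assert part.assignment == truth.partition().assignment

    def test_below_true_granularity_all_pure(self, sim_bundle):
        truth = sim_bundle["truth"]
        part = mr.oracle_partitioner(truth, 20, np.random.default_rng(0))
        pur = mr.purity(part, truth.metacell_of)
        assert all(v == 1.0 for v in pur.values())
        sizes = np.array(list(part.sizes().values()))
        assert 10 <= sizes.mean() <= 35

    def test_double_granularity_merges_pairs(self, sim_bundle):
        truth = sim_bundle["truth"]
        part = mr.oracle_partitioner(truth, 100, np.random.default_rng(0))
        pur = mr.purity(part, truth.metacell_of)
        assert all(v < 1.0 for v in pur.values())
        assert sum(part.sizes().values()) == sim_bundle["counts"].n_cells


class TestClosedForms:
    def test_within_correlation_forced_cases(self):
        assert mr.theoretical_within_correlation(0.5, 0.5) == pytest.approx(-1.0)
        assert mr.theoretical_within_correlation(0.01, 0.01) == pytest.approx(
            -1.0 / 99.0
        )
        assert mr.theoretical_within_correlation(1e-9, 0.3) == pytest.approx(0.0, abs=1e-4)

    def test_mixture_bias_hand_value(self):
        lam1, lam2 = np.array([0.6, 0.4]), np.array([0.4, 0.6])
        assert mr.theoretical_mixture_bias(lam1, lam2, 3, 0, 1) == pytest.approx(0.01)

    def test_mixture_bias_vanishes_for_identical_states(self):
        lam = np.array([0.3, 0.7])
        assert mr.theoretical_mixture_bias(lam, lam, 5, 0, 1) == 0.0

    def test_mixture_bias_antisymmetry(self):
        lam1, lam2 = np.array([0.7, 0.3]), np.array([0.2, 0.8])
        same = mr.theoretical_mixture_bias(lam1, lam1 * 0 + lam1, 4, 0, 1)
        assert same == 0.0
        # the bracket is symmetric under swapping the two states
        a = mr.theoretical_mixture_bias(lam1, lam2, 4, 0, 1)
        b = mr.theoretical_mixture_bias(lam2, lam1, 4, 0, 1)
        assert a == pytest.approx(b)

    def test_multinomial_consistency_of_cells_within_metacell(self, sim_bundle):
        # conditional on library size, counts of cells sharing a metacell are
        # multinomial in the shared relative abundances: the pooled profile
        # converges to lambda
        counts, truth = sim_bundle["counts"], sim_bundle["truth"]
        mc = truth.metacell_ids[0]
        idx = [i for i, c in enumerate(counts.cell_ids) if truth.metacell_of[c] == mc]
        pooled = counts.values[idx].sum(axis=0)
        lam = truth.lambda_of(mc)
        # compare aggregated frequencies against lambda on well-covered features
        big = lam > 5e-3
        freq = pooled / pooled.sum()
        assert freq[big] == pytest.approx(lam[big], rel=0.35)
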