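"""Observed sum, missing-mass corrections, sampling and deterministic baselines."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logsumexp

import isingz as iz
from conftest import all_patterns, random_covariates, random_model


class TestObservedSum:
    def test_full_table_equals_exact(self, rng):
        model = random_model(rng, 4)
        cov = random_covariates(rng, 5)
        pats = all_patterns(4)
        table = iz.PatternTable(patterns=pats, counts=np.ones(16, dtype=int),
                                bin_index=np.arange(16))
        cov16 = random_covariates(rng, 16)
        X = iz.observed_sum_X(model, table, cov16)
        Z = iz.exact_partition(model, cov16)
        assert np.allclose(X.log_values, Z.log_values, atol=1e-10)

    def test_silent_pattern_alone_gives_one(self, rng):
        model = random_model(rng, 4)
        table = iz.PatternTable(patterns=np.zeros((1, 4), dtype=np.uint8),
                                counts=np.array([3]), bin_index=np.zeros(3, int))
        cov = random_covariates(rng, 3)
        X = iz.observed_sum_X(model, table, cov)
        assert np.allclose(X.values, 1.0)

    def test_subset_matches_naive_summation(self, rng):
        model = random_model(rng, 4)
        cov = random_covariates(rng, 6)
        pats = all_patterns(4)[rng.choice(16, size=5, replace=False)]
        table = iz.PatternTable(patterns=pats, counts=np.ones(5, dtype=int),
                                bin_index=np.arange(5))
        cov5 = random_covariates(rng, 5)
        X = iz.observed_sum_X(model, table, cov5)
        H = model.fields(cov5)
        for t in range(5):
            naive = sum(np.exp(iz.log_weight(p, H[t], model.J)) for p in pats)
            assert X.values[t] == pytest.approx(naive, rel=1e-10)

    def test_empty_table_rejected(self, rng):
        model = random_model(rng, 3)
        with pytest.raises(ValueError):
            table = iz.PatternTable(patterns=np.zeros((0, 3), dtype=np.uint8),
                                    counts=np.zeros(0, int),
                                    bin_index=np.zeros(0, int))
            iz.observed_sum_X(model, table, random_covariates(rng, 0 + 1))


class TestGoodTuring:
    def test_counting_example(self):
        raster = iz.SpikeRaster(data=np.array([[0, 0], [0, 1], [0, 1], [1, 1]]))
        assert iz.good_turing(iz.build_pattern_table(raster)) == pytest.approx(0.5)

    def test_no_singletons_gives_zero(self):
        raster = iz.SpikeRaster(data=np.tile([1, 0], (6, 1)))
        assert iz.good_turing(iz.build_pattern_table(raster)) == 0.0

    def test_matches_analytic_missing_mass_of_bernoulli_population(self):
        # independent Bernoulli neurons: the true missing mass of the
        # observed pattern set is computable from the product law
        rng = np.random.default_rng(99)
        N, p, L = 10, 0.025, 20000
        data = (rng.random((L, N)) < p).astype(np.uint8)
        table = iz.build_pattern_table(iz.SpikeRaster(data=data))
        m_gt = iz.good_turing(table)
        k = table.patterns.sum(axis=1)
        observed_mass = np.sum(p ** k * (1 - p) ** (N - k))
        true_missing = 1.0 - observed_mass
        se = np.sqrt(table.n_singletons + 1) / L
        assert abs(m_gt - true_missing) < 3 * se + 2 / L


class TestChainProbabilities:
    def _random_chain(self, rng, n, R=2, coupled=True):
        ordering = rng.permutation(n)
        stim = [rng.normal(size=R) for _ in range(n)]
        neigh = [rng.normal(scale=0.5, size=n - 1 - k) if coupled
                 else np.zeros(n - 1 - k) for k in range(n)]
        return iz.ChainModel(ordering=ordering, stim_weights=stim,
                             neighbor_weights=neigh)

    def test_uncoupled_chain_is_product_of_marginals(self, rng):
        n = 4
        chain = self._random_chain(rng, n, coupled=False)
        row = rng.normal(size=2)
        pattern = rng.integers(0, 2, size=n)
        expected = 1.0
        for k in range(n):
            p_k = expit(row @ chain.stim_weights[k])
            bit = pattern[chain.ordering[k]]
            expected *= p_k if bit else (1 - p_k)
        assert iz.chain_pattern_prob(chain, pattern, row) == pytest.approx(expected, rel=1e-12)

    def test_chain_probabilities_sum_to_one(self, rng):
        chain = self._random_chain(rng, 3)
        row = rng.normal(size=2)
        total = sum(iz.chain_pattern_prob(chain, np.array(p), row)
                    for p in itertools.product([0, 1], repeat=3))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_conditional_enumeration(self, rng):
        # independent oracle: multiply the logistic conditionals by hand
        n = 4
        chain = self._random_chain(rng, n)
        row = rng.normal(size=2)
        for _ in range(6):
            pattern = rng.integers(0, 2, size=n)
            sigma = pattern[chain.ordering]
            prob = 1.0
            for k in range(n):
                eta = row @ chain.stim_weights[k]
                if k < n - 1:
                    eta += 2.0 * sigma[k + 1:] @ chain.neighbor_weights[k]
                p_k = expit(eta)
                prob *= p_k if sigma[k] else (1 - p_k)
            assert iz.chain_pattern_prob(chain, pattern, row) == pytest.approx(prob, rel=1e-10)


class TestMissingMass:
    def test_full_table_gives_zero(self, rng):
        chain = TestChainProbabilities()._random_chain(rng, 4)
        pats = all_patterns(4)
        table = iz.PatternTable(patterns=pats, counts=np.ones(16, int),
                                bin_index=np.arange(16))
        cov = random_covariates(rng, 16, n_cov=2)
        M = iz.missing_mass_series(chain, table, cov)
        assert np.allclose(M.values, 0.0, atol=1e-12)

    def test_complement_sum_oracle(self, rng):
        # M from 1 - sum(observed) equals the direct sum over the
        # unobserved patterns
        n = 4
        chain = TestChainProbabilities()._random_chain(rng, n)
        keep = rng.choice(16, size=6, replace=False)
        pats = all_patterns(n)[keep]
        table = iz.PatternTable(patterns=pats, counts=np.ones(6, int),
                                bin_index=np.arange(6))
        cov = random_covariates(rng, 6, n_cov=2)
        M = iz.missing_mass_series(chain, table, cov)
        others = [p for i, p in enumerate(all_patterns(n)) if i not in keep]
        for t in range(6):
            direct = sum(iz.chain_pattern_prob(chain, p, cov.data[t])
                         for p in others)
            assert M.values[t] == pytest.approx(direct, abs=1e-10)

    def test_silent_table_with_strong_inhibition(self, rng):
        # only the silent pattern observed, strongly negative drive:
        # M(s) equals 1 minus the chain probability of the zero pattern
        chain = iz.ChainModel(ordering=np.arange(3),
                              stim_weights=[np.array([-4.0])] * 3,
                              neighbor_weights=[np.zeros(2), np.zeros(1),
                                                np.zeros(0)])
        table = iz.PatternTable(patterns=np.zeros((1, 3), np.uint8),
                                counts=np.array([2]), bin_index=np.zeros(2, int))
        cov = iz.CovariateMatrix(data=np.ones((2, 1)))
        M = iz.missing_mass_series(chain, table, cov)
        expected = 1.0 - iz.chain_pattern_prob(chain, np.zeros(3), np.ones(1))
        assert np.allclose(M.values, expected, atol=1e-12)
        assert np.all(M.values < 0.1)


class TestZFromMissingMass:
    def test_zero_missing_mass_returns_X(self, rng):
        X = iz.PartitionSeries(log_values=rng.normal(size=5), method="X_only")
        M = iz.MissingMassSeries(values=np.zeros(5), method="good_turing_constant")
        Z = iz.z_from_missing_mass(X, M)
        assert np.allclose(Z.log_values, X.log_values)

    def test_half_missing_mass_doubles(self):
        X = iz.PartitionSeries(log_values=np.log([2.0, 4.0]), method="X_only")
        M = iz.MissingMassSeries(values=np.array([0.5, 0.5]),
                                 method="good_turing_constant")
        Z = iz.z_from_missing_mass(X, M)
        assert np.allclose(Z.values, [4.0, 8.0])

    def test_true_missing_mass_recovers_exact(self, rng):
        # plugging the enumeration-true M(s) into the inversion must
        # reproduce the exact partition function identically
        model = random_model(rng, 5)
        cov = random_covariates(rng, 8)
        raster = iz.SpikeRaster(data=rng.integers(0, 2, size=(40, 5)))
        table = iz.build_pattern_table(raster)
        X = iz.observed_sum_X(model, table, cov)
        Z = iz.exact_partition(model, cov)
        M_true = 1.0 - np.exp(X.log_values - Z.log_values)
        Z2 = iz.z_from_missing_mass(
            X, iz.MissingMassSeries(values=M_true, method="conditional_logistic"))
        assert np.allclose(Z2.log_values, Z.log_values, atol=1e-10)

    def test_saturated_missing_mass_is_an_error(self):
        X = iz.PartitionSeries(log_values=np.zeros(3), method="X_only")
        M = iz.MissingMassSeries(values=np.array([0.2, 1.0, 0.3]),
                                 method="conditional_logistic")
        with pytest.raises(ValueError, match="bin"):
            iz.z_from_missing_mass(X, M)


class TestImportanceSampling:
    def test_zero_variance_when_proposal_equals_target(self, rng):
        model = random_model(rng, 5, j_scale=0.0)
        cov = random_covariates(rng, 4)
        Z = iz.importance_sampling_Z(model, cov, n_samples=200, seed=1)
        H = model.fields(cov)
        expected = np.sum(np.log1p(np.exp(H)), axis=1)
        assert np.allclose(Z.log_values, expected, atol=1e-12)
        assert np.allclose(Z.mc_se, 0.0)

    def test_within_monte_carlo_error_of_exact(self, rng):
        model = random_model(rng, 6)
        cov = random_covariates(rng, 20)
        Z_is = iz.importance_sampling_Z(model, cov, n_samples=50_000, seed=2)
        Z_ex = iz.exact_partition(model, cov)
        err = np.abs(Z_is.values - Z_ex.values)
        frac_ok = np.mean(err <= 4 * Z_is.mc_se)
        assert frac_ok >= 0.95

    def test_standard_error_shrinks_with_root_n(self, rng):
        model = random_model(rng, 5)
        cov = random_covariates(rng, 10)
        se_small = iz.importance_sampling_Z(model, cov, n_samples=2_000,
                                            seed=3).mc_se.mean()
        se_big = iz.importance_sampling_Z(model, cov, n_samples=8_000,
                                          seed=4).mc_se.mean()
        assert se_big / se_small == pytest.approx(0.5, rel=0.25)

    def test_too_few_samples_rejected(self, rng):
        model = random_model(rng, 3)
        with pytest.raises(ValueError):
            iz.importance_sampling_Z(model, random_covariates(rng, 2),
                                     n_samples=1, seed=0)

    def test_reproducible_for_fixed_seed(self, rng):
        model = random_model(rng, 4)
        cov = random_covariates(rng, 5)
        a = iz.importance_sampling_Z(model, cov, n_samples=500, seed=11)
        b = iz.importance_sampling_Z(model, cov, n_samples=500, seed=11)
        assert np.array_equal(a.log_values, b.log_values)


class TestDeterministicBaselines:
    @pytest.mark.parametrize("method", ["nmf", "tap", "bethe", "low_rate"])
    def test_uncoupled_limit_is_exact(self, rng, method):
        model = random_model(rng, 6, j_scale=0.0)
        cov = random_covariates(rng, 5)
        Z = iz.deterministic_Z(model, cov, method=method)
        H = model.fields(cov)
        expected = np.sum(np.log1p(np.exp(H)), axis=1)
        assert np.allclose(Z.log_values, expected, atol=1e-7)

    def test_bethe_beats_naive_mean_field_at_weak_coupling(self, rng):
        model = random_model(rng, 8, j_scale=0.05, h_loc=-2.0)
        cov = random_covariates(rng, 30)
        Z_ex = iz.exact_partition(model, cov)
        err_nmf = np.abs(iz.deterministic_Z(model, cov, "nmf").log_values
                         - Z_ex.log_values)
        err_bethe = np.abs(iz.deterministic_Z(model, cov, "bethe").log_values
                           - Z_ex.log_values)
        assert np.mean(err_bethe < err_nmf) >= 0.8

    def test_naive_mean_field_is_a_lower_bound(self, rng):
        for _ in range(5):
            model = random_model(rng, 7, j_scale=0.4, h_loc=-1.5)
            cov = random_covariates(rng, 6)
            Z_nmf = iz.deterministic_Z(model, cov, "nmf")
            Z_ex = iz.exact_partition(model, cov)
            assert np.all(Z_nmf.log_values <= Z_ex.log_values + 1e-9)

    def test_unknown_method_rejected(self, rng):
        model = random_model(rng, 3)
        with pytest.raises(ValueError):
            iz.deterministic_Z(model, random_covariates(rng, 2), "kikuchi")
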