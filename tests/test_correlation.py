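"""Distance-decay correlation profiles and per-interval matrices."""

import numpy as np
import pytest
from scipy import stats

from epimodules.combine import z_transform
from epimodules.correlation import (
    CorrelationProfile,
    estimate_profile,
    interval_matrix,
    neighbor_distances,
)
from epimodules.genome_context import ContextDefinition, GeneModel, associate_loci, derive_intervals

from conftest import make_loci


def _assoc(positions, p_values):
    gene = GeneModel("G", "chr1", 0, max(positions) + 1, "+")
    ctx = ContextDefinition("body", "meth", ("gene_body",))
    (iv,) = derive_intervals([gene], ctx)
    loci = make_loci(positions, p_values)
    (assoc,) = associate_loci([iv], loci, ctx)
    return assoc


def constant_profile(rho, max_dist=1_000_000):
    return CorrelationProfile(
        context_name="c",
        bin_edges=np.array([0.0, float(max_dist)]),
        bin_mean_corr=np.array([rho]),
        bin_n_pairs=np.array([100]),
        n_resamples=1,
        n_bins=1,
    )


class TestNeighborDistances:
    def test_downstream_neighbor_only(self):
        assoc = _assoc([100, 150], [0.01, 0.5])
        pairs = neighbor_distances([assoc], significance_threshold=0.05)
        assert len(pairs) == 1
        d, za, zb = pairs[0]
        assert d == 50.0
        assert za == pytest.approx(z_transform(0.01))
        assert zb == pytest.approx(z_transform(0.5))

    def test_singleton_interval_contributes_nothing(self):
        assert neighbor_distances([_assoc([100], [0.001])]) == []

    def test_pair_count_matches_brute_force(self, rng):
        positions = np.sort(rng.choice(100_000, size=100, replace=False))
        p_values = rng.uniform(0.001, 1.0, size=100)
        assoc = _assoc([int(p) for p in positions], list(p_values))
        threshold = 0.2
        pairs = neighbor_distances([assoc], significance_threshold=threshold)
        # brute force: each significant locus pairs with nearest up/down neighbor
        expected = 0
        for k in range(100):
            if p_values[k] > threshold:
                continue
            expected += int(k > 0) + int(k < 99)
        assert len(pairs) == expected


class TestEstimateProfile:
    def test_perfect_correlation_limit(self, rng):
        z = rng.exponential(size=2000)
        d = rng.uniform(1, 5000, size=2000)
        pairs = list(zip(d, z, z))
        prof = estimate_profile(pairs, n_bins=20, n_resamples=50, seed=1)
        populated = prof.bin_n_pairs >= 3
        assert np.all(prof.bin_mean_corr[populated] > 0.99)

    def test_independence_limit(self, rng):
        pairs = list(zip(rng.uniform(1, 5000, 5000), rng.normal(size=5000), rng.normal(size=5000)))
        prof = estimate_profile(pairs, n_bins=10, n_resamples=100, seed=2)
        populated = prof.bin_n_pairs >= 3
        # each bin mean within 4 sigma of 0 (Pearson sd ~ 1/sqrt(bin size))
        bound = 4.0 / np.sqrt(prof.bin_n_pairs[populated])
        assert np.all(np.abs(prof.bin_mean_corr[populated]) < bound)

    def test_exponential_decay_recovered(self, rng):
        """Simulated corr(d) = exp(-d/1000) must come back as a decreasing profile."""
        n = 10_000
        d = rng.uniform(1, 5000, size=n)
        rho = np.exp(-d / 1000.0)
        za = rng.standard_normal(n)
        zb = rho * za + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        prof = estimate_profile(list(zip(d, za, zb)), n_bins=50, n_resamples=100, seed=3)
        populated = prof.bin_n_pairs >= 10
        corr = stats.spearmanr(prof.bin_centers[populated], prof.bin_mean_corr[populated]).statistic
        assert corr < -0.8
        # absolute accuracy: mean |estimated - true| over populated bins
        truth = np.exp(-prof.bin_centers[populated] / 1000.0)
        assert np.mean(np.abs(prof.bin_mean_corr[populated] - truth)) < 0.1

    def test_seeded_reproducibility(self, rng):
        pairs = list(zip(rng.uniform(1, 100, 500), rng.normal(size=500), rng.normal(size=500)))
        p1 = estimate_profile(pairs, n_bins=10, n_resamples=50, seed=9)
        p2 = estimate_profile(pairs, n_bins=10, n_resamples=50, seed=9)
        assert np.array_equal(p1.bin_mean_corr, p2.bin_mean_corr)

    def test_sparse_bin_flagged_zero(self):
        pairs = [(1.0, 0.5, 0.5), (2.0, 0.1, 0.2)]
        prof = estimate_profile(pairs, n_bins=2, n_resamples=10, seed=0)
        assert np.all(prof.bin_mean_corr[prof.bin_n_pairs < 3] == 0.0)

    def test_tsv_round_trip(self, tmp_path, rng):
        pairs = list(zip(rng.uniform(1, 100, 500), rng.normal(size=500), rng.normal(size=500)))
        prof = estimate_profile(pairs, n_bins=10, n_resamples=20, seed=4)
        path = tmp_path / "profile.tsv"
        prof.to_tsv(str(path))
        back = CorrelationProfile.from_tsv(str(path))
        np.testing.assert_allclose(back.bin_edges, prof.bin_edges)
        np.testing.assert_allclose(back.bin_mean_corr, prof.bin_mean_corr)


class TestIntervalMatrix:
    def test_single_locus(self):
        assoc = _assoc([10], [0.5])
        ic = interval_matrix(assoc, constant_profile(0.6))
        assert ic.matrix.shape == (1, 1)
        assert ic.matrix[0, 0] == 1.0
        assert ic.cholesky_upper[0, 0] == 1.0

    def test_two_locus_closed_form(self):
        """2x2 case against the closed-form Cholesky factor."""
        assoc = _assoc([10, 60], [0.5, 0.5])
        ic = interval_matrix(assoc, constant_profile(0.6))
        np.testing.assert_allclose(ic.matrix, [[1, 0.6], [0.6, 1]], atol=1e-12)
        np.testing.assert_allclose(ic.cholesky_upper, [[1, 0.6], [0, 0.8]], atol=1e-12)

    def test_factor_reconstructs_matrix(self, rng):
        positions = sorted(int(p) for p in rng.choice(5000, size=12, replace=False))
        assoc = _assoc(positions, [0.5] * 12)
        ic = interval_matrix(assoc, constant_profile(0.4))
        np.testing.assert_allclose(ic.cholesky_upper.T @ ic.cholesky_upper, ic.matrix, atol=1e-8)

    def test_repair_makes_positive_definite(self):
        """A decay profile sharp enough to break positive-definiteness gets repaired."""
        prof = CorrelationProfile(
            context_name="c",
            bin_edges=np.array([0.0, 15.0, 1e6]),
            bin_mean_corr=np.array([0.99, -0.5]),
            bin_n_pairs=np.array([10, 10]),
            n_resamples=1,
            n_bins=2,
        )
        assoc = _assoc([0, 10, 20, 30], [0.5] * 4)
        ic = interval_matrix(assoc, prof)
        eigvals = np.linalg.eigvalsh(ic.matrix)
        assert eigvals.min() >= 1e-6 - 1e-12
        np.testing.assert_allclose(np.diag(ic.matrix), 1.0, atol=1e-12)
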