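import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scpower.data_model import ExpressionThreshold, GammaMixture
from scpower.expression import (
    dispersion_from_mean,
    expected_expressed_genes,
    gene_expression_probability,
    mean_umi_from_reads,
    mixture_at_depth,
    rank_to_mean,
    reads_from_mean_umi,
)


class TestReadUMICurve:
    def test_inverse_of_log_linear(self, flat_prior):
        # curve (b0=0, b1=1000): reads = 1000 ln(umi)
        assert mean_umi_from_reads(flat_prior, 6907.755) == pytest.approx(1000, rel=1e-4)

    def test_round_trip(self, flat_prior):
        for umi in (1.0, 50.0, 2000.0):
            reads = reads_from_mean_umi(flat_prior, umi)
            assert mean_umi_from_reads(flat_prior, max(reads, 1e-9)) == pytest.approx(
                umi, rel=1e-9
            )

    def test_floor_at_one(self, flat_prior):
        # curve with intercept 5000: mapped reads at b0 imply mean UMI of 1
        flat_prior.read_umi_curve = type(flat_prior.read_umi_curve)(5_000.0, 1_000.0)
        with pytest.warns(UserWarning, match="floor"):
            assert mean_umi_from_reads(flat_prior, 1_000.0) == 1.0

    def test_invalid_curve(self, flat_prior):
        flat_prior.read_umi_curve = type(flat_prior.read_umi_curve)(0.0, -1.0)
        with pytest.raises(ValueError, match="slope"):
            mean_umi_from_reads(flat_prior, 100.0)


class TestMixtureAtDepth:
    def test_constant_curves_reproduce_mixture(self, flat_prior, truth_mixture):
        for depth in (10.0, 500.0, 5000.0):
            mix = mixture_at_depth(flat_prior, depth)
            assert mix.p1 == pytest.approx(truth_mixture.p1)
            assert mix.mean1 == pytest.approx(truth_mixture.mean1)
            assert mix.mean2 == pytest.approx(truth_mixture.mean2)

    def test_p1_floor(self, synthetic_prior):
        # p1 line = 0.5 - 1e-4 * umi goes negative above umi=5000
        mix = mixture_at_depth(synthetic_prior, 7000.0)
        assert mix.p1 == 0.01
        assert mix.p1 + mix.p2 + mix.p3 == pytest.approx(1.0)

    def test_moment_inversion(self, synthetic_prior):
        # component with mean 2 and sd 1 -> shape 4, rate 2
        prior = synthetic_prior
        prior.component_curves["mean1"] = type(prior.component_curves["mean1"])(2.0, 0.0)
        prior.component_curves["sd1"] = type(prior.component_curves["sd1"])(1.0, 0.0)
        mix = mixture_at_depth(prior, 100.0)
        assert mix.shape1 == pytest.approx(4.0)
        assert mix.rate1 == pytest.approx(2.0)

    def test_out_of_range_error(self, synthetic_prior):
        synthetic_prior.component_curves["mean1"] = type(
            synthetic_prior.component_curves["mean1"]
        )(0.1, -0.01)
        with pytest.raises(ValueError, match="mean1"):
            mixture_at_depth(synthetic_prior, 100.0)


class TestRankToMean:
    def test_exponential_closed_form(self):
        # single Exp(1) component, G=100, rank=50 -> -ln(0.495)
        mix = GammaMixture(0.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1e-9)
        mu = rank_to_mean(mix, 50, 100)
        assert mu == pytest.approx(-np.log(0.495), rel=1e-6)

    def test_zero_mass(self, truth_mixture):
        # deep rank -> quantile below p1 -> mu = 0
        g = 100
        rank = g  # q = 0.005 < p1 = 0.3
        assert rank_to_mean(truth_mixture, rank, g) == 0.0

    def test_monotone_nonincreasing(self, truth_mixture):
        ranks = np.arange(1, 501)
        mus = rank_to_mean(truth_mixture, ranks, 500)
        assert np.all(np.diff(mus) <= 1e-12)

    def test_rank_bounds(self, truth_mixture):
        with pytest.raises(ValueError):
            rank_to_mean(truth_mixture, 0, 100)
        with pytest.raises(ValueError):
            rank_to_mean(truth_mixture, 101, 100)

    def test_quantile_against_scipy_gamma(self):
        mix = GammaMixture(0.0, 1.0, 0.0, 3.0, 2.0, 1.0, 1.0)
        q = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(
            mix.quantile(q), stats.gamma.ppf(q, a=3.0, scale=0.5), rtol=1e-6
        )


class TestDispersionFromMean:
    def test_direct_evaluation(self, synthetic_prior):
        synthetic_prior.dispersion_trend = type(synthetic_prior.dispersion_trend)(a0=0.1, a1=2.0)
        assert dispersion_from_mean(synthetic_prior, 4.0) == pytest.approx(0.6)

    def test_constant_when_a1_zero(self, synthetic_prior):
        synthetic_prior.dispersion_trend = type(synthetic_prior.dispersion_trend)(a0=0.3, a1=0.0)
        for mu in (0.1, 1.0, 100.0):
            assert dispersion_from_mean(synthetic_prior, mu) == pytest.approx(0.3)

    def test_negative_clamped(self, synthetic_prior):
        synthetic_prior.dispersion_trend = type(synthetic_prior.dispersion_trend)(a0=-1.0, a1=0.0)
        assert dispersion_from_mean(synthetic_prior, 5.0) == 1e-8

    def test_zero_mean_error(self, synthetic_prior):
        with pytest.raises(ValueError):
            dispersion_from_mean(synthetic_prior, 0.0)


class TestGeneExpressionProbability:
    def test_zero_mean(self, default_threshold):
        assert gene_expression_probability(0.0, 0.5, 100, 4, default_threshold) == 0.0

    def test_closed_form_example(self):
        # mu=0.01, phi=2, n_cs=100, n=0, n_s=2, k=0.5:
        # p = 1 - (50/51)^50, P = p^2
        thr = ExpressionThreshold(min_count=0, individual_fraction=0.5)
        p = 1 - (50 / 51) ** 50
        expected = 1 - stats.binom.cdf(1, 2, p)
        got = gene_expression_probability(0.01, 2.0, 100, 2, thr)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.3950, abs=5e-4)

    def test_saturated(self):
        thr = ExpressionThreshold(min_count=0, individual_fraction=0.5)
        assert gene_expression_probability(1e6, 0.1, 100, 10, thr) == pytest.approx(1.0)

    def test_nonzero_cells_mode(self):
        thr = ExpressionThreshold(mode="nonzero-cells", min_count=2, individual_fraction=0.5)
        mu, phi, n_cs = 0.5, 1.0, 20
        p_cell = 1 - stats.nbinom.cdf(0, 1 / phi, (1 / phi) / (1 / phi + mu))
        p_ind = stats.binom.sf(1, n_cs, p_cell)
        expected = stats.binom.sf(1, 3, p_ind)
        assert gene_expression_probability(mu, phi, n_cs, 3, thr) == pytest.approx(expected)

    def test_length_normalized_requires_length(self):
        thr = ExpressionThreshold(min_count=1, individual_fraction=0.5, length_normalized=True)
        with pytest.raises(ValueError, match="gene_length"):
            gene_expression_probability(1.0, 0.5, 10, 4, thr)
        # 2kb transcript doubles the count threshold
        low = gene_expression_probability(1.0, 0.5, 10, 4, thr, gene_length=2000)
        base = gene_expression_probability(
            1.0, 0.5, 10, 4, ExpressionThreshold(min_count=2, individual_fraction=0.5)
        )
        assert low == pytest.approx(base)

    @settings(max_examples=30, deadline=None)
    @given(
        mu=st.floats(0.001, 50),
        phi=st.floats(0.01, 3),
        n=st.integers(0, 20),
        k=st.floats(0, 0.9),
    )
    def test_monotonicity_properties(self, mu, phi, n, k):
        thr = ExpressionThreshold(min_count=n, individual_fraction=k)
        thr_higher_n = ExpressionThreshold(min_count=n + 5, individual_fraction=k)
        p_small = gene_expression_probability(mu, phi, 10, 8, thr)
        p_more_cells = gene_expression_probability(mu, phi, 40, 8, thr)
        p_higher_mu = gene_expression_probability(mu * 2, phi, 10, 8, thr)
        p_stricter = gene_expression_probability(mu, phi, 10, 8, thr_higher_n)
        assert p_more_cells >= p_small - 1e-12
        assert p_higher_mu >= p_small - 1e-12
        assert p_stricter <= p_small + 1e-12
        assert 0.0 <= p_small <= 1.0


class TestPseudobulkLaw:
    def test_sum_of_nb_matches_scaled_law(self):
        # sum of n iid NB(mu, phi) ~ NB(n mu, phi/n): KS not rejected at 1%
        mu, phi, n = 2.0, 0.5, 30
        size = 1 / phi
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sums = rng.negative_binomial(size, size / (size + mu), size=(4000, n)).sum(axis=1)
            size2 = n / phi
            direct = rng.negative_binomial(size2, size2 / (size2 + n * mu), size=4000)
            _, pval = stats.ks_2samp(sums, direct)
            assert pval > 0.01


class TestExpectedExpressedGenes:
    def test_all_zero_mixture(self, flat_prior):
        flat_prior.component_curves["p1"] = type(flat_prior.component_curves["p1"])(0.99, 0.0)
        flat_prior.p3_const = 0.0
        # p1 = 0.99 leaves 1% of genes; force total zero weight via threshold
        total, probs = expected_expressed_genes(
            flat_prior, 10, 4, 1000.0, ExpressionThreshold(min_count=10**9, individual_fraction=0.5)
        )
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_bounds(self, flat_prior, default_threshold):
        total, probs = expected_expressed_genes(flat_prior, 50, 4, 5000.0, default_threshold)
        assert 0 <= total <= flat_prior.n_genes
        assert np.all((probs >= 0) & (probs <= 1))

    def test_monotone_in_cells(self, flat_prior, default_threshold):
        totals = [
            expected_expressed_genes(flat_prior, n_cs, 4, 5000.0, default_threshold)[0]
            for n_cs in (5, 20, 80)
        ]
        assert totals == sorted(totals)
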