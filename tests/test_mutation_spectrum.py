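"""Effect spectrum, improvement distribution, sampler, and fitters."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

import fixwalk as fw
from fixwalk.mutation_spectrum import EffectSample


def product_density_cdf(grid, alpha, N):
    """Independent oracle: numerically integrated, normalized product of the
    exponential occurrence density and the closed-form fixation probability
    of a single mutant."""

    def product(s):
        return alpha * math.exp(-alpha * s) * fw.fixation_probability_closed(
            1 / (2 * N), s, N
        )

    Z, _ = integrate.quad(product, 0, 50)
    return np.array([integrate.quad(product, 0, s)[0] / Z for s in grid])


class TestEffectDistribution:
    def test_pdf_at_zero_equals_rate(self):
        dist = fw.EffectDistribution(e_delta1=1 / 30)
        assert fw.effect_pdf(0.0, dist) == pytest.approx(30.0)
        assert dist.alpha == pytest.approx(30.0)

    def test_mean_is_e_delta1(self):
        dist = fw.EffectDistribution(e_delta1=0.2)
        mean, _ = integrate.quad(lambda s: s * fw.effect_pdf(s, dist), 0, np.inf)
        assert mean == pytest.approx(0.2, rel=1e-6)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            fw.effect_pdf(-0.1, fw.EffectDistribution(e_delta1=0.1))
        with pytest.raises(ValueError):
            fw.EffectDistribution(e_delta1=-1.0)


class TestImprovementDistribution:
    def test_beta_hand_value(self):
        expected = 1 / 30 - 1 / 32 + 1 / (1500 * 1531)
        assert fw.improvement_beta(30, 1500) == pytest.approx(expected, rel=1e-12)

    def test_beta_large_population_limit(self):
        assert fw.improvement_beta(30, math.inf) == pytest.approx(1 / 30 - 1 / 32)
        assert fw.improvement_beta(30, 1e9) == pytest.approx(1 / 30 - 1 / 32, rel=1e-6)

    @pytest.mark.parametrize("alpha", [10, 30, 60])
    @pytest.mark.parametrize("N", [100, 15000, math.inf])
    def test_cdf_normalized(self, alpha, N):
        dist = fw.ImprovementDistribution(alpha=alpha, N=N)
        assert fw.improvement_cdf(0.0, dist) == 0.0
        assert fw.improvement_cdf(10.0, dist) > 0.999

    def test_cdf_monotone(self):
        dist = fw.ImprovementDistribution(alpha=30, N=1500)
        vals = fw.improvement_cdf(np.linspace(0, 2, 500), dist)
        assert np.all(np.diff(vals) >= 0)

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError):
            fw.improvement_cdf(-0.5, fw.ImprovementDistribution(alpha=30, N=1500))

    def test_closed_form_matches_product_integral(self):
        """The closed-form CDF approximates the occurrence x fixation product;
        observed discrepancy is ~7e-4, asserted below 2e-3."""
        alpha, N = 30.0, 1500
        grid = np.linspace(0, 1, 41)
        oracle = product_density_cdf(grid, alpha, N)
        closed = fw.improvement_cdf(grid, fw.ImprovementDistribution(alpha=alpha, N=N))
        assert np.max(np.abs(oracle - closed)) < 2e-3

    def test_derivative_proportional_to_product_density(self):
        alpha, N = 30.0, 1500
        dist = fw.ImprovementDistribution(alpha=alpha, N=N)
        occ = fw.EffectDistribution(e_delta1=1 / alpha)
        grid = np.linspace(0.01, 0.5, 30)
        h = 1e-6
        deriv = (fw.improvement_cdf(grid + h, dist) - fw.improvement_cdf(grid - h, dist)) / (2 * h)
        prod = np.array(
            [fw.effect_pdf(s, occ) * fw.fixation_probability_closed(1 / (2 * N), s, N)
             for s in grid]
        )
        assert np.all(deriv >= 0)
        # the closed form tracks the exact product density to a few percent
        # pointwise (observed spread ~4%); proportionality asserted at 10%
        ratios = deriv / prod
        assert np.max(ratios) / np.min(ratios) == pytest.approx(1.0, rel=0.10)


class TestSampler:
    def test_draws_match_cdf(self, improvement_dist, rng):
        x = fw.sample_improvement(improvement_dist, rng, size=50_000)
        assert np.all(x > 0)
        ks = stats.kstest(x, lambda s: fw.improvement_cdf(s, improvement_dist))
        assert ks.statistic < 0.01

    def test_mean_matches_quadrature(self, improvement_dist, rng):
        x = fw.sample_improvement(improvement_dist, rng, size=50_000)
        alpha, N = improvement_dist.alpha, improvement_dist.N

        def product(s):
            return alpha * math.exp(-alpha * s) * fw.fixation_probability_closed(
                1 / (2 * N), s, N)

        Z, _ = integrate.quad(product, 0, 50)
        mean_oracle = integrate.quad(lambda s: s * product(s), 0, 50)[0] / Z
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - mean_oracle) < 3 * se

    def test_scalar_draw(self, improvement_dist):
        x = fw.sample_improvement(improvement_dist, np.random.default_rng(0))
        assert isinstance(x, float) and x > 0


class TestMLEFitter:
    def test_mle_is_sample_mean(self):
        fit = fw.fit_exponential_mle(EffectSample(effects=[0.1, 0.3]))
        assert fit.e_delta1 == pytest.approx(0.2)
        assert fit.se == pytest.approx(0.2 / math.sqrt(2))

    @given(st.lists(st.floats(1e-3, 10.0), min_size=2, max_size=30))
    def test_mle_identity(self, effects):
        fit = fw.fit_exponential_mle(EffectSample(effects=effects))
        assert fit.e_delta1 == pytest.approx(float(np.mean(effects)))

    def test_single_observation_flagged(self):
        fit = fw.fit_exponential_mle(EffectSample(effects=[0.5]))
        assert fit.e_delta1 == 0.5
        assert fit.se is None

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fw.fit_exponential_mle(EffectSample(effects=[]))

    def test_preobserved_sample_warns(self):
        with pytest.warns(UserWarning, match="conflates"):
            fw.fit_exponential_mle(EffectSample(effects=[0.1, 0.2], kind="preobserved"))

    def test_parameter_recovery(self, rng):
        effects = rng.exponential(1 / 30, size=1000)
        fit = fw.fit_exponential_mle(EffectSample(effects=effects))
        assert abs(fit.e_delta1 - 1 / 30) < 3 * fit.se


class TestLSQFitter:
    def test_exact_bins_identified(self):
        alpha = 37.0
        edges = np.linspace(0, 0.4, 9)
        probs = np.exp(-alpha * edges[:-1]) - np.exp(-alpha * edges[1:])
        sample = EffectSample(effects=[0.01], bin_edges=edges, bin_counts=probs * 1e6)
        fit = fw.fit_exponential_lsq(sample)
        assert fit.alpha == pytest.approx(37.0, rel=1e-4)

    def test_density_mode(self):
        alpha = 20.0
        edges = np.linspace(0, 0.4, 41)  # narrow bins: midpoint density is accurate
        probs = np.exp(-alpha * edges[:-1]) - np.exp(-alpha * edges[1:])
        sample = EffectSample(effects=[0.01], bin_edges=edges, bin_counts=probs * 1e6)
        fit = fw.fit_exponential_lsq(sample, fit_density=True)
        assert fit.alpha == pytest.approx(20.0, rel=0.01)

    def test_noisy_recovery_within_bootstrap_ci(self, rng):
        effects = rng.exponential(1 / 30, size=500)
        edges = np.linspace(0, effects.max() + 1e-9, 12)
        counts, _ = np.histogram(effects, bins=edges)
        sample = EffectSample(effects=effects, bin_edges=edges, bin_counts=counts)
        fit = fw.fit_exponential_lsq(sample)
        boots = []
        for _ in range(100):
            res = rng.choice(effects, size=500, replace=True)
            c, _ = np.histogram(res, bins=edges)
            boots.append(
                fw.fit_exponential_lsq(
                    EffectSample(effects=res, bin_edges=edges, bin_counts=c)
                ).alpha
            )
        lo, hi = np.quantile(boots, [0.005, 0.995])
        assert lo <= 30.0 <= hi
        assert fit.alpha == pytest.approx(30.0, rel=0.3)

    def test_too_few_bins_rejected(self):
        sample = EffectSample(effects=[0.1], bin_edges=[0, 0.2, 0.4], bin_counts=[1, 0])
        with pytest.raises(ValueError):
            fw.fit_exponential_lsq(sample)

    def test_unbinned_rejected(self):
        with pytest.raises(ValueError):
            fw.fit_exponential_lsq(EffectSample(effects=[0.1, 0.2]))


class TestEffectsTableIO:
    def test_round_trip(self, tmp_path, rng):
        sample = EffectSample(effects=rng.exponential(0.1, size=50))
        path = tmp_path / "effects.csv"
        fw.write_effects_table(sample, path)
        back = fw.read_effects_table(path)
        assert np.allclose(back.effects, sample.effects)

    def test_count_column_and_comments(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("# viral fitness effects\neffect,count\n0.1,2\n0.3,1\n")
        sample = fw.read_effects_table(path)
        assert sorted(sample.effects) == pytest.approx([0.1, 0.1, 0.3])

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0.1\n0.2\n")
        with pytest.raises(ValueError, match="effect"):
            fw.read_effects_table(path)

    def test_bad_value_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("effect\n0.1\n-0.5\n")
        with pytest.raises(ValueError, match="line 3"):
            fw.read_effects_table(path)


class TestEffectSampleValidation:
    def test_nonpositive_effects_rejected(self):
        with pytest.raises(ValueError):
            EffectSample(effects=[0.1, -0.2])

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            EffectSample(effects=[0.1], bin_edges=[0, 0.2, 0.1], bin_counts=[1, 1])
        with pytest.raises(ValueError):
            EffectSample(effects=[0.1], bin_edges=[0, 0.2], bin_counts=[1, 2])
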