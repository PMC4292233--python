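"""Quantitative-genetic core: equilibrium density, initialization,
normalized effects, genotypes, gametes, heterozygosity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import chisquare

from treeadapt import genetics as g


class TestEquilibriumDensity:
    def test_uniform_when_H_half_k2(self):
        # di-allelic locus at H = 0.5: density is flat at 1 everywhere
        for x in (0.3, 0.5, 0.99):
            assert g.equilibrium_allele_density(x, H=0.5, k=2) == pytest.approx(1.0)

    def test_u_shape_and_symmetry_at_low_H(self):
        # most alleles nearly fixed or nearly lost when H < 0.5
        assert g.equilibrium_allele_density(0.05, 0.25, 2) > g.equilibrium_allele_density(0.5, 0.25, 2)
        x = np.linspace(0.01, 0.99, 33)
        np.testing.assert_allclose(
            g.equilibrium_allele_density(x, 0.25, 2),
            g.equilibrium_allele_density(1 - x, 0.25, 2),
        )

    @pytest.mark.parametrize("H", [0.1, 0.25, 0.5, 0.8])
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_normalizes_to_one(self, H, k):
        val, _ = quad(g.equilibrium_allele_density, 0, 1, args=(H, k))
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [dict(x=0.0, H=0.5, k=2), dict(x=1.0, H=0.5, k=2),
                                     dict(x=0.5, H=0.0, k=2), dict(x=0.5, H=1.0, k=2),
                                     dict(x=0.5, H=0.5, k=1)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            g.equilibrium_allele_density(bad["x"], bad["H"], bad["k"])


def _phi_quantiles_brute(H, n_loci):
    """Independent oracle: numeric integration of phi plus bisection
    (handles the integrable endpoint singularities of the U-shape)."""

    def cdf(t):
        val, _ = quad(g.equilibrium_allele_density, 0, t, args=(H, 2), points=[0, t])
        return val

    out = []
    for i in range(1, n_loci + 1):
        level, lo, hi = (i - 0.5) / n_loci, 1e-12, 1 - 1e-12
        for _ in range(60):
            mid = (lo + hi) / 2
            if cdf(mid) < level:
                lo = mid
            else:
                hi = mid
        out.append((lo + hi) / 2)
    return np.array(out)


class TestInitialFrequencies:
    def test_uniform_density_gives_evenly_spaced(self):
        np.testing.assert_allclose(
            g.initial_allele_frequencies(0.5, 2, 10), np.arange(0.05, 1.0, 0.1)
        )

    def test_single_locus_uniform(self):
        np.testing.assert_allclose(g.initial_allele_frequencies(0.5, 2, 1), [0.5])

    def test_matches_brute_force_inversion(self):
        p = g.initial_allele_frequencies(0.25, 2, 10)
        np.testing.assert_allclose(p, _phi_quantiles_brute(0.25, 10), atol=2e-4)

    def test_low_H_symmetric_with_mass_near_extremes(self):
        p25 = g.initial_allele_frequencies(0.25, 2, 10)
        p50 = g.initial_allele_frequencies(0.5, 2, 10)
        np.testing.assert_allclose(p25 + p25[::-1], 1.0, atol=1e-12)
        assert p25[0] < p50[0] and p25[-1] > p50[-1]
        assert np.all(np.diff(p25) >= 0)
        assert np.all((p25 > 0) & (p25 < 1))


def _hwe_moments(p, effects):
    """Analytic HWE mean/variance of the summed diploid deviate."""
    q = 1 - p
    per_copy_mean = p * effects[:, 1] + q * effects[:, 0]
    per_copy_var = p * effects[:, 1] ** 2 + q * effects[:, 0] ** 2 - per_copy_mean**2
    return 2 * per_copy_mean.sum(), 2 * per_copy_var.sum()


class TestAllelicEffects:
    @given(st.lists(st.floats(0.02, 0.98), min_size=1, max_size=15))
    @settings(deadline=None, max_examples=50)
    def test_hwe_standardization_any_frequencies(self, freqs):
        p = np.array(freqs)
        effects, _ = g.assign_allelic_effects(p)
        mean, var = _hwe_moments(p, effects)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(1.0, abs=1e-9)

    def test_single_locus_half_gives_E_inv_sqrt2(self):
        effects, E = g.assign_allelic_effects(np.array([0.5]))
        assert E == pytest.approx(1 / np.sqrt(2))
        # the three diploid genotype values are -2E, 0, +2E with HWE
        # weights 1/4, 1/2, 1/4, whose variance is forced to 1
        vals = np.array([2 * effects[0, 0], effects[0, 0] + effects[0, 1], 2 * effects[0, 1]])
        np.testing.assert_allclose(vals, [-2 * E, 0.0, 2 * E], atol=1e-12)
        assert vals @ np.array([0.25, 0.5, 0.25]) == pytest.approx(0.0)
        assert (vals**2) @ np.array([0.25, 0.5, 0.25]) == pytest.approx(1.0)

    def test_extreme_genotypes_are_pm_20E(self):
        # 10-locus, di-allelic system: the fully "+" and fully "−"
        # homozygotes span 20E to −20E around the trait mean
        arch = g.TraitArchitecture.from_heterozygosity("t", 10, 0.25, 0.0, 1.0, 1.0)
        allplus = g.genotypic_values(np.ones((10, 2), dtype=np.int8), arch)
        allminus = g.genotypic_values(np.zeros((10, 2), dtype=np.int8), arch)
        assert allplus == pytest.approx(20 * arch.E, rel=1e-12)
        assert allminus == pytest.approx(-20 * arch.E, rel=1e-12)

    def test_monomorphic_architecture_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            g.assign_allelic_effects(np.array([1.0, 0.0]))


class TestGenotypicValue:
    def test_heterozygote_with_symmetric_effects_is_mean(self):
        arch = g.TraitArchitecture.from_heterozygosity("t", 4, 0.5, 100.0, 9.0, 1.0)
        # H=0.5 frequencies are symmetric; a genotype heterozygous at every
        # locus with the locus order reversed on the paternal copy cancels
        het = np.stack([np.zeros(4, dtype=np.int8), np.ones(4, dtype=np.int8)], axis=1)
        assert g.genotypic_values(het, arch) == pytest.approx(100.0)

    def test_zero_genetic_variance_collapses_to_mean(self, rng):
        arch = g.TraitArchitecture.from_heterozygosity("t", 10, 0.25, 125.0, 0.0, 1.0)
        geno = g.sample_genotypes(arch, 50, rng)
        np.testing.assert_allclose(g.genotypic_values(geno, arch), 125.0)

    def test_all_plus_homozygote_against_enumeration(self):
        arch = g.TraitArchitecture.from_heterozygosity("t", 10, 0.25, 125.0, 5.0, 0.5)
        got = g.genotypic_values(np.ones((10, 2), dtype=np.int8), arch)
        # enumeration oracle: sum per-copy effects explicitly
        acc = 125.0 + np.sqrt(5.0) * sum(
            arch.allelic_effect[l, 1] * 2 for l in range(10)
        )
        assert got == pytest.approx(acc)
        assert got == pytest.approx(125.0 + np.sqrt(5.0) * 20 * arch.E)

    def test_bad_allele_index_rejected(self, budburst_arch):
        geno = np.ones((10, 2), dtype=np.int8)
        geno[3, 1] = 2
        with pytest.raises(ValueError, match="allele index"):
            g.genotypic_values(geno, budburst_arch)


class TestPhenotypicValue:
    def test_full_heritability_is_exact(self, rng):
        arch = g.TraitArchitecture.from_heterozygosity("t", 10, 0.25, 125.0, 5.0, 1.0)
        G = np.linspace(120, 130, 11)
        np.testing.assert_array_equal(g.phenotypic_value(G, arch, rng), G)

    def test_environmental_variance_doubles_at_h2_half(self, rng):
        # h² = 0.5, Vg = 5 ⇒ Ve = 5 and phenotypic variance ≈ 10
        arch = g.TraitArchitecture.from_heterozygosity("t", 10, 0.25, 125.0, 5.0, 0.5)
        geno = g.sample_genotypes(arch, 100_000, rng)
        P = g.phenotypic_value(g.genotypic_values(geno, arch), arch, rng)
        assert np.var(P) == pytest.approx(10.0, rel=0.05)

    def test_source_population_genetic_variance_scale(self, budburst_arch, rng):
        # 235 trees sampled from the source population: genotypic sample
        # variance close to the configured 5 d
        geno = g.sample_genotypes(budburst_arch, 235, rng)
        G = g.genotypic_values(geno, budburst_arch)
        se = 5.0 * np.sqrt(2.0 / 234.0)
        assert abs(np.var(G, ddof=1) - 5.0) < 3 * se


class TestSamplingAndGametes:
    def test_fixed_frequencies_give_fixed_genotypes(self, rng):
        freq = np.column_stack([np.zeros(5), np.ones(5)])
        arch = g.TraitArchitecture(
            name="t", n_loci=5, k=2, heterozygosity_target=0.5,
            allele_freq=freq, allelic_effect=None,
            trait_mean=0.0, genetic_variance=1.0, heritability=1.0,
        )
        geno = g.sample_genotypes(arch, 100, rng)
        assert np.all(geno == 1)

    def test_sampled_allele_frequencies_match(self, budburst_arch, rng):
        n = 100_000
        geno = g.sample_genotypes(budburst_arch, n, rng)
        p_hat = np.mean(geno == 1, axis=(0, 2))
        p = budburst_arch.allele_freq[:, 1]
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert np.all(np.abs(p_hat - p) < 3 * se + 1e-12)

    def test_homozygote_gametes_identical(self, rng):
        geno = np.ones((10, 2), dtype=np.int8)
        gam = g.make_gamete(g.Genotype(geno), rng)
        np.testing.assert_array_equal(gam.alleles, np.ones(10))

    def test_heterozygote_gametes_uniform_over_1024(self, rng):
        # fully heterozygous 10-locus parent: all 2^10 gametes equiprobable
        geno = np.stack([np.zeros(10, dtype=np.int8), np.ones(10, dtype=np.int8)], axis=1)
        n = 100_000
        gams = g.make_gametes(np.broadcast_to(geno, (n, 10, 2)), rng)
        codes = gams @ (1 << np.arange(10))
        counts = np.bincount(codes, minlength=1024)
        assert chisquare(counts).pvalue > 1e-3

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_gamete_alleles_come_from_parent(self, seed):
        r = np.random.default_rng(seed)
        geno = r.integers(0, 2, size=(8, 2)).astype(np.int8)
        gam = g.make_gametes(geno, r)
        assert all(gam[l] in geno[l] for l in range(8))

    def test_gamete_pool_frequency_is_martingale(self, budburst_arch):
        # expected allele frequency among gametes equals the parental
        # population frequency (checked over 200 replicate pools)
        base = np.random.default_rng(99)
        parents = g.sample_genotypes(budburst_arch, 60, base)
        p_parent = np.mean(parents == 1)
        pool_freqs = []
        for rep in range(200):
            r = np.random.default_rng(1000 + rep)
            pool_freqs.append(np.mean(g.make_gametes(parents, r) == 1))
        se = np.std(pool_freqs, ddof=1) / np.sqrt(200)
        assert abs(np.mean(pool_freqs) - p_parent) < 3 * se


class TestHeterozygosity:
    def test_monomorphic_population_is_zero(self):
        geno = np.ones((20, 5, 2), dtype=np.int8)
        he, ho = g.population_heterozygosity(geno)
        assert he == 0.0 and ho == 0.0

    def test_single_locus_at_half(self):
        # 2 trees: one 0/0, one 1/1 -> p = 0.5, expected het = 2pq = 0.5
        geno = np.array([[[0, 0]], [[1, 1]]], dtype=np.int8)
        he, ho = g.population_heterozygosity(geno)
        assert he == pytest.approx(0.5)
        assert ho == 0.0

    def test_two_locus_hand_computed(self):
        # locus 1: alleles (0,1),(0,0) -> p1 = 0.25, 2pq = 0.375
        # locus 2: alleles (1,1),(0,1) -> p1 = 0.75, 2pq = 0.375
        geno = np.array([[[0, 1], [1, 1]], [[0, 0], [0, 1]]], dtype=np.int8)
        he, ho = g.population_heterozygosity(geno)
        assert he == pytest.approx(0.375)
        assert ho == pytest.approx(0.5)  # 2 of 4 tree-locus pairs

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            g.population_heterozygosity(np.empty((0, 5, 2), dtype=np.int8))
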