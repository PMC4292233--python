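"""Quantitative-genetic representation of adaptive model parameters.

A model parameter (e.g. the critical state of forcing that triggers bud
burst) is treated as a polygenic trait: ``n_loci`` unlinked di-allelic loci
contribute additively to a standardized genotypic deviate, which is scaled
by the genetic standard deviation ``sqrt(Vg)`` and shifted by the observed
population mean to give the parameter value of an individual tree.

Initial allele frequencies are drawn from the mutation–drift equilibrium
density ``phi(x)``, a Beta law parameterized by the population
heterozygosity ``H`` and the number of alleles per locus ``k``: inverting
its cumulative distribution at ``n_loci`` evenly spaced probability levels
yields one "+"-allele frequency per locus.  Raw allelic effects of +1/−1
are then affinely normalized so that, under Hardy–Weinberg equilibrium at
those frequencies, the summed diploid deviate has mean 0 and variance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as _beta

__all__ = [
    "TraitArchitecture",
    "Genotype",
    "Haplotype",
    "equilibrium_allele_density",
    "initial_allele_frequencies",
    "assign_allelic_effects",
    "genotypic_value",
    "genotypic_values",
    "phenotypic_value",
    "sample_genotype",
    "sample_genotypes",
    "make_gamete",
    "make_gametes",
    "population_heterozygosity",
]


def _beta_shapes(H: float, k: int) -> tuple[float, float]:
    if not 0.0 < H < 1.0:
        raise ValueError(f"heterozygosity H must lie in (0,1), got {H}")
    if k < 2:
        raise ValueError(f"alleles per locus k must be >= 2, got {k}")
    theta = H / (1.0 - H)
    return theta, (k - 1) * theta


def equilibrium_allele_density(x, H: float, k: int):
    """Equilibrium allele-frequency density phi(x).

    Beta(theta, (k-1)*theta) with theta = H/(1-H).  Uniform (phi = 1) for
    k = 2, H = 0.5; U-shaped for k = 2, H < 0.5 (most alleles near 0 or 1).

    Parameters
    ----------
    x : float or array, allele frequency in (0, 1)
    H : target heterozygosity in (0, 1)
    k : number of alleles per locus, >= 2
    """
    a, b = _beta_shapes(H, k)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("allele frequency x must lie strictly in (0,1)")
    out = _beta.pdf(x, a, b)
    return float(out) if out.ndim == 0 else out


def initial_allele_frequencies(H: float, k: int, n_loci: int) -> np.ndarray:
    """Per-locus "+"-allele frequencies from inverting the cumulative phi.

    Quantiles are taken at mid-levels (i - 0.5)/n_loci, i = 1..n_loci, so
    the set is symmetric for symmetric phi (p_l + p_{n+1-l} = 1 at k = 2)
    and no locus starts fixed.  Returned frequencies are non-decreasing.
    """
    if n_loci < 1:
        raise ValueError(f"n_loci must be >= 1, got {n_loci}")
    if k != 2:
        raise NotImplementedError(
            "allele-frequency initialization is implemented for di-allelic "
            "loci (k=2); phi itself accepts k>2 via equilibrium_allele_density"
        )
    a, b = _beta_shapes(H, k)
    levels = (np.arange(1, n_loci + 1) - 0.5) / n_loci
    p = _beta.ppf(levels, a, b)
    if not np.all(np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = levels[~np.isfinite(p) | (p <= 0) | (p >= 1)]
        raise ArithmeticError(f"quantile inversion failed at level(s) {bad}")
    return p


def assign_allelic_effects(freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize raw +1/−1 allelic effects for a di-allelic architecture.

    Raw per-copy effects (allele 0 → −1, allele 1 → +1) are centered by the
    per-locus Hardy–Weinberg mean copy effect (p − q) and divided by the
    HWE standard deviation of the summed diploid deviate,
    sigma = sqrt(8 · Σ_l p_l q_l), so the population mean is exactly 0 and
    the variance exactly 1 (analytic moments, not sampled).

    Returns
    -------
    effects : (n_loci, 2) array; effects[l, 1] = 2 q_l / sigma ("+" allele),
        effects[l, 0] = −2 p_l / sigma ("−" allele).
    E : per-allele effect magnitude 1/sigma.  The allele-substitution
        effect is 2E at every locus, so a fully "+" vs fully "−" homozygote
        differ by 4·n_loci·E (±2·n_loci·E around the center when the
        frequency set is symmetric).
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1:
        raise ValueError("freqs must be a 1-D vector of '+'-allele frequencies")
    q = 1.0 - p
    var = 8.0 * np.sum(p * q)
    if var <= 0.0:
        raise ValueError("degenerate architecture: all loci monomorphic")
    sigma = np.sqrt(var)
    effects = np.column_stack([-2.0 * p / sigma, 2.0 * q / sigma])
    return effects, 1.0 / sigma


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic encoding of one adaptive model parameter.

    Attributes
    ----------
    name : trait label (e.g. "S_c_star", "budburst_date")
    n_loci : number of unlinked loci
    k : alleles per locus (effects and simulation require k = 2)
    heterozygosity_target : H used to derive the initial frequencies
    allele_freq : (n_loci, k) initial allele frequencies; column 1 is the
        "+" allele for k = 2
    allelic_effect : (n_loci, k) standardized per-copy effects (unitless)
    trait_mean : population mean in trait units
    genetic_variance : Vg, trait units squared
    heritability : narrow-sense h² in (0, 1]
    E : per-allele effect magnitude after normalization
    """

    name: str
    n_loci: int
    k: int
    heterozygosity_target: float
    allele_freq: np.ndarray
    allelic_effect: np.ndarray | None
    trait_mean: float
    genetic_variance: float
    heritability: float
    E: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.k < 2:
            raise ValueError("n_loci >= 1 and k >= 2 required")
        if self.genetic_variance < 0.0:
            raise ValueError("genetic_variance must be >= 0")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        f = np.asarray(self.allele_freq, dtype=float)
        if f.shape != (self.n_loci, self.k):
            raise ValueError("allele_freq must have shape (n_loci, k)")
        if np.any(f < 0.0) or np.any(f > 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.max(np.abs(f.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("per-locus allele frequencies must sum to 1")
        object.__setattr__(self, "allele_freq", f)

    @classmethod
    def from_heterozygosity(
        cls,
        name: str,
        n_loci: int,
        heterozygosity: float,
        trait_mean: float,
        genetic_variance: float,
        heritability: float,
        k: int = 2,
    ) -> "TraitArchitecture":
        """Build a di-allelic architecture from (H, n_loci) as in the model
        initialization: phi-quantile frequencies plus normalized effects."""
        p = initial_allele_frequencies(heterozygosity, k, n_loci)
        freq = np.column_stack([1.0 - p, p])
        effects, E = assign_allelic_effects(p)
        return cls(
            name=name,
            n_loci=n_loci,
            k=k,
            heterozygosity_target=heterozygosity,
            allele_freq=freq,
            allelic_effect=effects,
            trait_mean=float(trait_mean),
            genetic_variance=float(genetic_variance),
            heritability=float(heritability),
            E=E,
        )

    @property
    def environmental_variance(self) -> float:
        """Ve such that h² = Vg / (Vg + Ve)."""
        h2 = self.heritability
        return self.genetic_variance * (1.0 - h2) / h2


@dataclass(frozen=True)
class Genotype:
    """Per-locus ordered diploid allele indices (maternal, paternal)."""

    alleles: np.ndarray  # (n_loci, 2) integer

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("Genotype.alleles must have shape (n_loci, 2)")
        object.__setattr__(self, "alleles", a)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]


@dataclass(frozen=True)
class Haplotype:
    """Per-locus single allele indices — one gamete."""

    alleles: np.ndarray  # (n_loci,) integer

    @property
    def n_loci(self) -> int:
        return np.asarray(self.alleles).shape[0]


def _check_conforms(alleles: np.ndarray, arch: TraitArchitecture) -> None:
    a = np.asarray(alleles)
    if a.shape[-2] != arch.n_loci:
        raise ValueError(
            f"genotype has {a.shape[-2]} loci, architecture {arch.n_loci}"
        )
    if np.any(a < 0) or np.any(a >= arch.k):
        raise ValueError(f"allele index outside [0, {arch.k})")


def genotypic_values(alleles: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Trait values for an array of genotypes, shape (..., n_loci, 2).

    value = trait_mean + sqrt(Vg) · Σ_loci Σ_copies allelic_effect
    """
    if arch.allelic_effect is None:
        raise ValueError(f"architecture {arch.name!r} has no allelic effects")
    _check_conforms(alleles, arch)
    a = np.asarray(alleles)
    eff = np.take_along_axis(
        np.broadcast_to(arch.allelic_effect, a.shape[:-1] + (arch.k,)), a, axis=-1
    )
    deviate = eff.sum(axis=(-2, -1))
    return arch.trait_mean + np.sqrt(arch.genetic_variance) * deviate


def genotypic_value(g: Genotype, arch: TraitArchitecture) -> float:
    """Trait value of a single genotype (deterministic)."""
    return float(genotypic_values(g.alleles, arch))


def phenotypic_value(G, arch: TraitArchitecture, rng: np.random.Generator):
    """Add an environmental deviate e ~ N(0, Ve), Ve = Vg·(1−h²)/h².

    The deviate is drawn once per individual (at birth); with h² = 1 the
    phenotype equals the genotypic value exactly.
    """
    G = np.asarray(G, dtype=float)
    ve = arch.environmental_variance
    if ve == 0.0:
        e = np.zeros(G.shape)
    else:
        e = rng.normal(0.0, np.sqrt(ve), size=G.shape)
    out = G + e
    return float(out) if out.ndim == 0 else out


def sample_genotypes(
    arch: TraitArchitecture, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n genotypes under Hardy–Weinberg and linkage equilibrium.

    Both allele copies are drawn independently per locus at the
    architecture's allele frequencies.  Returns (n, n_loci, 2) int8.
    """
    cdf = np.cumsum(arch.allele_freq, axis=1)  # (L, k)
    u = rng.random((n, arch.n_loci, 2))
    # searchsorted per locus against that locus' cdf
    out = np.empty((n, arch.n_loci, 2), dtype=np.int8)
    for l in range(arch.n_loci):
        out[:, l, :] = np.searchsorted(cdf[l], u[:, l, :], side="right")
    np.clip(out, 0, arch.k - 1, out=out)
    return out


def sample_genotype(arch: TraitArchitecture, rng: np.random.Generator) -> Genotype:
    return Genotype(sample_genotypes(arch, 1, rng)[0])


def make_gametes(alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per genotype: an allele copy chosen with probability 1/2
    per locus, independently across loci (free recombination).

    alleles : (..., n_loci, 2) → returns (..., n_loci)
    """
    a = np.asarray(alleles)
    pick = rng.integers(0, 2, size=a.shape[:-1])
    return np.take_along_axis(a, pick[..., None], axis=-1)[..., 0]


def make_gamete(g: Genotype, rng: np.random.Generator) -> Haplotype:
    return Haplotype(make_gametes(g.alleles, rng))


def population_heterozygosity(
    genotypes: np.ndarray, k: int = 2
) -> tuple[float, float]:
    """Expected and observed heterozygosity of a population.

    Parameters
    ----------
    genotypes : (n_trees, n_loci, 2) allele indices of the living trees
    k : number of alleles per locus

    Returns
    -------
    (expected, observed) : expected = mean over loci of 1 − Σ_a p̂_a² with
    p̂ the realized allele frequencies; observed = fraction of heterozygous
    tree-locus pairs.
    """
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[0] == 0:
        raise ValueError("need a non-empty (n, n_loci, 2) genotype array")
    n, L, _ = g.shape
    he = 0.0
    for l in range(L):
        counts = np.bincount(g[:, l, :].ravel(), minlength=k)
        p = counts / (2 * n)
        he += 1.0 - np.sum(p**2)
    expected = he / L
    observed = float(np.mean(g[:, :, 0] != g[:, :, 1]))
    return expected, observed
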