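"""Build the genetic architecture of a bud-burst trait and inspect it.

A model parameter becomes a quantitative trait: 10 di-allelic loci whose
"+"-allele frequencies come from inverting the cumulative equilibrium
density phi (here with heterozygosity H = 0.25), and whose +1/−1 allelic
effects are normalized to give a standardized deviate with Hardy–Weinberg
mean 0 and variance 1.
"""

import numpy as np

from treeadapt import genetics as g

arch = g.TraitArchitecture.from_heterozygosity(
    "budburst_date", n_loci=10, heterozygosity=0.25,
    trait_mean=125.0,        # day-of-year of May 5
    genetic_variance=5.0,    # d² — Dutch beech source population
    heritability=0.5,
)

print("'+'-allele frequencies per locus:")
print(np.round(arch.allele_freq[:, 1], 4))
print(f"per-allele effect magnitude E = {arch.E:.4f}")

hi = g.genotypic_values(np.ones((10, 2), dtype=np.int8), arch)
lo = g.genotypic_values(np.zeros((10, 2), dtype=np.int8), arch)
print(f"extreme genotypic values: {lo:.2f} .. {hi:.2f} d "
      f"(±20E·sqrt(Vg) around day {arch.trait_mean:.0f})")

rng = np.random.default_rng(1)
geno = g.sample_genotypes(arch, 235, rng)
G = g.genotypic_values(geno, arch)
P = g.phenotypic_value(G, arch, rng)
print(f"235 sampled trees: genotypic var {np.var(G, ddof=1):.2f} d "
      f"(configured Vg = 5), phenotypic var {np.var(P, ddof=1):.2f} d "
      f"(expected Vg/h² = 10)")
# The sample variance fluctuates around the configured genetic variance;
# halving heritability doubles the phenotypic variance.
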