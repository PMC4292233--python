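import numpy as np
import pytest

from treeadapt.genetics import TraitArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def budburst_arch():
    """Bud-burst-date trait of the source beech population: 10 di-allelic
    loci, H = 0.25, mean day-of-year 125 (May 5), Vg = 5 d, h² = 0.5."""
    return TraitArchitecture.from_heterozygosity(
        "budburst", n_loci=10, heterozygosity=0.25,
        trait_mean=125.0, genetic_variance=5.0, heritability=0.5,
    )
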