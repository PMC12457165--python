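import numpy as np
import pytest

from selindex.simulate import SimConfig, SimTraitSpec, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A small mixed founder/offspring population with one trait of each kind."""
    cfg = SimConfig(
        n_founders=80, n_offspring=40, n_trio_offspring=20,
        n_snps=600, n_causal_per_trait=60,
        maf_range=(0.1, 0.5),
        trait_specs=[
            SimTraitSpec("trainability", "ordinal", 0.4, (0.05, 0.20, 0.40, 0.25, 0.10)),
            SimTraitSpec("atopic_dermatitis", "binary", 0.3, 0.2),
            SimTraitSpec("gait", "continuous", 0.5),
        ],
        success_weights={"trainability": 0.53},
        missing_rate=0.03,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_grm(small_pop):
    from selindex import compute_grm
    return compute_grm(small_pop.genotypes)


@pytest.fixture
def toy_genotypes():
    """3 individuals x 2 SNPs with dosages ((0,2),(1,1),(2,0))."""
    from selindex import GenotypeMatrix
    return GenotypeMatrix(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
                          ["a", "b", "c"], ["s1", "s2"])
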