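import numpy as np
import pytest

from panelgp.grm import build_grm
from panelgp.simdata import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 500-individual polygenic dataset with moderate LD."""
    cfg = SimConfig(n_individuals=500, chromosome_lengths_bp=(5_000_000,) * 4,
                    marker_density_per_mb=100, seed=42, maf_floor=0.02,
                    traits=("ADG", "LW"), h2={"ADG": 0.4, "LW": 0.38},
                    genetic_corr=0.8)
    rng = np.random.default_rng(42)
    genotypes, marker_map = simulate_genotypes(cfg, rng)
    traits, truth = simulate_phenotypes(genotypes, marker_map, cfg, rng)
    return cfg, genotypes, marker_map, traits, truth


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    _, genotypes, *_ = small_dataset
    return build_grm(genotypes)
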