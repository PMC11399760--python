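import numpy as np
import pytest
from hypothesis import settings

from glycometa.synthetic_data import (CausalGene, SimConfig,
                                      simulate_all_cohorts,
                                      simulate_annotations, ancestry_mafs)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study conditions shared across the suite."""
    return SimConfig(
        n_cohorts_per_ancestry={"EUR": 2, "AFR": 1},
        n_individuals=400, n_variants=60, n_genes=6,
        causal_genes=[CausalGene(gene="GENE0", effect=0.15)],
        seed=11)


@pytest.fixture(scope="session")
def small_cohorts(small_cfg):
    return simulate_all_cohorts(small_cfg)


@pytest.fixture(scope="session")
def small_annotations(small_cfg):
    return simulate_annotations(
        small_cfg.variant_panel(), small_cfg.variant_gene_assignment(),
        seed=small_cfg.seed, maf_by_ancestry=ancestry_mafs(small_cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
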