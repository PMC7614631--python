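import numpy as np
import pytest

from devilclones.simcohort import (
    SyntheticGenome,
    dft1_config,
    dft2_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_genome() -> SyntheticGenome:
    return SyntheticGenome.generate(2_000_000, n_genes=12, n_l1=6, seed=7)


@pytest.fixture(scope="session")
def dft1_small():
    """A small DFT1-like cohort with full variant-level output."""
    cfg = dft1_config(n_tumours=10, genome_scale=1 / 1000, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def dft2_small():
    """A small DFT2-like cohort (male founder, LINE-1 active)."""
    cfg = dft2_config(n_tumours=10, genome_scale=1 / 1000, seed=202)
    return simulate_cohort(cfg)
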