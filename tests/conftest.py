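import numpy as np
import pytest

from taintscan.simulate import QTLSpec, SimConfig


@pytest.fixture
def tiny_cfg():
    """Small but non-degenerate study: 20 half-sib families, 2 chromosomes."""
    return SimConfig(
        n_sires=20,
        offspring_low=8,
        offspring_high=12,
        n_chrom=2,
        snps_per_chrom=40,
        founder_pool_size=8,
        qtl_specs=(QTLSpec(1, 50.0, 0.06),),
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
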