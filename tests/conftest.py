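import numpy as np
import pytest

from hicdelta.contact_io import GenomeSpec, bin_genome
from hicdelta.matrix_metrics import ice_normalize
from hicdelta.synthetic_data import (
    ExpressionEffects,
    SyntheticConfig,
    generate_expression,
    generate_pair,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded paired dataset under the generator's default conditions."""
    cfg = SyntheticConfig(seed=1)
    ds = generate_pair(cfg)
    ds.genes = generate_expression(ds.truth, cfg.genome, ExpressionEffects(), seed=1)
    return ds


@pytest.fixture(scope="session")
def iced_500(default_dataset):
    """ICE-balanced compartment-resolution matrices for both conditions."""
    return {
        cond: ice_normalize(default_dataset.matrices[(cond, 500_000)])
        for cond in ("normal", "tumor")
    }


@pytest.fixture(scope="session")
def iced_50(default_dataset):
    """ICE-balanced TAD-resolution matrices for both conditions."""
    return {
        cond: ice_normalize(default_dataset.matrices[(cond, 50_000)])
        for cond in ("normal", "tumor")
    }


@pytest.fixture
def one_chrom_bins():
    """A single 30 Mb chromosome binned at 50 kb (600 bins)."""
    return bin_genome(GenomeSpec(("chr1",), (30_000_000,)), 50_000)
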