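import numpy as np
import pytest

from soyadapt.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A small 4-group structured panel shared by read-only tests."""
    cfg = SimConfig(
        seed=42,
        n_per_group={"WILD": 30, "NR": 60, "HR": 60, "SR": 90},
        n_snps=600,
        n_chromosomes=5,
        chrom_length_bp=10_000_000,
        n_causal=8,
        missing_rate=0.05,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def two_group_genotypes():
    """A clean two-group panel for differentiation statistics."""
    from soyadapt.simulate import simulate_genotypes

    cfg = SimConfig(
        seed=7,
        n_per_group={"NR": 80, "SR": 80},
        n_snps=400,
        n_chromosomes=4,
        chrom_length_bp=8_000_000,
        fst_targets={("NR", "SR"): 0.12},
        n_causal=5,
        missing_rate=0.0,
    )
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
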