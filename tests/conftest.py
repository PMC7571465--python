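import numpy as np
import pytest

from rilmap.simulate import SimConfig, breed_ril_population


@pytest.fixture(scope="session")
def noiseless_pop():
    """Error-free reference population: 3 chromosomes x 300 SNPs, 100 lines."""
    cfg = SimConfig(
        n_chromosomes=3,
        chrom_lengths_cM=[100.0] * 3,
        chrom_lengths_bp=[20_000_000] * 3,
        n_snps_per_chrom=300,
        n_lines=100,
        mean_depth=30.0,
        error_rate=0.0,
        missing_rate=0.0,
        contaminated_line_fraction=0.0,
        seed=101,
    )
    return breed_ril_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
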