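import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from epidiverge.config import SimulationConfig
from epidiverge import synthetic_data as sd
from epidiverge import methylome_io as mio


SMALL = dict(
    n_chromosomes=2, chrom_length=600_000, n_genes=40, n_orphan_cgis=8,
    n_planted_dmrs=20, n_planted_degs=12, n_repeats=10, n_hdrs=1,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small but complete simulated study shared across tests."""
    return sd.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_study):
    return mio.filter_coverage(small_study["wild"])


def make_matrix(pos, meth, total, populations, chrom="chr1"):
    """Build a MethylomeMatrix from plain arrays (single chromosome)."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    samples = list(populations)
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64)})
    return mio.MethylomeMatrix(sites, meth, total, samples, dict(populations))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
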