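import numpy as np
import pytest

from svdiverge.io_formats import GenotypeMatrix
from svdiverge.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_fixture():
    """One simulated study at default parameters, shared across tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(default_fixture, tmp_path_factory):
    """The default study written to disk in every external format."""
    outdir = tmp_path_factory.mktemp("fixture")
    default_fixture.write(outdir)
    return outdir


def make_matrix(calls, sample_prefix="S", depths=None):
    """Small GenotypeMatrix from a samples x variants nested list."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"sv{j}" for j in range(m)],
        calls,
        depths,
    )
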