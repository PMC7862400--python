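import numpy as np
import pytest

from iddtools.synthetic_data import SimConfig, generate, write_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic bundle shared across tests."""
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    """The same bundle written to disk in its external formats."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, outdir)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
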