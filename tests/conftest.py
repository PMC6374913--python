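import dataclasses

import pytest
from hypothesis import settings

from genbias import syndata

settings.register_profile("genbias", deadline=None, derandomize=True)
settings.load_profile("genbias")


@pytest.fixture(scope="session")
def small_config() -> syndata.SimConfig:
    return syndata.SimConfig(n_orthogroups=150, seed=42)


@pytest.fixture(scope="session")
def bundle(small_config):
    """One shared synthetic bundle (150 orthogroups, seed 42)."""
    return syndata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    bundle.write(d)
    return d


@pytest.fixture()
def make_config():
    def _make(**overrides) -> syndata.SimConfig:
        return dataclasses.replace(syndata.SimConfig(), **overrides)

    return _make
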