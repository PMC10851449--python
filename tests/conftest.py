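import pytest

from medmap.synthetic import SimConfig, generate_fixture


@pytest.fixture
def small_config():
    return SimConfig(n_soc=4, n_pt_per_soc=6, seed=11)


@pytest.fixture
def fixture_dir(tmp_path, small_config):
    """A small generated vocabulary release plus its ground truth."""
    truth = generate_fixture(small_config, tmp_path)
    return tmp_path, small_config, truth
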