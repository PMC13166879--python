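import pytest

from nanohgt.simulate import SimConfig, simulate_bundle, write_bundle


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale bundle: 80 nanochromosomes, 5 planted alien genes."""
    return SimConfig(n_contigs=80, n_alien=5, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_config, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(small_config, d)
    return d


@pytest.fixture(scope="session")
def bundle_inputs(bundle_dir):
    from nanohgt.cli import load_bundle_inputs

    return load_bundle_inputs(bundle_dir)
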