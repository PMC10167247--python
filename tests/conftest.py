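import pytest

from nfatevo import pipeline, simulate


@pytest.fixture(scope="session")
def species_tree():
    """A small fixed species tree shared by simulator-driven tests."""
    return simulate.simulate_species_tree(8, 1.0, seed=3)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The bundled synthetic demo study, generated once per session."""
    out = tmp_path_factory.mktemp("demo")
    cfg_path = pipeline.make_demo(out, seed=1)
    return cfg_path
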