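import pytest

from codel import fixtures as fx


@pytest.fixture(scope="session")
def af_kb():
    return fx.bundled_kb("atrial_fibrillation")


@pytest.fixture(scope="session")
def depression_kb():
    return fx.bundled_kb("depression")


@pytest.fixture(scope="session")
def protocols():
    return fx.bundled_protocols()


@pytest.fixture(scope="session")
def af_fixture():
    return fx.build_af_fixture()


@pytest.fixture(scope="session")
def af_transcripts(af_fixture):
    _, configs = af_fixture
    return {name: fx.run_config(cfg) for name, cfg in configs.items()}


@pytest.fixture(scope="session")
def emily_transcript():
    _, cfg = fx.build_depression_fixture()
    return fx.run_config(cfg)
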