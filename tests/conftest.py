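import pytest

from fishwelfare import default_model_config, default_ontology


@pytest.fixture(scope="session")
def cfg():
    return default_model_config()


@pytest.fixture(scope="session")
def onto():
    return default_ontology()


@pytest.fixture(scope="session")
def cfg_dict(cfg):
    """Mutable copy of the default config as a plain mapping."""
    return cfg.model_dump()
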