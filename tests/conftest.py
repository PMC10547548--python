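import pytest

from inclufit.interface import generate_fixture, model_from_dict


@pytest.fixture
def random_model_factory():
    """Seed -> (IFModel, expected effect from the straight-line reference evaluator)."""

    def make(seed: int):
        doc, sidecar = generate_fixture(seed)
        return model_from_dict(doc), sidecar["effect"]

    return make
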