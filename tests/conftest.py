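import pytest

from fuzzygrant import demo_case


@pytest.fixture(scope="session")
def case():
    """The bundled Ukrainian healthcare competition case."""
    return demo_case()
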