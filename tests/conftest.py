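import pytest

from riboconnect.demo import demo_gate_pool
from riboconnect.fixtures import FixtureSpec, generate_fixture_transcript
from riboconnect.rna_io import packaged_aptamer_library


@pytest.fixture(scope="session")
def library():
    return packaged_aptamer_library()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def transcript(fixture_spec):
    return generate_fixture_transcript(fixture_spec, id="toy_mrna", capped=True)


@pytest.fixture(scope="session")
def gate_pool():
    return demo_gate_pool(seed=0)
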