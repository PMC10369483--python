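import pytest

from ffport.fixtures import generate_fixture_ff
from ffport.pipeline import run_conversion_from_file


@pytest.fixture(scope="session")
def fixture_ff(tmp_path_factory):
    """The full synthetic toy force field, written to disk once."""
    fx = generate_fixture_ff(seed=1, size=10)
    outdir = tmp_path_factory.mktemp("fixture_ff")
    config_path = fx.write(str(outdir))
    return fx, config_path


@pytest.fixture(scope="session")
def conversion(fixture_ff, tmp_path_factory):
    """One full conversion run shared by the read-only tests."""
    _fx, config_path = fixture_ff
    outdir = tmp_path_factory.mktemp("port")
    return run_conversion_from_file(config_path, outdir=str(outdir))


@pytest.fixture(scope="session")
def merged(conversion):
    return conversion.source
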