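import pytest

from g4switch import build_ceb_family


@pytest.fixture(scope="session")
def ceb():
    """The ten-member CEB oligonucleotide family keyed by acronym."""
    return {r.id: r for r in build_ceb_family()}
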