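import pytest

import endodiv as ed


@pytest.fixture(scope="session")
def catalog():
    """The packaged 77-isolate survey catalog."""
    return ed.datasets.load_isolate_catalog()


@pytest.fixture(scope="session")
def phyto_results():
    """Radicle-inhibition screen of the 77 fermentation broths."""
    return ed.datasets.load_phytotoxicity()


@pytest.fixture(scope="session")
def zone_records():
    """Disc-diffusion/MIC panel of the purified compounds."""
    return ed.datasets.load_zone_table()
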