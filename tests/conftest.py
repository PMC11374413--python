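import pytest

import thermniche as tn


@pytest.fixture(scope="session")
def bagrada():
    return tn.bagrada()


@pytest.fixture(scope="session")
def harlequin():
    return tn.harlequin()


@pytest.fixture(scope="session")
def generic():
    return tn.generic_warm()


@pytest.fixture(scope="session")
def bagrada_niche(bagrada):
    return tn.niche_metrics(bagrada)


@pytest.fixture(scope="session")
def harlequin_niche(harlequin):
    return tn.niche_metrics(harlequin)
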