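import pytest

from gprich import FrequencyCounts, load_fixture


@pytest.fixture(scope="session")
def vascular():
    """Vascular-plant survey row (188 species, 1,008 individuals)."""
    return load_fixture("vascular")


@pytest.fixture(scope="session")
def butterfly():
    """Malayan butterfly survey row (620 species, 9,031 individuals)."""
    return load_fixture("butterfly")


@pytest.fixture(scope="session")
def vascular_fc(vascular):
    """Full vascular spectrum with the aggregated tail expanded."""
    return vascular.frequency_counts()


@pytest.fixture(scope="session")
def butterfly_fc(butterfly):
    return butterfly.frequency_counts()


@pytest.fixture
def simple_fc():
    """Small hand-checkable spectrum: 6 species, 15 individuals."""
    return FrequencyCounts({1: 2, 2: 1, 3: 2, 5: 1})
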