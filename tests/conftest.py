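import pytest

from pahrisk import SizeConversionTable, load_analyte_metadata


@pytest.fixture(scope="session")
def meta():
    return load_analyte_metadata()


@pytest.fixture(scope="session")
def size_table():
    return SizeConversionTable.default()
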