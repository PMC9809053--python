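import pytest

from molfrag.fixtures import panel_records, toy_panel


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture()
def panel_mols():
    """Fresh molecule records for the fixture panel (mutable per test)."""
    return panel_records()
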