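import pytest

from solvadv import Conditions, load_reference_table


@pytest.fixture(scope="session")
def reference_rows():
    """The bundled 12-row coformer table (11 coformers + API row)."""
    return load_reference_table()


@pytest.fixture(scope="session")
def reference_by_name(reference_rows):
    return {row.name: row for row in reference_rows}


@pytest.fixture(scope="session")
def body_conditions():
    """Reference experimental conditions: pH 6.5, 37 °C."""
    return Conditions(ph=6.5, temperature=310.15)
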