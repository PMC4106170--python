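import pytest

from acacs import example_table
from acacs.synthetic import SyntheticShiftConfig, generate_shift_corpus


@pytest.fixture(scope="session")
def fixture_table():
    """The bundled example ACS table (built from a synthetic corpus)."""
    return example_table()


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic shift corpus with its emission log."""
    return generate_shift_corpus(
        SyntheticShiftConfig(n_proteins=3, length_range=(10, 10), seed=42)
    )
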