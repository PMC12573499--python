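import pytest

from cladeprimer.primer_model import builtin_primers
from cladeprimer.synthetic_fixtures import (
    classification_panel_config,
    generate_pcr_templates,
    generate_reference_panel,
    table2_panel_config,
)


@pytest.fixture(scope="session")
def primers():
    return builtin_primers()


@pytest.fixture(scope="session")
def clade_pair(primers):
    """The shipped clade-specific forward/reverse pair."""
    return primers["BM0639-5LNA"], primers["BM0853-3LNA"]


@pytest.fixture(scope="session")
def template_panel():
    """13-template in-silico PCR panel (5 target-role templates)."""
    return generate_pcr_templates(table2_panel_config(seed=101))


@pytest.fixture(scope="session")
def reference_panel():
    """Aligned reference panel with the same taxon structure."""
    return generate_reference_panel(table2_panel_config(seed=202))


@pytest.fixture(scope="session")
def classification_panel():
    return generate_pcr_templates(classification_panel_config(seed=303))
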