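import numpy as np
import pytest

from statemr.core_io import GeneRecord
from statemr.synthetic import simulate_ld_panel


@pytest.fixture(scope="session")
def panel_small():
    """50-SNP, 300-individual reference panel with realistic LD decay."""
    return simulate_ld_panel(50, 300, 0.95, (0.05, 0.5), seed=101)


@pytest.fixture(scope="session")
def panel_medium():
    """200-SNP, 400-individual panel spanning ~1 Mb."""
    return simulate_ld_panel(200, 400, 0.95, (0.05, 0.5), seed=202)


@pytest.fixture(scope="session")
def centered_gene():
    """A gene whose +-500 kb cis window covers the whole simulated region."""
    return GeneRecord("GENE1", "1", 495_000, 505_000, "+", "CD4_naive_0h")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
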