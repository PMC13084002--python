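import numpy as np
import pytest

from esrkit import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trace_data():
    """Mixed 50:50 population, 5x iRFP offset, peak deficit 0.3."""
    cfg = synth.GeneratorConfig(seed=11, n_cells=120)
    return synth.gen_cell_traces(cfg)


@pytest.fixture(scope="session")
def expression_data():
    cfg = synth.GeneratorConfig(seed=12, n_genes=400)
    return synth.gen_expression(cfg)
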