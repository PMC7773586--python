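import numpy as np
import pytest

from cytokinetics.align import aggregate
from cytokinetics.panel import DEFAULT_GRID, load_signature_table, panel_by_id
from cytokinetics.simulate import simulate_panel


@pytest.fixture(scope="session")
def panel():
    return load_signature_table()


@pytest.fixture(scope="session")
def byid(panel):
    return panel_by_id(panel)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def control_means(panel):
    """Mean kinetics of the full default panel, 30 cells/protein, seed 1."""
    traces, truth = simulate_panel(panel, n_cells=30, seed=1)
    mks = {}
    for tpl in panel:
        sub = [t for t in traces if t.protein_id == tpl.protein_id]
        mks[tpl.protein_id] = aggregate(sub, protein_id=tpl.protein_id)
    return mks
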