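import numpy as np
import pandas as pd
import pytest

from oxistate.containers import GeneSet
from oxistate.preprocess import log_normalize, qc_filter
from oxistate.simulate import SimConfig, make_gene_set, simulate_bulk, simulate_cells


@pytest.fixture(scope="session")
def sim_cfg():
    """Reference study conditions: 2,000 cells, 400-gene OS set, 200
    responsive genes boosted 2-fold in 25% of cells."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def study(sim_cfg):
    """Simulated cells + truth, QC-filtered and log-normalized."""
    cells, truth = simulate_cells(sim_cfg)
    cells = log_normalize(qc_filter(cells))
    return cells, truth


@pytest.fixture(scope="session")
def os_set(sim_cfg):
    gene_set, _ = make_gene_set(sim_cfg)
    return gene_set


@pytest.fixture(scope="session")
def bulk_study(sim_cfg):
    return simulate_bulk(sim_cfg)


@pytest.fixture()
def random_panels():
    """20 random 50-cell x 200-gene matrices with a 25-gene set (seeded)."""
    rng = np.random.default_rng(42)
    panels = []
    genes = [f"g{i:03d}" for i in range(200)]
    s = GeneSet("s", tuple(rng.choice(genes, size=25, replace=False)))
    for i in range(20):
        vals = rng.gamma(2.0, 1.0, size=(50, 200))
        # inject ties so average-rank handling is exercised
        vals[vals < 0.3] = 0.0
        df = pd.DataFrame(
            vals, index=[f"c{j}" for j in range(50)], columns=genes
        )
        panels.append(df)
    return panels, s
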