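import numpy as np
import pandas as pd
import pytest

from subpoisson.model import ModelSpec
from subpoisson.synthetic import (
    PopulationConfig,
    SpotNoiseConfig,
    generate_population,
    generate_spot_table,
)


@pytest.fixture(scope="session")
def small_population():
    """300 cells from the default 3-step model with ground truth."""
    pop = PopulationConfig(n_cells=300)
    cells, truth = generate_population(pop, seed=101)
    spots = generate_spot_table(cells, truth, SpotNoiseConfig(), seed=102)
    return pop, cells, truth, spots


@pytest.fixture()
def toy_spots():
    """Hand-built two-cell, one-replicate spot table (all cytoplasmic)."""
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c1", "c1", "c2", "c2"],
            "replicate_id": ["r1"] * 5,
            "channel": ["mRNA"] * 5,
            "x": 0.0,
            "y": 0.0,
            "z": 0.0,
            "intensity": [2.0, 4.0, 6.0, 4.0, 4.0],
            "compartment": ["cytoplasmic"] * 5,
        }
    )


@pytest.fixture()
def simple_cells():
    def make(cell_ids, n_nuclei=1, length=10.0, width=3.5, radius=1.0):
        rows = []
        for cid in cell_ids:
            rows.append(
                {
                    "cell_id": cid,
                    "replicate_id": "r1",
                    "length": length,
                    "width": width,
                    "n_nuclei": n_nuclei,
                    "nuc1_x": 0.0,
                    "nuc1_y": 0.0,
                    "nuc1_z": 0.0,
                    "nuc1_r": radius,
                    "nuc2_x": 2.5 if n_nuclei == 2 else np.nan,
                    "nuc2_y": 0.0 if n_nuclei == 2 else np.nan,
                    "nuc2_z": 0.0 if n_nuclei == 2 else np.nan,
                    "nuc2_r": radius if n_nuclei == 2 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    return make
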