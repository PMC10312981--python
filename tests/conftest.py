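import numpy as np
import pandas as pd
import pytest

from cisa import AnalysisConfig, CellTable, LabelMask, MarkerImage
from cisa.synthetic import SyntheticConfig, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """A small noiseless f=2 tissue shared across read-only tests."""
    cfg = SyntheticConfig(n_pairs=15, n_other=5, polarization_factor=2.0, rng_seed=11)
    return generate_tissue(cfg)


@pytest.fixture()
def three_cell_mask():
    """Reference 5x5 square flanked by two neighbors touching its membrane."""
    labels = np.zeros((13, 17), np.int32)
    labels[4:9, 6:11] = 1  # reference
    labels[4:9, 1:5] = 2  # left neighbor (1 px gap)
    labels[4:9, 12:16] = 3  # right neighbor (1 px gap)
    mask = LabelMask(labels)
    df = pd.DataFrame(
        {
            "cell_id": [1, 2, 3],
            "x_um": [8.0, 2.5, 13.5],
            "y_um": [6.0, 6.0, 6.0],
            "types": [
                frozenset({"T-cell"}),
                frozenset({"macrophage"}),
                frozenset({"macrophage"}),
            ],
        }
    )
    return mask, CellTable(df)


def make_cell_table(xy, types, window_um=None):
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xy) + 1),
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "types": [frozenset({t}) if isinstance(t, str) else frozenset(t) for t in types],
        }
    )
    return CellTable(df, window_um=window_um)
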