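import numpy as np
import pytest

from sdmshift.grid import RasterGrid
from sdmshift.pipeline import RunConfig, run_pipeline


@pytest.fixture
def small_grid() -> RasterGrid:
    """3x3 geographic grid, origin (30, 31), half-degree cells."""
    return RasterGrid(
        values=np.arange(9, dtype=float).reshape(3, 3),
        mask=np.zeros((3, 3), dtype=bool),
        origin_x=30.0,
        origin_y=31.0,
        cell_size=0.5,
    )


@pytest.fixture(scope="session")
def small_run():
    """One full pipeline run on a small synthetic world, shared by the
    end-to-end and map-algebra tests."""
    cfg = RunConfig.from_dict(
        {
            "seed": 7,
            "simulate": {"n_rows": 60, "n_cols": 60, "n_species": 5,
                         "n_presences_per_species": 60, "n_pas": 8},
            "model": {"background_n": 1500, "n_knots": 5},
            "evaluation": {"k": 5},
            "pa": {"n_random_pixels": 800},
        }
    )
    return cfg, run_pipeline(cfg)
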