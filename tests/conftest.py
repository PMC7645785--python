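import numpy as np
import pandas as pd
import pytest

import handmap as hm


@pytest.fixture(scope="session")
def grid():
    return hm.make_target_grid()


@pytest.fixture(scope="session")
def small_config():
    """A 6-subject cohort, otherwise default conditions."""
    return hm.CohortConfig(n_subjects=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config, grid):
    return hm.generate_cohort(small_config, grid)


@pytest.fixture(scope="session")
def small_maps(small_cohort, grid):
    return hm.build_all_maps(small_cohort, grid)


@pytest.fixture(scope="session")
def default_maps(grid):
    """Maps of a full default 26-subject cohort (shared, read-only)."""
    cfg = hm.CohortConfig(seed=5)
    return hm.build_all_maps(hm.generate_cohort(cfg, grid), grid)


def make_trials(grid, errors_mm, subject_id=0, session=1):
    """Build a matching-trial table with prescribed (2, rows, cols) errors in mm."""
    geom = grid.geometry
    rows, cols = np.indices((geom.n_rows, geom.n_cols))
    r, c = rows.ravel(), cols.ravel()
    pos = grid.positions
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "experiment": 1,
            "session": session,
            "trial_index": np.arange(1, geom.n_targets + 1),
            "target_row": r + 1,
            "target_col": c + 1,
            "target_x_mm": pos[r, c, 0],
            "target_y_mm": pos[r, c, 1],
            "hand_x_mm": pos[r, c, 0] + errors_mm[0, r, c],
            "hand_y_mm": pos[r, c, 1] + errors_mm[1, r, c],
        }
    )


@pytest.fixture
def uniform_map():
    """A map with the same (3, 4) mm error vector everywhere (0.5 cm magnitude)."""
    errors = np.zeros((2, 5, 20))
    errors[0] = 0.3
    errors[1] = 0.4
    return hm.ErrorMap(errors=errors, subject_id="u", session=1)
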