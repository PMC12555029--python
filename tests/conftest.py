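import numpy as np
import pandas as pd
import pytest

from imctme import phenotyping as ph
from imctme.panel import default_panel
from imctme.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort reused across modules (read-only)."""
    cfg = CohortConfig(
        n_samples=6, n_primary=2, rois_per_sample=(2, 2),
        cells_per_roi=(800, 800), roi_side_um=400.0, seed=123,
    )
    cells, meta, truth = simulate_cohort(cfg)
    return cfg, cells, meta, truth


@pytest.fixture(scope="session")
def phenotyped_cohort(small_cohort, panel):
    cfg, cells, meta, truth = small_cohort
    positivity = ph.fit_positivity(cells, panel, method="otsu")
    tree = ph.default_gating_tree(panel)
    labeled, summary = ph.assign_lineages(cells, tree, positivity)
    return cfg, labeled, meta, truth, positivity, summary


def random_cell_table(panel, n=20, seed=0):
    """A schema-complete random cell table for round-trip tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "cell_id": [f"R1_C{i:04d}" for i in range(n)],
        "sample_id": "S01",
        "roi_id": "S01_R1",
        "x_um": rng.uniform(0, 100, n),
        "y_um": rng.uniform(0, 100, n),
    })
    for m in panel.names:
        df[m] = np.exp(rng.normal(0, 1, n))
    return df
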