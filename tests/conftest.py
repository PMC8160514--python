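import numpy as np
import pandas as pd
import pytest

import immunoreo as ir


@pytest.fixture(scope="session")
def small_cfg():
    """Compact three-cell-type configuration for fast fixture pipelines."""
    return ir.SyntheticConfig(
        seed=42,
        n_genes=300,
        cell_types=("B_cells", "NK_cells", "monocytes"),
        markers_per_type=12,
        marker_fold=6.0,
        noise_sd=0.2,
        samples_per_reference=12,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_cfg):
    return ir.make_reference_cohorts(small_cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cohorts):
    """(background, signatures, params, cohorts) for the compact fixture."""
    cancer, control, immune, markers = small_cohorts
    background, signatures = ir.derive_signatures(cancer, immune, markers)
    params = ir.calibrate(cancer, control, immune, signatures, background)
    return background, signatures, params, small_cohorts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        {
            "s1": [5.0, 3.0, 1.0],
            "s2": [6.0, 2.0, 4.0],
        },
        index=["G1", "G2", "G3"],
    )
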