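"""Shared fixtures: one full-grid default-conditions pipeline run.

The run uses the default four-donor scenario with the complete
3 algorithms x 3 equations candidate grid; simulation sizes (candidate
grid, forest size, restarts) are scaled down from the package defaults so
the whole suite stays fast, which does not change any of the structural
counts the run is used to verify.
"""

import pytest

from mediaforge.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run():
    config = PipelineConfig(
        seed=1,
        n_lambda=30,
        rf_trees=100,
        rf_mtry_grid=[1 / 3, 1.0],
        n_formulations=20_000,
        elbow_kmax=8,
        n_restarts=15,
    )
    return run_pipeline(config)
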