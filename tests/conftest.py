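import numpy as np
import pytest

import mmstack as ms

FAST_ENET = ms.HyperparamGrid(l1_ratios=(0.5,), alphas=(0.01, 0.1, 1.0))
FAST_RF = ms.RFGrid(n_estimators=(50,), max_depths=(3,), max_features=(1.0,))


def small_block_specs(region_count: int = 10, n_features: int = 30):
    """Three compact blocks: two connectivity vectors, one region map."""
    return (
        ms.BlockSpec("fc_rest", "connectivity_vector", "rest",
                     region_count=region_count),
        ms.BlockSpec("fc_task", "connectivity_vector", "task",
                     region_count=region_count),
        ms.BlockSpec("morph_gmv", "region_map", "struct",
                     n_features=n_features),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """N=150, signal only in fc_rest (R^2=0.5), no confound contamination."""
    spec = ms.CohortSpec(n_subjects=150, folds_hint=5,
                         blocks=small_block_specs(),
                         informative=("fc_rest",), signal_r2=0.5,
                         confound_r2=0.0)
    cohort, blocks, manifest = ms.generate_cohort(spec, seed=42)
    return spec, cohort, blocks, manifest


@pytest.fixture(scope="session")
def fitted_small_model():
    """A fitted 3-block model reused by stacking/saturation/model tests."""
    spec = ms.CohortSpec(n_subjects=150, folds_hint=5,
                         blocks=small_block_specs(),
                         informative=("fc_rest", "morph_gmv"),
                         signal_r2=0.5, confound_r2=0.1)
    model = ms.MultimodalStacking.from_synthetic(
        spec, seed=7, repeats=1, folds=5,
        enet_grid=FAST_ENET, rf_grid=FAST_RF)
    return model, model.fit(seed=0)
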