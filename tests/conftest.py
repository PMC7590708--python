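import numpy as np
import pytest

import syndromix as sx
from syndromix import fmm
from syndromix.family import GAUSSIAN_ITEM_MODELS


@pytest.fixture(scope="session")
def frele_cohort():
    """Mid-sized FRéLE-like four-class cohort (shared across tests)."""
    cfg = sx.default_config_frele(n_subjects=800, seed=20101)
    return sx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def frele_items(frele_cohort):
    return sx.encode_fmm_items(frele_cohort)


@pytest.fixture(scope="session")
def small_gaussian_params():
    """Well-scaled two-class one-factor model on standardized-like items."""
    K = 2
    return fmm.FMMParams(
        pi=[0.45, 0.55],
        intercepts=np.tile([0.0, 0.5, -0.3, 0.2, 0.1], (K, 1)),
        loadings=np.tile([1.0, 0.8, 0.6, 0.5, 0.4], (K, 1)),
        theta=np.tile([1.0, 1.2, 0.9, 1.1, 1.0], (K, 1)),
        alpha=[0.0, 1.2],
        psi=[0.5, 0.6],
        item_models=GAUSSIAN_ITEM_MODELS,
    )


@pytest.fixture(scope="session")
def mixed_item_params():
    """Two-class model with a censored item and a two-part item."""
    K = 2
    return fmm.FMMParams(
        pi=[0.4, 0.6],
        intercepts=np.tile([43.15, 0.0, 34.77, 44.28, 7.05], (K, 1)),
        loadings=np.tile([1.0, 4.1, 1.21, 2.17, -0.35], (K, 1)),
        theta=[[110.0, 900.0, 120.0, 160.0, 9.0],
               [100.0, 850.0, 110.0, 140.0, 9.0]],
        alpha=[0.0, 20.0],
        psi=[60.0, 45.0],
        occ_logit=[-0.5, -2.0],
        floor=15.0,
        item_models=("gaussian", "gaussian", "gaussian",
                     "censored-gaussian", "two-part-magnitude"),
    )
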