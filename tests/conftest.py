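import warnings

import numpy as np
import pandas as pd
import pytest

from fluidprint.core_io import FeatureMatrix
from fluidprint.synth import CohortConfig, PeakSpec, SurvivalConfig, default_config

# lifelines/sklearn emit benign small-sample warnings in several tests
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A reduced grid (7,200 points) keeps spectrum-level tests fast while
    preserving ~0.1 Da sampling, well below the 0.35 Da peak width."""
    cfg = default_config(seed=7, n_points=7200)
    return cfg


@pytest.fixture
def clean_config():
    """Noise-free variant: spectra are exact Gaussian mixtures."""
    return CohortConfig(
        n_per_group={"HC": 2, "ccRCC": 2},
        serum_panel=[
            PeakSpec(203.05, 100.0, width_sigma=0.1),
            PeakSpec(400.0, 80.0, width_sigma=0.3),
        ],
        urine_panel=[PeakSpec(150.0, 80.0, width_sigma=0.2)],
        n_points=7200,
        noise_sigma=0.0,
        baseline_amplitude=0.0,
        sample_scale_sigma=0.0,
        peak_scale_sigma=0.0,
        mz_jitter_sigma=0.0,
        survival=SurvivalConfig(baseline_hazard=0.0),
        seed=3,
    )


def make_matrix(values, sample_ids=None, labels=None, **kw):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    labels = labels or [f"S{100 + j}.0" for j in range(p)]
    return FeatureMatrix(
        pd.DataFrame(values, index=sample_ids, columns=labels), **kw
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
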