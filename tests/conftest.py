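import numpy as np
import pandas as pd
import pytest

from gcvoc.features import WaveletConfig
from gcvoc.preprocess import Chromatogram, PreprocessConfig
from gcvoc.simulate import CohortConfig, generate_cohort
from gcvoc.study import SelectorConfig, build_features


@pytest.fixture(scope="session")
def default_cohort():
    """Study-layout synthetic cohort with the default planted effects."""
    cfg = CohortConfig(seed=11)
    chroms, records = generate_cohort(cfg)
    return cfg, chroms, records


@pytest.fixture(scope="session")
def default_fm(default_cohort):
    cfg, chroms, records = default_cohort
    return build_features(chroms, records, PreprocessConfig(), WaveletConfig())


@pytest.fixture(scope="session")
def fast_selector_cfg():
    """Reduced-size selector settings used throughout the test suite."""
    return SelectorConfig(
        rf_trees=100, boruta_max_iter=25, rfe_subset_sizes=(5, 10, 25, 50), rfe_cv_folds=3
    )


@pytest.fixture(scope="session")
def tiny_cohort_cfg():
    """Miniature cohort (same structure, small counts) for orchestration tests."""
    return CohortConfig(
        seed=5,
        training_counts={"CD": 3, "UC": 3, "IBDU": 2},
        validation_counts={"CD": 2, "UC": 2, "IBDU": 2},
        n_followup={"training": 4, "validation": 3},
    )


def make_processed(values, sample_id="s", tick_s=0.5, batch=""):
    """Chromatogram carrying all stage flags, for feature-stage tests."""
    return Chromatogram(
        sample_id=sample_id,
        tick_s=tick_s,
        values=np.asarray(values, dtype=float),
        batch=batch,
        baseline_corrected=True,
        normalised=True,
        aligned=True,
    )


@pytest.fixture
def gaussian_trace():
    """Single Gaussian peak on a zero baseline, already 'processed'."""
    t = np.arange(0, 2400.5, 0.5)
    v = np.exp(-0.5 * ((t - 600.0) / 10.0) ** 2)
    return make_processed(v)
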