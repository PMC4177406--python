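"""Shared fixtures: small synthetic cohorts and their feature matrices.

The heavier cohort-level fixtures are session-scoped so the signal-recovery,
null-calibration and monotonicity tests share one set of featurized cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from noduletex.pipeline import RunConfig, assemble_datasets, featurize_cohort
from noduletex.synthetic import CohortSpec, generate_cohort

# Scaled-down study conditions used by the cohort-level tests: the 1:3
# benign:malignant patient ratio and per-patient ROI structure of the study,
# at a size a single CPU handles quickly (~420 ROIs at 64 px).
COHORT_KW = dict(
    n_benign_patients=14,
    n_malignant_patients=42,
    rois_per_patient=(7, 9),
    image_size=64,
    diameter_range_mm=(7.0, 30.0),
    noise_sd=1.0,
)


def make_cohort(contrast: float, seed: int = 1, **overrides):
    kw = {**COHORT_KW, **overrides}
    return generate_cohort(CohortSpec(texture_contrast=contrast, seed=seed, **kw))


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def featurized_cohorts(run_config):
    """Feature matrices + patient tables for contrasts 0, 0.3, 0.6, 1.0."""
    out = {}
    for contrast in (0.0, 0.3, 0.6, 1.0):
        cohort = make_cohort(contrast)
        features = featurize_cohort(cohort, run_config)
        out[contrast] = (features, cohort.patients)
    return out


@pytest.fixture(scope="session")
def cohort_datasets(featurized_cohorts):
    """Dataset variants (info/texture/both) per contrast level."""
    return {
        contrast: assemble_datasets(features, patients, which="all")
        for contrast, (features, patients) in featurized_cohorts.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
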