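"""Shared fixtures: a template geometry and a coarse seeded cohort.

The coarse resolution (16, 3, 1) matches the generator's labeling
resolution, so feature vectors and the ground-truth score live on the same
stress summary; heavier default-resolution checks live in the acceptance
tests only.
"""

import numpy as np
import pytest

from tavrisk import model as vbpr
from tavrisk.cohort import GeneratorParams, generate_cohort
from tavrisk.records import AorticRootGeometry

COARSE = (16, 3, 1)


@pytest.fixture(scope="session")
def geometry():
    return AorticRootGeometry(
        annulus_circumference=2.0 * np.pi * 12.0,
        wall_thickness=2.0,
        annulus_height=10.0,
        wall_stiffness=10.0,
        root_volume=9000.0,
        leaflet_volume=2000.0,
    )


@pytest.fixture(scope="session")
def coarse_resolution():
    return COARSE


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def cohort48(default_params):
    return generate_cohort(48, seed=1, params=default_params)


@pytest.fixture(scope="session")
def cohort48_features(cohort48):
    X, names = vbpr.assemble_matrix(cohort48, COARSE)
    y = np.array([r.avb_label for r in cohort48])
    return X, y, names


@pytest.fixture(scope="session")
def fitted_model(cohort48_features):
    X, y, names = cohort48_features
    return vbpr.fit(X, y, select_k=16, seed=0, names=names)
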