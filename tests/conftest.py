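"""Shared fixtures.

Heavy objects (the desk-scale synthetic study, its preprocessed feature
matrix and one double-CV run) are session-scoped so the end-to-end tests
share a single computation.  The study uses the default generator
conditions (3 balanced classes of 60, default peak catalogue, baseline,
noise, drift jitter and retention offsets) on a 36 x 300 grid.
"""

import numpy as np
import pytest

import imsnose as ims
from imsnose.synth import SynthConfig, generate_dataset

STUDY_GRID = dict(n_ret=36, n_drift=300)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_config() -> SynthConfig:
    return SynthConfig(**STUDY_GRID, seed=1)


@pytest.fixture(scope="session")
def study_data(study_config):
    """(dataset, ground truths) for the desk-scale study conditions."""
    return generate_dataset(study_config)


@pytest.fixture(scope="session")
def study_features(study_data):
    """Fully preprocessed and flattened study dataset."""
    ds, _ = study_data
    out = ims.run_pipeline(ds)
    return ims.flatten_dataset(out), list(out.class_names)


@pytest.fixture(scope="session")
def study_cv(study_features):
    """One double-CV run (10 repeats, 5 folds, LV grid 1..20) on the study."""
    fm, class_names = study_features
    return ims.double_cv(fm.X, fm.y, ims.CVConfig(seed=7),
                         class_names=class_names)


@pytest.fixture()
def tiny_map():
    """A small deterministic map for I/O and plumbing tests."""
    rng = np.random.default_rng(42)
    return ims.IMSMap(
        intensity=rng.normal(size=(5, 8)),
        drift_time=np.linspace(4.0, 9.0, 8),
        retention_time=np.linspace(0.0, 40.0, 5),
        sample_id="tiny",
        label="EVOO",
        meta={"operator": "synthetic"},
    )
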