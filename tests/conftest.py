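import numpy as np
import pytest

import spinsense as ss
from spinsense.io import annotations_to_sample_mask
from spinsense.segmentation import WindowingParams


@pytest.fixture(scope="session")
def small_cfg():
    """A compact noisy study: 3 dogs, imbalanced counts, 2 min each."""
    return ss.SimulationConfig(
        n_subjects=3,
        events_per_subject=(8, 5, 3),
        background_minutes_per_subject=2.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return ss.simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_segments(small_study):
    """Windows of the small study, pooled, with per-subject provenance."""
    params = WindowingParams()
    out = {}
    for rec, ann in small_study:
        mask = annotations_to_sample_mask(rec, ann)
        out[rec.subject_id] = ss.segment_stream(rec, mask, params)
    return out


@pytest.fixture(scope="session")
def separable_study_scale():
    """Zero-noise fixture at full corpus scale: training folds cover the
    whole duration range, so every family can be perfect."""
    return ss.simulate_study(ss.separable_config(seed=7))


@pytest.fixture(scope="session")
def study_scale_cfg():
    """The full emulated corpus: 6 dogs, counts 74/23/16/10/9/3."""
    return ss.SimulationConfig(seed=20)


@pytest.fixture(scope="session")
def study_scale(study_scale_cfg):
    return ss.simulate_study(study_scale_cfg)


@pytest.fixture(scope="session")
def rf_lodo_report(study_scale):
    return ss.run_protocol(
        study_scale, ss.SplitProtocol(kind="lodo_full_cv", seed=20), model="random_forest"
    )


@pytest.fixture(scope="session")
def heuristic_lodo_report(study_scale):
    return ss.run_protocol(
        study_scale, ss.SplitProtocol(kind="lodo_full_cv", seed=20), model="heuristic"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
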