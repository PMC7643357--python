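"""Shared fixtures: synthetic data specs and the trained detector.

The trained detector fixture runs the full small-scale training once
per session (a few minutes on one CPU) and is shared by every test
that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

import ssedetect as sd
from ssedetect import detector as dt

#: study conditions for the learned-detector evaluation: training-set
#: size, held-out size, and seeds, fixed once
TRAIN_N = 300
HELDOUT_N = 50
TRAIN_SEED = 11
HELDOUT_SEED = 99


@pytest.fixture(scope="session")
def default_spec() -> sd.SyntheticSpec:
    return sd.SyntheticSpec(seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def noise_free_spec() -> sd.SyntheticSpec:
    return sd.SyntheticSpec(seed=7, p_bg_rate=0.0, p_fg=(1.0, 0.0))


@pytest.fixture(scope="session")
def heldout_dataset() -> list[sd.SyntheticSample]:
    return sd.make_dataset(HELDOUT_N, sd.SyntheticSpec(seed=HELDOUT_SEED))


@pytest.fixture(scope="session")
def trained_model(default_spec) -> dt.DetectorModel:
    """Detector trained on the default synthetic conditions."""
    dataset = sd.make_dataset(TRAIN_N, default_spec)
    config = dt.DetectorConfig(train=dt.TrainConfig(epochs=16, seed=0))
    return dt.train(dataset, config)


def pooled_pipeline_report(samples, detect_fn, selection=None):
    """Run detect -> filter -> select -> match over samples; pooled report."""
    selection = selection or sd.SelectionConfig()
    report = None
    for sample in samples:
        selected = sd.greedy_select(
            sd.filter_candidates(detect_fn(sample.map), selection)
        )
        r = sd.match_detections(selected, sample.truth)
        report = r if report is None else report.merge(r)
    return report
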