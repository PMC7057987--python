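"""Shared fixtures: small synthetic datasets and one slim trained model.

Training fixtures use a slim 2-conv-2-fully variant at 64x64 so the whole
suite stays desk-scale; the full default 4-conv-3-fully architecture is
exercised in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import dsdmonitor as dm


def make_labeled_frames(n: int, shape=(64, 64), seed: int = 42):
    return dm.generate_labeled_frames(n, shape=shape, seed=seed)


SLIM_NET = dm.NetworkSpec(conv_filters=(8, 16), fc_widths=(32, 2))


@pytest.fixture(scope="session")
def labeled_frames():
    return make_labeled_frames(320)


@pytest.fixture(scope="session")
def trained(labeled_frames):
    """A slim classifier trained once and shared across the suite."""
    frames, labels = labeled_frames
    model = dm.FrameClassifier(
        frames,
        labels,
        network=SLIM_NET,
        train_config=dm.TrainConfig(epochs=5, learning_rate=1e-3, seed=0),
    )
    return model.fit(holdout_fraction=0.2)
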