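"""Shared fixtures.

The trained-model fixture is session-scoped: both classifiers are trained
from scratch on synthetic data exactly once and reused by every test that
needs them (end-to-end recovery, ablations, robustness).
"""

from __future__ import annotations

import numpy as np
import pytest

import vesiclepick as vp
from vesiclepick.pipeline import train_models

#: Held-out evaluation condition: quarter-size micrographs at the same
#: vesicle density as the 512 px generator default.
EVAL_CONFIG = vp.SynthConfig(
    image_height_px=256, image_width_px=256, n_vesicles=12, n_distractors=4
)


@pytest.fixture(scope="session")
def trained_models():
    """(model_first, model_refine, info) trained on the synthetic defaults."""
    return train_models(seed=0)


@pytest.fixture(scope="session")
def eval_images():
    """Ten held-out seeded micrographs with ground truth."""
    return [
        vp.generate_micrograph(EVAL_CONFIG.with_(seed=9000 + i)) for i in range(10)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
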