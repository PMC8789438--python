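"""Shared fixtures: all test data is generated, nothing is stored on disk."""

from __future__ import annotations

import numpy as np
import pytest

from cobci.benchmark import make_benchmark
from cobci.synthetic import SimConfig, simulate_group


@pytest.fixture(scope="session")
def tiny_group():
    """A small, clean 3-subject synchronized group (no artifacts)."""
    cfg = SimConfig(
        n_subjects=3,
        n_target_videos=6,
        n_nontarget_videos=6,
        video_length_range=(4.0, 6.0),
        noise_sd=3.0,
        artifact_rate=0.0,
        seed=11,
    )
    return cfg, *simulate_group(cfg)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Smoke-scale end-to-end benchmark: source domain + aligned group."""
    return make_benchmark("tiny", 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
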