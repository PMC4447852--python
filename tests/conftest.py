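"""Shared fixtures: rendered scenes, scenery models, segmented frames.

Everything is generated programmatically at session scope; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from cowtof.calib import compute_scenery_info
from cowtof.config import PipelineConfig
from cowtof.segment import sort_frame
from cowtof.tofsim import (
    SceneConfig,
    fv_shape,
    hf_shape,
    render_cow_frame,
    render_empty_frame,
)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def scene() -> SceneConfig:
    """Noise-free default scene."""
    return SceneConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def scene_sym() -> SceneConfig:
    """Noise-free scene with walls symmetric about the image centre, for
    mirror-symmetry checks."""
    return SceneConfig(noise_sigma=0.0, wall_left_col=3, wall_right_col=172)


@pytest.fixture(scope="session")
def scene_noisy() -> SceneConfig:
    return SceneConfig(noise_sigma=1.0, seed=11)


@pytest.fixture(scope="session")
def scenery(scene, config):
    frames = [render_empty_frame(scene) for _ in range(20)]
    return compute_scenery_info(frames, config.calib)


@pytest.fixture(scope="session")
def scenery_sym(scene_sym, config):
    frames = [render_empty_frame(scene_sym) for _ in range(20)]
    return compute_scenery_info(frames, config.calib)


@pytest.fixture(scope="session")
def scenery_noisy(scene_noisy, config):
    rng = np.random.default_rng(77)
    frames = [render_empty_frame(scene_noisy, rng) for _ in range(30)]
    return compute_scenery_info(frames, config.calib)


@pytest.fixture(scope="session")
def hf_render(scene):
    return render_cow_frame(scene, hf_shape())


@pytest.fixture(scope="session")
def fv_render(scene):
    return render_cow_frame(scene, fv_shape())


@pytest.fixture(scope="session")
def hf_seg(hf_render, scenery, config):
    frame, _ = hf_render
    seg = sort_frame(frame, scenery, config.segment)
    assert seg.keep_decision
    return seg


@pytest.fixture(scope="session")
def fv_seg(fv_render, scenery, config):
    frame, _ = fv_render
    seg = sort_frame(frame, scenery, config.segment)
    assert seg.keep_decision
    return seg
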