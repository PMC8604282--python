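"""Shared fixtures: small synthetic scenes and derived rasters."""

from __future__ import annotations

import numpy as np
import pytest

import weedspot as ws


@pytest.fixture(scope="session")
def small_scene() -> ws.ScenePair:
    """One 96x96 scene with both weed classes, moderate noise and holes."""
    cfg = ws.SceneConfig(image_size=(96, 96), n_grass=2, n_broadleaf=1, seed=42)
    return ws.generate_scene(cfg)


@pytest.fixture(scope="session")
def filled_depth(small_scene) -> ws.DepthRaster:
    return ws.fill_holes(small_scene.depth)


@pytest.fixture(scope="session")
def small_pha(small_scene, filled_depth) -> ws.PHAImage:
    return ws.recode_to_pha(filled_depth, small_scene.camera)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 64x64 scene pairs prepared as (rgb, pha, annotations) triples."""
    pairs = []
    anns = {}
    for s in range(8):
        cfg = ws.SceneConfig(image_size=(64, 64), n_grass=1, n_broadleaf=1, seed=100 + s)
        pair = ws.generate_scene(cfg)
        pha = ws.recode_to_pha(ws.fill_holes(pair.depth), pair.camera)
        pairs.append((pair.rgb, pha.quantized, pair.annotations))
        anns[str(s)] = pair.annotations
    return pairs, anns


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
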