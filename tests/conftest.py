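"""Shared fixtures: rendered scenes and matched disparity maps.

Rendering and semi-global matching are the expensive steps, so scenes used by
several tests are session-scoped.  All randomness is seeded; every fixture is
generated programmatically at test time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import canostereo as cs
from canostereo import camera_geometry as cg
from canostereo import stereo_matcher as sm


@dataclass
class RenderedScene:
    scene: cs.SceneSpec
    pair: cg.ImagePair
    true_depth: cg.DepthMap
    true_labels: np.ndarray
    dmap_raw: sm.DisparityMap
    dmap_filled: sm.DisparityMap

    @property
    def rig(self):
        return self.scene.rig


def _render_and_match(scene: cs.SceneSpec, disparity_range: int = 64) -> RenderedScene:
    pair, depth, labels = cs.render_views(scene)
    raw = cs.match_semiglobal(pair, sm.MatcherConfig(disparity_range=disparity_range))
    return RenderedScene(scene, pair, depth, labels, raw, cs.fill_disparity(raw))


@pytest.fixture(scope="session")
def sim_rig():
    return cs.SIM_RIG


@pytest.fixture(scope="session")
def sparse_canopy():
    """Sparse non-overlapping canopy rendered and matched (seed 5)."""
    return _render_and_match(cs.preset_scene("sparse-canopy", seed=5))


@pytest.fixture(scope="session")
def sparse_canopy_alt():
    """Second sparse canopy (seed 11) to guard against single-draw luck."""
    return _render_and_match(cs.preset_scene("sparse-canopy", seed=11))


@pytest.fixture(scope="session")
def spiked_canopy():
    """Dense flowering-stage canopy with protruding ears (seed 7)."""
    return _render_and_match(cs.preset_scene("spiked-canopy", seed=7),
                             disparity_range=80)


@pytest.fixture(scope="session")
def dense_canopy():
    """Overlapping dense canopy (seed 3) for the occlusion regime."""
    return _render_and_match(cs.preset_scene("dense-canopy", seed=3))


@pytest.fixture(scope="session")
def ground_only():
    """Fronto-parallel textured ground at exactly 1 m (seed 3)."""
    scene = cs.SceneSpec(rig=cs.SIM_RIG, ground_depth=1.0, leaves=[], seed=3)
    return _render_and_match(scene)


@pytest.fixture(scope="session")
def sparse_model(sparse_canopy):
    """Two-class SVM trained on pixels sampled from the sparse render."""
    from canostereo import segmentation as seg
    from canostereo.synthetic_scene import training_set_from_render

    ts = training_set_from_render(np.asarray(sparse_canopy.pair.left, float),
                                  sparse_canopy.true_labels, n=8000, seed=1)
    return seg.train_classifier(ts, n_classes=2)
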