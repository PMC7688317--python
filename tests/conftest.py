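import numpy as np
import pytest

import musemargin as mm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def three_class_spec(seed: int, width: int = 768, height: int = 256) -> mm.PhantomSpec:
    """Small three-strip phantom: tumor | fibrous stroma | adipose."""
    regions = mm.vertical_strip_layout(width, height, ["IDC", "stroma", "adipose"])
    return mm.PhantomSpec(width_px=width, height_px=height, regions=regions, seed=seed)


@pytest.fixture
def small_phantom():
    """(scene, truth) of a small three-class phantom, fixed seed."""
    scene, truth = mm.generate_scene(three_class_spec(seed=3))
    return scene, truth


@pytest.fixture
def fast_config():
    """Pipeline config scaled for test runtime: small tiles and overlaps,
    64-px small patches merged 4x4."""
    return mm.PipelineConfig(
        scene_width_px=560,
        scene_height_px=420,
        tile_w_px=240,
        tile_h_px=200,
        overlap_x_um=120.0,
        overlap_y_um=100.0,
        patch_px=64,
        large_block=4,
        zero_limit=8,
        seed=11,
    )
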