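import numpy as np
import pytest

from segadapt.benchmark import (
    ObjectSpec,
    SceneSpec,
    default_scene,
    generate_series,
    render_scene,
)


@pytest.fixture
def two_level_scene():
    """Clean 64x64 scene: two well-separated bright objects (0.8) on a dark
    background (0.2); perfectly separable by any threshold in (0.2, 0.8)."""
    spec = SceneSpec(
        height=64,
        width=64,
        background=0.2,
        objects=(
            ObjectSpec(1, "rectangle", (11.0, 11.0), 0.8, (20.0, 20.0)),
            ObjectSpec(1, "disk", (6.0,), 0.8, (44.0, 44.0)),
        ),
    )
    image, gt = render_scene(spec)
    return spec, image, gt


@pytest.fixture
def tiny_scene():
    """48x48 scene with one rectangle and one disk, used for fast searches."""
    spec = SceneSpec(
        height=48,
        width=48,
        background=0.15,
        objects=(
            ObjectSpec(1, "rectangle", (9.0, 9.0), 0.85, (14.0, 14.0)),
            ObjectSpec(2, "disk", (5.0,), 0.7, (33.0, 33.0)),
        ),
        seed=7,
    )
    image, gt = render_scene(spec)
    return spec, image, gt


@pytest.fixture
def tiny_series(tiny_scene):
    spec, _, _ = tiny_scene
    return generate_series(spec, B=3, N=6, sigma_max=0.1, shading_max=0.4)


@pytest.fixture(scope="session")
def default_series():
    """Full-scale 13-level series of the built-in scene (seed 1)."""
    return generate_series(default_scene(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
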