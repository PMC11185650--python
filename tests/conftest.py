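import numpy as np
import pytest

import pixikit as pk
from pixikit.fixtures import Scene, SceneObject, SceneSpec, generate_shape_scene


@pytest.fixture
def scene() -> Scene:
    """A disk, a rectangle, and a plus sign on a 48x48 canvas, noise-free."""
    spec = SceneSpec(
        extent=(48, 48),
        objects=(
            SceneObject("disk", (12, 12, 6)),
            SceneObject("rectangle", (28, 8, 10, 6)),
            SceneObject("plus", (30, 34, 9, 3)),
        ),
        background=0.1,
        noise_sigma=0.0,
    )
    return generate_shape_scene(spec, "img1")


@pytest.fixture
def scene_project(scene) -> pk.Project:
    """Committed project holding the scene image and its labeled objects."""
    project = pk.create_project("demo")
    project.add_images([scene.image])
    project.register_kind("object")
    cat = project.register_category("object", "blob", (0, 255, 0))
    for ann in scene.annotations:
        ann.category_id = cat.id
    project.add_annotations(scene.annotations)
    return project.commit()


def random_mask(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """Random nonempty blobby mask (thresholded smooth noise)."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    noise = rng.random((h, w))
    from scipy import ndimage

    smooth = ndimage.uniform_filter(noise, size=5)
    mask = smooth > np.quantile(smooth, 0.6)
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return mask
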