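import numpy as np
import pytest

from nucleomorph.synth import LabeledScene


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    side = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def scene_from_mask(
    mask: np.ndarray,
    value: int | tuple[int, int, int] = 100,
    pixel_size_um: float = 0.25,
    image: np.ndarray | None = None,
) -> LabeledScene:
    """Single-nucleus scene with a flat (or supplied) image."""
    if image is None:
        image = np.zeros(mask.shape + (3,), dtype=np.uint8)
        image[:] = np.asarray(value, dtype=np.uint8)
    return LabeledScene(
        image=image,
        labels=mask.astype(np.uint16),
        pixel_size_um=pixel_size_um,
    )


@pytest.fixture
def disk30_scene() -> LabeledScene:
    return scene_from_mask(disk_mask(30))


@pytest.fixture
def disk10_scene() -> LabeledScene:
    return scene_from_mask(disk_mask(10))
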