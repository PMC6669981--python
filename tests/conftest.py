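import numpy as np
import pytest

from plantpheno import imaging
from plantpheno.synthdata import PlantSpec, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def simple_scene():
    """Two plants at known chlorophyll under a neutral illuminant."""
    return SceneSpec(
        plants=(
            PlantSpec("p1", height_cm=6.0, plumpness=0.2, chlorophyll=0.5),
            PlantSpec("p2", height_cm=4.0, plumpness=0.7, chlorophyll=0.25),
        ),
        pixels_per_cm=15.0,
    )


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    rr, cc = np.mgrid[:n, :n]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def square_mask(side: int, pad: int = 3) -> np.ndarray:
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def image_from_mask(mask: np.ndarray, fg=0.7, bg=0.05) -> imaging.RGBImage:
    px = np.full(mask.shape + (3,), bg, dtype=float)
    px[mask] = fg
    return imaging.RGBImage(pixels=px, provenance="synthetic:test")
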