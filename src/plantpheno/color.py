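"""White-reference color normalization and the green/red chlorophyll proxy.

A white reference (the ruler strip in each photograph) is sampled, its cast
is estimated with the grey-world method, and plant ROI colors are mapped to
the appearance they would have under a neutral (D65) illuminant via a
Bradford chromatic adaptation in XYZ space.  The corrected mean green/red
ratio of an ROI is the chlorophyll proxy: paler (chlorotic) tissue has a
lower G/R.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import RGBImage, ROIStats

logger = logging.getLogger(__name__)

__all__ = [
    "WhiteReference",
    "ChromaticAdaptation",
    "ColorIndex",
    "sample_white",
    "grey_world_gains",
    "srgb_linearize",
    "srgb_delinearize",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "bradford_matrix",
    "correct_roi_color",
    "D65_WHITE_XYZ",
    "BRADFORD",
]

# sRGB (IEC 61966-2-1) primaries with a D65 white point.
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_RGB_MATRIX = np.linalg.inv(RGB_TO_XYZ_MATRIX)

#: XYZ of the sRGB white point, i.e. the matrix applied to (1, 1, 1).
D65_WHITE_XYZ = RGB_TO_XYZ_MATRIX @ np.ones(3)

# Bradford cone-response matrix (Lam/BFD), the canonical constants.
BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
BRADFORD_INV = np.linalg.inv(BRADFORD)


@dataclass(frozen=True)
class WhiteReference:
    """Mean raw RGB of an achromatic reference region (e.g. the ruler)."""

    mean_rgb_raw: np.ndarray
    region: tuple[int, int, int, int]  # (row0, col0, height, width)
    n_pixels: int

    def __post_init__(self):
        rgb = np.asarray(self.mean_rgb_raw, dtype=float)
        object.__setattr__(self, "mean_rgb_raw", rgb)
        if rgb.shape != (3,):
            raise ValueError("mean_rgb_raw must be a 3-vector")
        if np.any(rgb <= 0):
            raise ValueError("white reference has a zero channel; gains undefined")
        if self.n_pixels < 100:
            raise ValueError(
                f"white reference region has only {self.n_pixels} pixels (need >= 100)"
            )


@dataclass(frozen=True)
class ChromaticAdaptation:
    """A linear XYZ->XYZ map taking one white point onto another."""

    source_white_xyz: np.ndarray
    dest_white_xyz: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        src = np.asarray(self.source_white_xyz, dtype=float)
        dst = np.asarray(self.dest_white_xyz, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "source_white_xyz", src)
        object.__setattr__(self, "dest_white_xyz", dst)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m @ src, dst, atol=1e-10):
            raise ValueError("adaptation matrix does not map source white to dest white")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.matrix.T


@dataclass(frozen=True)
class ColorIndex:
    """Corrected mean color of one ROI and its green/red chlorophyll proxy."""

    roi_id: str
    mean_rgb_raw: np.ndarray
    mean_rgb_corrected: np.ndarray
    gr_ratio: float
    rg_ratio: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.gr_ratio <= 0:
            raise ValueError("gr_ratio must be positive")
        if self.rg_ratio is None:
            object.__setattr__(self, "rg_ratio", 1.0 / self.gr_ratio)


def sample_white(image: RGBImage, region: tuple[int, int, int, int]) -> WhiteReference:
    """Mean per-channel value over a rectangular white-reference region.

    ``region`` is (row0, col0, height, width).  Raises if the region means
    are clipped dark (<= 0.01) or saturated (>= 0.995) — a blown-out
    reference carries no illuminant information.
    """
    r0, c0, h, w = region
    px = image.pixels
    if r0 < 0 or c0 < 0 or r0 + h > px.shape[0] or c0 + w > px.shape[1]:
        raise ValueError("white-reference region outside image bounds")
    patch = px[r0 : r0 + h, c0 : c0 + w]
    mean = patch.reshape(-1, 3).mean(axis=0)
    if np.any(mean <= 0.01) or np.any(mean >= 0.995):
        raise ValueError(
            f"white reference mean {np.round(mean, 4)} is clipped or saturated; "
            "choose an unclipped reference region"
        )
    return WhiteReference(mean_rgb_raw=mean, region=region, n_pixels=h * w)


def grey_world_gains(ref: WhiteReference) -> np.ndarray:
    """Per-channel gains equalizing the reference channels (grey-world).

    g_c = mean(ref) / ref_c, so that gains * ref is achromatic with every
    channel equal to the reference's channel average.
    """
    m = ref.mean_rgb_raw.mean()
    return m / ref.mean_rgb_raw


def srgb_linearize(v: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded [0,1] -> linear light."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_delinearize(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_linearize` (linear light -> encoded)."""
    v = np.asarray(v, dtype=float)
    v = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def rgb_to_xyz(rgb: np.ndarray, linearize: bool = True) -> np.ndarray:
    """Map sRGB values (last axis = 3) to CIE XYZ under D65 primaries."""
    rgb = np.asarray(rgb, dtype=float)
    lin = srgb_linearize(rgb) if linearize else rgb
    return lin @ RGB_TO_XYZ_MATRIX.T


def xyz_to_rgb(xyz: np.ndarray, delinearize: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_xyz`; out-of-gamut results are clipped."""
    xyz = np.asarray(xyz, dtype=float)
    lin = xyz @ XYZ_TO_RGB_MATRIX.T
    out = srgb_delinearize(lin) if delinearize else lin
    if np.any(out < -1e-12) or np.any(out > 1 + 1e-12):
        logger.info("xyz_to_rgb: out-of-gamut result clipped to [0, 1]")
    return np.clip(out, 0.0, 1.0)


def bradford_matrix(
    source_white_xyz: np.ndarray, dest_white_xyz: np.ndarray
) -> ChromaticAdaptation:
    """Bradford chromatic-adaptation matrix between two white points.

    M = B^-1 diag(rho_d/rho_s, gamma_d/gamma_s, beta_d/beta_s) B, where B is
    the Bradford cone matrix and (rho, gamma, beta) = B @ white.  M maps the
    source white exactly onto the destination white.
    """
    src = np.asarray(source_white_xyz, dtype=float)
    dst = np.asarray(dest_white_xyz, dtype=float)
    if np.any(src <= 0) or np.any(dst <= 0):
        raise ValueError("white points must be strictly positive")
    cone_src = BRADFORD @ src
    cone_dst = BRADFORD @ dst
    if np.any(cone_src <= 0) or np.any(cone_dst <= 0):
        raise ValueError("non-positive cone response; whites are not plausible illuminants")
    m = BRADFORD_INV @ np.diag(cone_dst / cone_src) @ BRADFORD
    return ChromaticAdaptation(source_white_xyz=src, dest_white_xyz=dst, matrix=m)


def correct_roi_color(
    image: RGBImage,
    roi: ROIStats,
    ref: WhiteReference,
    dest_white: np.ndarray | None = None,
    *,
    linearize: bool = True,
    grey_world: bool = True,
) -> ColorIndex:
    """White-reference corrected mean color and G/R ratio of one ROI.

    Pipeline: mean raw RGB over the ROI pixels -> optional grey-world
    pre-gain estimated from the white reference -> RGB to XYZ -> Bradford
    adaptation from the (pre-gained) reference white to ``dest_white``
    (default D65) -> XYZ back to RGB -> G/R of the corrected mean.

    ``linearize`` selects the sRGB transfer function on both legs; disable it
    for images that are already linear light (e.g. synthetic scenes), which
    makes the whole pipeline linear so that correcting the ROI mean equals
    the mean of corrected pixels.
    """
    dest = D65_WHITE_XYZ if dest_white is None else np.asarray(dest_white, dtype=float)
    rows, cols = roi.pixel_indices
    px = image.pixels[rows, cols]  # (n, 3)
    mean_raw = px.mean(axis=0)

    gains = grey_world_gains(ref) if grey_world else np.ones(3)
    ref_rgb = ref.mean_rgb_raw * gains
    roi_rgb = mean_raw * gains

    src_white = rgb_to_xyz(ref_rgb, linearize=linearize)
    adapt = bradford_matrix(src_white, dest)
    corrected = xyz_to_rgb(adapt.apply(rgb_to_xyz(roi_rgb, linearize=linearize)),
                           delinearize=linearize)
    if corrected[0] < 1e-6:
        raise ValueError("corrected red channel ~ 0; green/red ratio undefined")
    gr = float(corrected[1] / corrected[0])
    return ColorIndex(
        roi_id=roi.roi_id,
        mean_rgb_raw=mean_raw,
        mean_rgb_corrected=corrected,
        gr_ratio=gr,
    )
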