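"""Segmentation, color-space conversion and ROI morphometrics."""

import numpy as np
import pytest

from plantpheno import imaging
from plantpheno.imaging import (
    RGBImage,
    SegmentationMask,
    circularity,
    convert_space,
    extract_rois,
    otsu_threshold,
    perimeter_area_ratio,
    refine_mask,
    threshold,
)
from plantpheno.synthdata import PlantSpec, SceneSpec, render_scene

from conftest import disk_mask, image_from_mask, square_mask


# ---------------------------------------------------------------------------
# color-space conversion


def _hsi_scalar(r, g, b):
    """Independent per-pixel HSI reference (scalar arithmetic)."""
    i = (r + g + b) / 3.0
    s = 0.0 if i == 0 else 1.0 - min(r, g, b) / i
    mx, mn = max(r, g, b), min(r, g, b)
    if mx == mn:
        h = 0.0
    elif mx == r:
        h = ((g - b) / (mx - mn)) % 6 / 6.0
    elif mx == g:
        h = ((b - r) / (mx - mn) + 2) / 6.0
    else:
        h = ((r - g) / (mx - mn) + 4) / 6.0
    return h, s, i


def _cmyk_scalar(r, g, b):
    k = 1.0 - max(r, g, b)
    if k >= 1.0:
        return 0.0, 0.0, 0.0, 1.0
    return (1 - r - k) / (1 - k), (1 - g - k) / (1 - k), (1 - b - k) / (1 - k), k


def test_convert_space_matches_scalar_oracle(rng):
    px = rng.random((7, 5, 3))
    image = RGBImage(pixels=px)
    hsi = convert_space(image, "HSI")
    cmyk = convert_space(image, "CMYK")
    hsv = convert_space(image, "HSV")
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            r, g, b = px[i, j]
            h, s, inten = _hsi_scalar(r, g, b)
            assert hsi["H"][i, j] == pytest.approx(h, abs=1e-12)
            assert hsi["S"][i, j] == pytest.approx(s, abs=1e-12)
            assert hsi["I"][i, j] == pytest.approx(inten, abs=1e-12)
            c, m, y, k = _cmyk_scalar(r, g, b)
            for name, val in zip("CMYK", (c, m, y, k)):
                assert cmyk[name][i, j] == pytest.approx(val, abs=1e-12)
            assert hsv["V"][i, j] == pytest.approx(max(r, g, b), abs=1e-12)


def test_convert_space_degenerate_pixels():
    grey = RGBImage(pixels=np.full((2, 2, 3), 0.5))
    hsi = convert_space(grey, "HSI")
    assert np.allclose(hsi["S"], 0.0) and np.allclose(hsi["I"], 0.5)
    black = RGBImage(pixels=np.zeros((2, 2, 3)))
    cmyk = convert_space(black, "CMYK")
    assert np.allclose(cmyk["K"], 1.0)
    for ch in "CMY":
        assert np.allclose(cmyk[ch], 0.0)


def test_convert_space_unknown_space():
    with pytest.raises(ValueError, match="unknown color space"):
        convert_space(RGBImage(pixels=np.zeros((2, 2, 3))), "LAB")


# ---------------------------------------------------------------------------
# thresholding


def _between_class_variance(values, thresh, nbins=256):
    """Unnormalized between-class variance of the histogram split at thresh."""
    values = np.asarray(values, float).ravel()
    hist, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    lo = centers < thresh
    w0, w1 = hist[lo].sum(), hist[~lo].sum()
    if w0 == 0 or w1 == 0:
        return -np.inf
    mu0 = (hist[lo] * centers[lo]).sum() / w0
    mu1 = (hist[~lo] * centers[~lo]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def _otsu_exhaustive(values, nbins=256):
    """Brute-force search over all histogram cuts (independent oracle).

    Returns (best edge, best variance).  Cuts through runs of empty bins tie
    exactly in real arithmetic, so callers should compare achieved variance,
    not the edge itself.
    """
    values = np.asarray(values, float).ravel()
    hist, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_edge = -np.inf, None
    for cut in range(nbins - 1):
        w0 = hist[: cut + 1].sum()
        w1 = hist[cut + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: cut + 1] * centers[: cut + 1]).sum() / w0
        mu1 = (hist[cut + 1 :] * centers[cut + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_edge = var, edges[cut + 1]
    return best_edge, best_var


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_otsu_achieves_exhaustive_optimum(seed):
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [rng.normal(0.25, 0.05, 400), rng.normal(0.7, 0.08, 300)]
    ).clip(0, 1)
    thresh = otsu_threshold(values)
    _, best_var = _otsu_exhaustive(values)
    assert _between_class_variance(values, thresh) == pytest.approx(best_var, rel=1e-9)
    # threshold separates the two modes
    assert 0.3 < thresh < 0.65


def test_otsu_exact_edge_on_gapless_histogram():
    # overlapping dense modes: every bin populated, so the maximizer is unique
    rng = np.random.default_rng(7)
    values = np.concatenate(
        [rng.uniform(0.0, 0.55, 4000), rng.uniform(0.45, 1.0, 3000)]
    )
    edge, _ = _otsu_exhaustive(values)
    assert otsu_threshold(values) == pytest.approx(edge, abs=1e-12)


def test_otsu_constant_channel_errors():
    with pytest.raises(ValueError, match="fixed"):
        otsu_threshold(np.full(100, 0.4))


def test_threshold_bimodal_channel_recovers_silhouette():
    mask_true = disk_mask(12)
    image = image_from_mask(mask_true, fg=0.7, bg=0.05)
    stack = convert_space(image, "RGB")
    otsu = threshold(stack, "R", "otsu")
    fixed = threshold(stack, "R", ("fixed", 0.4, 1.0))
    assert np.array_equal(otsu.mask, mask_true)
    assert np.array_equal(fixed.mask, mask_true)


def test_threshold_unknown_channel():
    image = image_from_mask(disk_mask(5))
    with pytest.raises(KeyError):
        threshold(convert_space(image, "RGB"), "Q", "otsu")


# ---------------------------------------------------------------------------
# mask refinement


def test_refine_removes_speckles_and_is_idempotent(rng):
    mask = square_mask(30, pad=10)
    speckled = mask.copy()
    for r, c in [(2, 2), (3, 40), (45, 5)]:
        speckled[r : r + 2, c] = True  # 2-px speckles
    image = image_from_mask(speckled)
    m = SegmentationMask(mask=speckled)
    refined = refine_mask(m, image, min_area_px=10)
    assert np.array_equal(refined.mask, mask)
    again = refine_mask(refined, image, min_area_px=10)
    assert np.array_equal(again.mask, refined.mask)


def test_refine_bg_threshold_zero_is_size_filter_only():
    mask = square_mask(20)
    image = image_from_mask(mask)
    out = refine_mask(SegmentationMask(mask=mask), image, bg_threshold=0.0, min_area_px=0)
    assert np.array_equal(out.mask, mask)


def test_refine_drops_dark_pixels():
    mask = square_mask(20, pad=4)
    image = image_from_mask(mask, fg=0.7, bg=0.02)
    dilated = mask.copy()
    dilated[3, 4:10] = True  # background row wrongly captured
    out = refine_mask(SegmentationMask(mask=dilated), image, bg_threshold=0.1)
    assert np.array_equal(out.mask, mask)


# ---------------------------------------------------------------------------
# ROI extraction and shape metrics


def test_extract_square_geometry():
    rois = extract_rois(SegmentationMask(mask=square_mask(100)))
    assert len(rois) == 1
    roi = rois[0]
    assert roi.area_px2 == 10000
    assert roi.bbox_height_px == 100
    assert roi.perimeter_px == pytest.approx(400, abs=2)
    assert perimeter_area_ratio(roi) == pytest.approx(4 / 100, rel=0.01)


def test_extract_disk_matches_analytic_circle():
    rois = extract_rois(SegmentationMask(mask=disk_mask(50)))
    roi = rois[0]
    assert roi.area_px2 == pytest.approx(np.pi * 50**2, rel=0.01)
    assert roi.perimeter_px == pytest.approx(2 * np.pi * 50, rel=0.03)
    assert perimeter_area_ratio(roi) == pytest.approx(2 / 50, rel=0.04)
    assert circularity(roi) == pytest.approx(1.0, rel=0.05)


def test_extract_orders_left_to_right():
    m = np.zeros((30, 60), dtype=bool)
    m[5:15, 40:55] = True  # right blob (bigger)
    m[10:18, 5:12] = True  # left blob
    rois = extract_rois(SegmentationMask(mask=m))
    assert len(rois) == 2
    assert rois[0].centroid[1] < rois[1].centroid[1]
    assert rois[0].area_px2 == 8 * 7


def test_extract_empty_mask_returns_empty_list():
    assert extract_rois(SegmentationMask(mask=np.zeros((5, 5), bool))) == []


def test_eight_connectivity_keeps_diagonal_stems():
    m = np.zeros((6, 6), dtype=bool)
    for i in range(5):
        m[i, i] = True
    rois = extract_rois(SegmentationMask(mask=m, connectivity=8))
    assert len(rois) == 1
    rois4 = extract_rois(SegmentationMask(mask=m, connectivity=4))
    assert len(rois4) == 5


@pytest.mark.parametrize(
    "mask",
    [square_mask(40), disk_mask(25), square_mask(8), disk_mask(6)],
    ids=["square40", "disk25", "square8", "disk6"],
)
def test_isoperimetric_inequality(mask):
    roi = extract_rois(SegmentationMask(mask=mask))[0]
    assert roi.perimeter_px**2 >= 4 * np.pi * roi.area_px2 * 0.95


def test_isoperimetric_on_rendered_plants():
    for seed in range(5):
        scene = SceneSpec(
            plants=(PlantSpec(f"p{seed}", 5.0, plumpness=seed / 5.0),), pixels_per_cm=14.0
        )
        _, truths = render_scene(scene, seed=seed)
        t = truths[0]
        assert t.perimeter_px**2 >= 4 * np.pi * t.area_px2 * 0.95


def test_plumper_plants_have_lower_perimeter_area_ratio():
    """At comparable area, a plump plant is more compact than a gracile one."""
    gracile = SceneSpec(
        plants=(PlantSpec("g", height_cm=6.0, plumpness=0.0),), pixels_per_cm=15.0
    )
    plump = SceneSpec(
        plants=(PlantSpec("p", height_cm=4.0, plumpness=0.8),), pixels_per_cm=15.0
    )
    _, tg = render_scene(gracile, seed=11)
    _, tp = render_scene(plump, seed=11)
    assert tp[0].area_px2 == pytest.approx(tg[0].area_px2, rel=0.25)
    ratio_g = tg[0].perimeter_px / tg[0].area_px2
    ratio_p = tp[0].perimeter_px / tp[0].area_px2
    assert ratio_p < ratio_g
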