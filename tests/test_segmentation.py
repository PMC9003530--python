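"""Depth/color segmentation chain and its morphological primitives."""

import numpy as np
import pytest
from skimage.color import rgb2hsv

from limbscan.errors import (DegenerateInputError, EmptySegmentationError,
                             InvalidArgumentError)
from limbscan.geometry import RGBDFrame
from limbscan.segmentation import (SegmentationConfig, depth_threshold, erode,
                                   hsv_color_filter, largest_region,
                                   median_filter, otsu_threshold, segment)
from limbscan.synthetic import (GREEN_RGB, LimbPhantom, RigLayout, make_rig,
                                render_rgbd)

GREEN = np.array(GREEN_RGB, dtype=np.uint8)


def brute_otsu(gray):
    """Exhaustive 256-candidate search minimising within-class variance."""
    g = np.asarray(gray).ravel().astype(np.float64)
    best_th, best_var = None, np.inf
    for th in range(256):
        lo, hi = g[g <= th], g[g > th]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(g), len(hi) / len(g)
        var = w0 * lo.var() + w1 * hi.var()
        if var < best_var - 1e-12:
            best_var, best_th = var, th
    return best_th


def naive_window_filter(mask, size, op):
    """Sliding-window reference with explicit padding (reflect for median,
    false for erosion)."""
    h, w = mask.shape
    r = size // 2
    if op == "median":
        # symmetric (edge-repeating) reflection, the border rule the
        # median filter uses
        padded = np.pad(mask.astype(int), r, mode="symmetric")
    else:
        padded = np.pad(mask.astype(int), r, mode="constant")
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + size, j:j + size]
            if op == "median":
                out[i, j] = np.median(win) > 0.5
            else:
                out[i, j] = win.min() == 1
    return out


def _frame(depth, color=None):
    from limbscan.geometry import CameraIntrinsics
    h, w = depth.shape
    K = CameraIntrinsics(width_px=w, height_px=h, fx=10, fy=10,
                         cx=(w - 1) / 2, cy=(h - 1) / 2)
    if color is None:
        color = np.zeros((h, w, 3), dtype=np.uint8)
    return RGBDFrame(color=color, depth=depth, intrinsics=K)


# -- depth threshold ---------------------------------------------------------

def test_depth_threshold():
    depth = np.array([[250.0, 600.0, 0.0]])
    frame = _frame(depth)
    assert depth_threshold(frame, 500).tolist() == [[True, False, False]]
    assert not depth_threshold(_frame(np.zeros((2, 2)))).any()
    assert depth_threshold(_frame(np.full((2, 2), 500.0)), 500).all()


# -- HSV color filter --------------------------------------------------------

def test_hsv_filter_pure_colors():
    green = np.zeros((4, 4, 3), np.uint8)
    green[:] = GREEN
    red = np.zeros((4, 4, 3), np.uint8)
    red[..., 0] = 220
    assert not hsv_color_filter(green).any()
    assert hsv_color_filter(red).all()


def test_hsv_filter_half_green_half_white():
    img = np.zeros((4, 8, 3), np.uint8)
    img[:, :4] = GREEN
    img[:, 4:] = 255
    mask = hsv_color_filter(img)
    assert not mask[:, :4].any() and mask[:, 4:].all()
    # agreement with a per-pixel HSV conversion oracle
    hsv = rgb2hsv(img / 255.0)
    inside = ((hsv[..., 0] * 360 >= 70) & (hsv[..., 0] * 360 <= 170)
              & (hsv[..., 1] >= 0.25) & (hsv[..., 2] >= 0.2))
    assert np.array_equal(mask, ~inside)


def test_hsv_filter_hue_wraparound_and_bad_bounds():
    red = np.zeros((2, 2, 3), np.uint8)
    red[..., 0] = 220
    # a wrapped interval through 0° covers red
    mask = hsv_color_filter(red, (330, 0.2, 0.2), (30, 1, 1))
    assert not mask.any()
    with pytest.raises(InvalidArgumentError):
        hsv_color_filter(red, (0, 0.9, 0), (360, 0.1, 1))


# -- Otsu --------------------------------------------------------------------

def test_otsu_bimodal_and_constant():
    raster = np.array([[10, 240] * 8] * 4, dtype=np.uint8)
    th = otsu_threshold(raster)
    assert 10 <= th < 240
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full((4, 4), 7, np.uint8))


def test_otsu_matches_exhaustive_search(rng):
    for _ in range(20):
        g = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
        assert otsu_threshold(g) == brute_otsu(g)


def test_otsu_separates_gaussian_blobs():
    rng = np.random.default_rng(7)
    lo = np.clip(rng.normal(60, 10, 1000), 0, 255)
    hi = np.clip(rng.normal(200, 10, 1000), 0, 255)
    g = np.concatenate([lo, hi]).reshape(40, 50)
    th = otsu_threshold(g)
    labels_true = np.concatenate([np.zeros(1000), np.ones(1000)])
    labels_est = (np.concatenate([lo, hi]) > th).astype(float)
    assert np.mean(labels_true != labels_est) < 0.01


# -- largest region ----------------------------------------------------------

def test_largest_region():
    mask = np.zeros((8, 8), bool)
    mask[1:3, 1:4] = True        # 6 px blob
    mask[6, 5:8] = True          # 3 px blob
    out = largest_region(mask)
    assert out[1:3, 1:4].all() and not out[6].any()
    single = np.zeros((4, 4), bool)
    single[1:3, 1:3] = True
    assert np.array_equal(largest_region(single), single)
    with pytest.raises(EmptySegmentationError):
        largest_region(np.zeros((3, 3), bool))


def test_largest_region_diagonal_connectivity_and_tiebreak():
    diag = np.eye(5, dtype=bool)             # 8-connected single component
    assert np.array_equal(largest_region(diag), diag)
    tie = np.zeros((3, 7), bool)
    tie[1, 0:2] = True                       # first in scan order
    tie[1, 5:7] = True
    out = largest_region(tie)
    assert out[1, 0:2].all() and not out[1, 5:7].any()


def test_largest_region_matches_component_enumeration(rng):
    from scipy import ndimage
    for _ in range(10):
        mask = rng.random((20, 20)) > 0.6
        if not mask.any():
            continue
        out = largest_region(mask)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = [(labels == k).sum() for k in range(1, n + 1)]
        assert out.sum() == max(sizes)
        assert (out & ~mask).sum() == 0


# -- median / erosion --------------------------------------------------------

def test_median_filter_basics():
    const = np.ones((20, 20), bool)
    assert median_filter(const, 15, 1).all()
    lone = np.zeros((31, 31), bool)
    lone[15, 15] = True
    assert not median_filter(lone, 15, 1).any()
    with pytest.raises(InvalidArgumentError):
        median_filter(const, 4, 1)


def test_median_filter_matches_naive_oracle(rng):
    for _ in range(5):
        mask = rng.random((32, 32)) > 0.5
        got = median_filter(mask, 3, 1)
        assert np.array_equal(got, naive_window_filter(mask, 3, "median"))


def test_erode_basics():
    assert not erode(np.zeros((5, 5), bool), 3, 1).any()
    square = np.zeros((40, 40), bool)
    square[5:35, 5:35] = True            # solid 30×30
    out = erode(square, 3, 10)           # each pass strips a 1-px border
    expected = np.zeros((40, 40), bool)
    expected[15:25, 15:25] = True
    assert np.array_equal(out, expected)
    with pytest.raises(InvalidArgumentError):
        erode(square, 2, 1)


def test_erode_matches_naive_oracle_and_is_contractive(rng):
    for _ in range(5):
        mask = rng.random((24, 24)) > 0.4
        got = erode(mask, 3, 1)
        assert np.array_equal(got, naive_window_filter(mask, 3, "erode"))
        assert not (got & ~mask).any()          # erosion only removes
        counts = [mask.sum()]
        for it in (1, 2, 3):
            counts.append(erode(mask, 3, it).sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# -- full chain --------------------------------------------------------------

@pytest.fixture(scope="module")
def rendered_view():
    layout = RigLayout(width_px=320, height_px=180)
    pose = make_rig(layout)[0]
    frame, silhouette = render_rgbd(LimbPhantom(), pose, layout.intrinsics)
    return frame, silhouette


def test_segment_phantom_dice_against_silhouette(rendered_view):
    from limbscan.metrics import dice
    frame, silhouette = rendered_view
    cfg = SegmentationConfig().scaled_to(frame.intrinsics.width_px)
    mask, masked = segment(frame, cfg)
    assert dice(mask, silhouette) >= 0.95
    assert (masked[~mask] == 0).all()
    assert (masked[mask] == frame.color[mask]).all()


def test_segment_final_mask_respects_depth_and_color_support(rendered_view):
    frame, _ = rendered_view
    cfg = SegmentationConfig().scaled_to(frame.intrinsics.width_px)
    mask, _, stages = segment(frame, cfg, return_stages=True)
    support = stages["depth"] & stages["color"]
    assert not (mask & ~support).any()


def test_segment_backdrop_only_raises_with_stage_name():
    color = np.zeros((20, 20, 3), np.uint8)
    color[:] = GREEN
    depth = np.full((20, 20), 600.0)
    with pytest.raises(EmptySegmentationError) as exc:
        segment(_frame(depth, color))
    assert exc.value.stage == "depth"


def test_segment_drops_small_spurious_blob(rendered_view):
    frame, silhouette = rendered_view
    color = frame.color.copy()
    depth = frame.depth.copy()
    color[2:6, 2:6] = (200, 30, 30)       # small non-green blob, in range
    depth[2:6, 2:6] = 300.0
    f2 = RGBDFrame(color=color, depth=depth, intrinsics=frame.intrinsics)
    cfg = SegmentationConfig().scaled_to(frame.intrinsics.width_px)
    mask, _ = segment(f2, cfg)
    assert not mask[2:6, 2:6].any()


def test_config_validation():
    with pytest.raises(InvalidArgumentError):
        SegmentationConfig(median_size=4)
    with pytest.raises(InvalidArgumentError):
        SegmentationConfig(depth_max_mm=0)
    cfg = SegmentationConfig().scaled_to(320)
    assert cfg.median_size % 2 == 1 and cfg.erosion_iters >= 1
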