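"""Localization stage: projection geometry, HU windowing, Gaussian
target construction and two-peak center extraction, each against an
independent brute-force oracle where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compositia import (
    CTVolume,
    extract_centers,
    localization_error,
    make_target,
    resize_to_grid,
    sagittal_project,
    window_channels,
)
from compositia.localization import (
    GRID_SHAPE,
    LOCALIZATION_WINDOWS,
    DetectionFailure,
    Heatmap,
    ProjectionTransform,
    volume_to_projection,
)
from compositia.volume_io import Annotation


# ---------------------------------------------------------------- projection
def test_projection_of_constant_volume_is_constant():
    vol = CTVolume(voxels=np.full((8, 10, 12), 100.0, np.float32), spacing=(1, 1, 1))
    img, _ = sagittal_project(vol)
    np.testing.assert_allclose(img, 100.0)
    assert img.shape == (10, 12)


def test_single_bright_voxel_projects_to_its_ap_si_position():
    vox = np.full((8, 10, 12), -1000.0, np.float32)
    vox[4, 3, 9] = 2000.0
    vol = CTVolume(voxels=vox, spacing=(1, 1, 1))
    img, _ = sagittal_project(vol, mode="mip")
    assert np.unravel_index(np.argmax(img), img.shape) == (3, 9)


def test_mip_matches_per_pixel_loop_oracle(phantom_pair):
    vol, _ = phantom_pair
    img, _ = sagittal_project(vol, mode="mip", slab_fraction=0.5)
    nx = vol.shape[0]
    half = max(1, int(round(nx * 0.25)))
    cx = nx // 2
    expected = np.empty(vol.shape[1:], np.float32)
    for j in range(vol.shape[1]):
        for k in range(vol.shape[2]):
            expected[j, k] = vol.voxels[cx - half:cx + half, j, k].max()
    np.testing.assert_array_equal(img, expected)


def test_projection_rejects_thin_volume():
    vol = CTVolume(voxels=np.zeros((1, 8, 8), np.float32), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        sagittal_project(vol)


# ---------------------------------------------------------------- windowing
@pytest.mark.parametrize("lo,hi", [*LOCALIZATION_WINDOWS, (-1024, 500), (-1024, 2048), (-190, -30), (40, 100)])
def test_window_matches_closed_form_on_dense_grid(lo, hi):
    hu = np.linspace(-1200, 3200, 10_000, dtype=np.float32)
    out = window_channels(hu[None, :], [(lo, hi)])[..., 0]
    expected = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    np.testing.assert_array_equal(out[0], expected)


def test_window_endpoints_midpoint_and_clipping():
    img = np.array([[1000.0, 2000.0, 1500.0, 3000.0, -262.0]], np.float32)
    out = window_channels(img, [(1000, 2000), (-1024, 500)])
    np.testing.assert_allclose(out[0, :, 0], [0, 1, 0.5, 1, 0], atol=1e-6)
    assert out[0, 4, 1] == pytest.approx(0.5, abs=1e-6)


def test_window_rejects_empty_or_invalid():
    with pytest.raises(ValueError):
        window_channels(np.zeros((2, 2)), [])
    with pytest.raises(ValueError):
        window_channels(np.zeros((2, 2)), [(5, 5)])


@given(hu=st.lists(st.floats(-1100, 3000), min_size=2, max_size=20))
@settings(max_examples=50, deadline=None)
def test_windowing_is_monotone_in_hu(hu):
    arr = np.sort(np.array(hu, dtype=np.float32))[None, :]
    for w in LOCALIZATION_WINDOWS:
        ch = window_channels(arr, [w])[0, :, 0]
        assert (np.diff(ch) >= -1e-7).all()


# ---------------------------------------------------------------- resize
def test_resize_identity_and_constant():
    t = ProjectionTransform(n_ap=128, n_si=256, grid=(128, 256), spacing=(1, 1))
    img = np.random.default_rng(0).random((128, 256, 3)).astype(np.float32)
    rec = resize_to_grid(img, t)
    np.testing.assert_allclose(rec.channels, img, atol=1e-5)
    const = np.full((60, 100, 3), 0.25, np.float32)
    t2 = ProjectionTransform(n_ap=60, n_si=100, grid=(60, 100), spacing=(1, 1))
    rec2 = resize_to_grid(const, t2)
    np.testing.assert_allclose(rec2.channels, 0.25, atol=1e-4)


def test_transform_roundtrip_within_half_pixel(phantom_pair):
    vol, ann = phantom_pair
    rec = volume_to_projection(vol)
    t = rec.transform
    for (j, k) in [(ann.l1_center[1], ann.l1_center[2]), (10.0, 100.0), (50.5, 3.25)]:
        u, v = t.voxel_to_pixel(j, k)
        j2, k2 = t.pixel_to_voxel(u, v)
        assert abs(j2 - j) < 1e-6 and abs(k2 - k) < 1e-6
        mm = t.pixel_to_mm(u, v)
        assert mm[1] == pytest.approx(k * vol.spacing[2], abs=1e-6)


# ---------------------------------------------------------------- heatmap
def test_make_target_single_center_peak_at_one():
    hm = make_target([(64, 128)], shape=GRID_SHAPE, sigma=15)
    assert np.unravel_index(np.argmax(hm.values), hm.values.shape) == (64, 128)
    assert hm.values.max() == pytest.approx(1.0)


def test_make_target_matches_gaussian_summation_oracle():
    centers = [(40, 60), (40, 160)]  # 100 px apart
    sigma = 15.0
    hm = make_target(centers, shape=GRID_SHAPE, sigma=sigma)
    uu, vv = np.meshgrid(np.arange(GRID_SHAPE[0]), np.arange(GRID_SHAPE[1]), indexing="ij")
    oracle = np.zeros(GRID_SHAPE)
    for cu, cv in centers:
        oracle += np.exp(-((uu - cu) ** 2 + (vv - cv) ** 2) / (2 * sigma**2))
    oracle /= oracle.max()
    # identical up to the filter's finite truncation
    np.testing.assert_allclose(hm.values, oracle, atol=2e-3)
    for cu, cv in centers:
        patch = hm.values[cu - 5:cu + 6, cv - 5:cv + 6]
        assert patch.max() == hm.values[cu, cv]


def test_make_target_zero_outside_four_sigma():
    hm = make_target([(64, 128)], shape=GRID_SHAPE, sigma=10)
    uu, vv = np.meshgrid(np.arange(GRID_SHAPE[0]), np.arange(GRID_SHAPE[1]), indexing="ij")
    far = np.hypot(uu - 64.0, vv - 128.0) > 40.0 + 1.5
    assert np.abs(hm.values[far]).max() < 1e-3


def test_make_target_small_sigma_concentrates_mass():
    hm = make_target([(30, 30), (90, 200)], shape=GRID_SHAPE, sigma=0.5)
    uu, vv = np.meshgrid(np.arange(GRID_SHAPE[0]), np.arange(GRID_SHAPE[1]), indexing="ij")
    near = (np.hypot(uu - 30, vv - 30) <= 2) | (np.hypot(uu - 90, vv - 200) <= 2)
    assert hm.values[~near].sum() < 0.01 * hm.values.sum()


def test_make_target_rejects_degenerate_centers():
    with pytest.raises(ValueError):
        make_target([(10, 10), (10.2, 10.4)], shape=GRID_SHAPE, sigma=5)
    with pytest.raises(ValueError):
        make_target([(500, 10)], shape=GRID_SHAPE, sigma=5)


# ---------------------------------------------------------------- peaks
def _vol_for_grid():
    return CTVolume(voxels=np.zeros((4, 128, 256), np.float32), spacing=(1, 1, 1))


def _identity_record():
    t = ProjectionTransform(n_ap=128, n_si=256, grid=GRID_SHAPE, spacing=(1.0, 1.0))
    return resize_to_grid(np.zeros((128, 256, 3), np.float32), t)


def test_extract_centers_recovers_construction_exactly():
    rec, vol = _identity_record(), _vol_for_grid()
    hm = make_target([(40, 200), (60, 90)], shape=GRID_SHAPE, sigma=15)
    pred = extract_centers(hm, rec, vol)
    assert pred.l1_pixel == (40, 200)  # superior peak is L1
    assert pred.l3_pixel == (60, 90)
    assert pred.l1_slice == 200 and pred.l3_slice == 90


def test_three_blobs_keep_two_strongest_against_bruteforce():
    rec, vol = _identity_record(), _vol_for_grid()
    sigma = 8.0
    blobs = [((30, 40), 1.0), ((64, 128), 0.9), ((100, 220), 0.2)]
    uu, vv = np.meshgrid(np.arange(128), np.arange(256), indexing="ij")
    img = np.zeros((128, 256))
    for (cu, cv), a in blobs:
        img += a * np.exp(-((uu - cu) ** 2 + (vv - cv) ** 2) / (2 * sigma**2))
    hm = Heatmap(values=img.astype(np.float32), sigma=sigma)
    # brute force: scan every pixel for local maxima, rank by intensity
    local_max = []
    for u in range(1, 127):
        for v in range(1, 255):
            patch = img[u - 1:u + 2, v - 1:v + 2]
            if img[u, v] == patch.max() and img[u, v] > 0.1 * img.max():
                local_max.append(((u, v), img[u, v]))
    local_max.sort(key=lambda p: -p[1])
    expected = {local_max[0][0], local_max[1][0]}
    pred = extract_centers(hm, rec, vol)
    assert {pred.l1_pixel, pred.l3_pixel} == expected


def test_uniform_zero_heatmap_is_detection_failure():
    rec, vol = _identity_record(), _vol_for_grid()
    hm = Heatmap(values=np.zeros(GRID_SHAPE, np.float32), sigma=15)
    with pytest.raises(DetectionFailure):
        extract_centers(hm, rec, vol)


def test_single_peak_is_detection_failure():
    rec, vol = _identity_record(), _vol_for_grid()
    hm = make_target([(64, 128)], shape=GRID_SHAPE, sigma=15)
    with pytest.raises(DetectionFailure):
        extract_centers(hm, rec, vol)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_target_then_extract_recovers_centers(seed):
    """make_target -> extract_centers is the identity for centers >= 3 sigma apart."""
    rng = np.random.default_rng(seed)
    sigma = 15.0
    while True:
        c1 = (int(rng.integers(5, 123)), int(rng.integers(5, 251)))
        c2 = (int(rng.integers(5, 123)), int(rng.integers(5, 251)))
        if np.hypot(c1[0] - c2[0], c1[1] - c2[1]) >= 3 * sigma and c1[1] != c2[1]:
            break
    hm = make_target([c1, c2], shape=GRID_SHAPE, sigma=sigma)
    pred = extract_centers(hm, _identity_record(), _vol_for_grid())
    sup, inf = (c1, c2) if c1[1] > c2[1] else (c2, c1)
    assert pred.l1_pixel == sup
    assert pred.l3_pixel == inf


# ---------------------------------------------------------------- errors
def test_localization_error_arithmetic():
    vol = CTVolume(voxels=np.zeros((4, 4, 40), np.float32), spacing=(1, 1, 3.0))
    ann = Annotation(l1_center=(2, 2, 30), l3_center=(2, 2, 20))
    from compositia.localization import CenterPrediction

    exact = CenterPrediction(l1_pixel=(0, 0), l3_pixel=(0, 0), l1_slice=30, l3_slice=20,
                             l1_mm=90.0, l3_mm=60.0, peak_intensities=(1, 1))
    assert localization_error(exact, ann, vol) == (0.0, 0.0, 0, 0)
    off = CenterPrediction(l1_pixel=(0, 0), l3_pixel=(0, 0), l1_slice=32, l3_slice=18,
                           l1_mm=96.0, l3_mm=54.0, peak_intensities=(1, 1))
    d1, d3, s1, s3 = localization_error(off, ann, vol)
    assert (d1, s1) == (6.0, 2) and (d3, s3) == (6.0, 2)
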