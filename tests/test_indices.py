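"""Body-composition indices against hand arithmetic and a per-pixel
brute-force oracle."""

import numpy as np
import pytest

from compositia import compute_report, region_area, region_density_stats
from compositia.indices import INDEX_COLUMNS, IndexReport, UndefinedStatisticError, reports_to_frame
from compositia.segmentation import LabelMask


def _mask(level, arr):
    return LabelMask(labels=np.asarray(arr, dtype=np.int32), level=level)


# ---------------------------------------------------------------- areas
def test_region_area_unit_conversion():
    arr = np.zeros((20, 20), int)
    arr.flat[:100] = 1
    assert region_area(_mask("L1", arr), "trabecular", (1.0, 1.0)) == pytest.approx(1.0)
    assert region_area(_mask("L1", np.zeros((4, 4), int)), "trabecular", (1.0, 1.0)) == 0.0
    arr2 = np.zeros((20, 20), int)
    arr2.flat[:173] = 1
    assert region_area(_mask("L1", arr2), "trabecular", (0.76, 0.76)) == pytest.approx(173 * 0.5776 / 100)


def test_region_area_linear_in_count_quadratic_in_spacing():
    arr = np.zeros((10, 10), int)
    arr.flat[:30] = 1
    a1 = region_area(_mask("L1", arr), "trabecular", (1.0, 1.0))
    arr2 = arr.copy()
    arr2.flat[30:60] = 1
    assert region_area(_mask("L1", arr2), "trabecular", (1.0, 1.0)) == pytest.approx(2 * a1)
    assert region_area(_mask("L1", arr), "trabecular", (2.0, 2.0)) == pytest.approx(4 * a1)


def test_class_areas_partition_the_slice(rng):
    labels = rng.integers(0, 4, size=(32, 32))
    m = _mask("L3", labels)
    total = sum(region_area(m, c, (0.7, 0.7)) for c in m.class_names)
    assert total == pytest.approx(32 * 32 * 0.49 / 100)


# ---------------------------------------------------------------- density
def test_density_stats_constant_and_two_pixel():
    arr = np.zeros((4, 4), int)
    arr[0, :2] = 1
    hu = np.zeros((4, 4), np.float32)
    hu[0, 0], hu[0, 1] = 150.0, 150.0
    assert region_density_stats(_mask("L1", arr), "trabecular", hu) == (150.0, 0.0)
    hu[0, 1] = 200.0
    hu[0, 0] = 100.0
    mean, sd = region_density_stats(_mask("L1", arr), "trabecular", hu)
    assert mean == pytest.approx(150.0)
    assert sd == pytest.approx(50.0)  # population convention, not 70.71


def test_density_stats_recover_injected_noise(rng):
    arr = np.zeros((40, 40), int)
    arr[:25, :25] = 1  # 625 px
    hu = np.zeros((40, 40), np.float32)
    hu[:25, :25] = rng.normal(160, 30, size=(25, 25))
    mean, sd = region_density_stats(_mask("L1", arr), "trabecular", hu)
    assert abs(mean - 160) / 160 < 0.05
    assert abs(sd - 30) / 30 < 0.10


def test_density_stats_empty_region_raises():
    with pytest.raises(UndefinedStatisticError):
        region_density_stats(_mask("L1", np.zeros((4, 4), int)), "cortical", np.zeros((4, 4)))


def test_density_invariant_to_other_class_relabeling(rng):
    labels = rng.integers(0, 3, size=(16, 16))
    hu = rng.normal(100, 20, size=(16, 16)).astype(np.float32)
    ref = region_density_stats(_mask("L1", labels), "trabecular", hu)
    relabeled = labels.copy()
    relabeled[labels == 2] = 0  # merge cortical into background
    assert region_density_stats(_mask("L1", relabeled), "trabecular", hu) == ref


# ---------------------------------------------------------------- report
def _brute_force_report(l1m, l1hu, l3m, l3hu, spacing):
    """Per-pixel loop oracle for all seven indices."""
    def px_area(n):  # same evaluation order as the implementation
        return n * spacing[0] * spacing[1] / 100.0

    counts = {"trab": 0, "sat": 0, "sma": 0, "vat": 0}
    trab_vals, sat_vals = [], []
    for i in range(l1m.shape[0]):
        for j in range(l1m.shape[1]):
            if l1m[i, j] == 1:
                counts["trab"] += 1
                trab_vals.append(l1hu[i, j])
    for i in range(l3m.shape[0]):
        for j in range(l3m.shape[1]):
            if l3m[i, j] == 1:
                counts["sma"] += 1
            elif l3m[i, j] == 2:
                counts["vat"] += 1
            elif l3m[i, j] == 3:
                counts["sat"] += 1
                sat_vals.append(l3hu[i, j])
    trab = np.array(trab_vals, dtype=np.float32)
    sat = np.array(sat_vals, dtype=np.float32)
    return {
        "bmd_avg": float(trab.mean()),
        "bmd_sd": float(trab.std(ddof=0)),
        "l1_trab_area": px_area(counts["trab"]),
        "l3_sat_area": px_area(counts["sat"]),
        "l3_sma": px_area(counts["sma"]),
        "l3_vat_area": px_area(counts["vat"]),
        "l3_sat_density_sd": float(sat.std(ddof=0)),
    }


@pytest.mark.parametrize("seed", range(20))
def test_compute_report_equals_bruteforce_loop(seed):
    rng = np.random.default_rng(seed)
    l1 = rng.integers(0, 3, size=(64, 64))
    l3 = rng.integers(0, 4, size=(64, 64))
    l1hu = rng.normal(100, 200, size=(64, 64)).astype(np.float32)
    l3hu = rng.normal(-50, 100, size=(64, 64)).astype(np.float32)
    spacing = (0.8, 0.8)
    rep = compute_report(_mask("L1", l1), l1hu, _mask("L3", l3), l3hu, spacing)
    expected = _brute_force_report(l1, l1hu, l3, l3hu, spacing)
    for key, val in expected.items():
        assert getattr(rep, key) == val, key


def test_report_on_constructed_fat_ring(phantom_pair):
    vol, ann = phantom_pair
    from compositia.phantom import truth_masks
    from compositia.pipeline import extract_slice

    tm1, tm3 = truth_masks(ann)
    sl1 = extract_slice(vol, ann.l1_center[2], "L1")
    sl3 = extract_slice(vol, ann.l3_center[2], "L3")
    rep = compute_report(tm1, sl1.hu, tm3, sl3.hu, sl1.spacing, subject_id="fixture")
    sat_px = int((ann.l3_mask == 3).sum())
    assert rep.l3_sat_area == pytest.approx(sat_px * 4.0 / 100)
    assert rep.bmd_avg == pytest.approx(160, rel=0.05)


def test_all_background_masks_raise_undefined_statistic():
    z1 = _mask("L1", np.zeros((8, 8), int))
    z3 = _mask("L3", np.zeros((8, 8), int))
    hu = np.zeros((8, 8), np.float32)
    assert region_area(z3, "sat", (1, 1)) == 0.0
    with pytest.raises(UndefinedStatisticError):
        compute_report(z1, hu, z3, hu, (1.0, 1.0))


def test_report_frame_has_seven_index_columns():
    rep = IndexReport(bmd_avg=150, bmd_sd=25, l1_trab_area=8, l3_sat_area=40,
                      l3_sma=30, l3_vat_area=10, l3_sat_density_sd=20, subject_id="a")
    df = reports_to_frame([rep, rep])
    assert list(df.columns) == ["subject_id", *INDEX_COLUMNS]
    assert len(df) == 2
    with pytest.raises(ValueError):
        IndexReport(bmd_avg=0, bmd_sd=-1, l1_trab_area=0, l3_sat_area=0,
                    l3_sma=0, l3_vat_area=0, l3_sat_density_sd=0)
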