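"""Segmentation stage: preprocessing windows, grid adaptation, mask
prediction rules and the Dice coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compositia import SlabSlice, predict_mask, preprocess_l1, preprocess_l3, vdsc
from compositia.segmentation import (
    CLASS_VOCAB,
    L1_WINDOW,
    L3_WINDOWS,
    LabelMask,
    to_grid,
)


def _slice(level, values):
    hu = np.full((32, 32), -1024.0, np.float32)
    hu.flat[: len(values)] = values
    return SlabSlice(hu=hu, spacing=(1.0, 1.0), level=level)


# ---------------------------------------------------------------- windows
def test_l1_window_endpoints_and_clipping():
    out = preprocess_l1(_slice("L1", [-1024, 500, 1000, -262]))
    assert out.shape == (32, 32, 1)
    np.testing.assert_allclose(out.flat[:4], [0.0, 1.0, 1.0, 0.5], atol=1e-6)


def test_l3_three_channel_midpoints():
    out = preprocess_l3(_slice("L3", [-110.0, 70.0, 512.0]))
    assert out.shape == (32, 32, 3)
    assert out[0, 0, 1] == pytest.approx(0.5, abs=1e-6)  # fat window midpoint
    assert out[0, 1, 2] == pytest.approx(0.5, abs=1e-6)  # muscle window midpoint
    assert out[0, 2, 0] == pytest.approx(0.5, abs=1e-6)  # full-contrast midpoint


def test_preprocess_rejects_wrong_level():
    with pytest.raises(ValueError):
        preprocess_l1(_slice("L3", [0]))
    with pytest.raises(ValueError):
        preprocess_l3(_slice("L1", [0]))


@given(hu=st.lists(st.floats(-1100, 2500), min_size=2, max_size=16))
@settings(max_examples=50, deadline=None)
def test_preprocessing_is_monotone_per_channel(hu):
    arr = np.sort(np.array(hu, np.float32))
    s = np.full((32, 32), -1024.0, np.float32)
    s.flat[: arr.size] = arr
    for level, fn, windows in (("L1", preprocess_l1, [L1_WINDOW]), ("L3", preprocess_l3, L3_WINDOWS)):
        out = fn(SlabSlice(hu=s, spacing=(1, 1), level=level))
        for c in range(len(windows)):
            vals = out.reshape(-1, out.shape[-1])[: arr.size, c]
            assert (np.diff(vals) >= -1e-7).all()


# ---------------------------------------------------------------- grids
def test_to_grid_pads_with_air_and_crops_centrally():
    small = np.full((10, 10), 50.0, np.float32)
    padded = to_grid(small, 16)
    assert padded.shape == (16, 16)
    assert padded[0, 0] == -1024.0
    assert padded[8, 8] == 50.0
    assert (padded == 50.0).sum() == 100

    big = np.arange(20 * 20, dtype=np.float32).reshape(20, 20)
    cropped = to_grid(big, 16)
    np.testing.assert_array_equal(cropped, big[2:18, 2:18])


def test_slab_slice_validation():
    with pytest.raises(ValueError):
        SlabSlice(hu=np.zeros((30, 30)), spacing=(1, 1), level="L1")  # not /16
    with pytest.raises(ValueError):
        SlabSlice(hu=np.zeros((32, 16)), spacing=(1, 1), level="L1")  # not square
    with pytest.raises(ValueError):
        SlabSlice(hu=np.zeros((32, 32)), spacing=(1, 1), level="LX")


# ---------------------------------------------------------------- masks
class _StubModel:
    """Fixed-probability model for exercising the argmax rules."""

    def __init__(self, probs):
        self.probs = probs

    def eval(self):
        return self

    def __call__(self, x):
        from compositia.nn import Tensor

        return Tensor(np.repeat(self.probs[None], x.shape[0], axis=0))


def test_predict_mask_uniform_and_tie_break():
    img = np.zeros((16, 16, 1), np.float32)
    probs = np.zeros((3, 16, 16), np.float32)
    probs[1] = 1.0
    mask = predict_mask(_StubModel(probs), img, "L1")
    assert (mask.labels == 1).all()

    tie = np.full((3, 16, 16), 1 / 3, np.float32)  # exact three-way tie
    mask = predict_mask(_StubModel(tie), img, "L1")
    assert (mask.labels == 0).all()  # lower class index wins


def test_label_mask_vocabulary_enforced():
    with pytest.raises(ValueError):
        LabelMask(labels=np.full((4, 4), 3), level="L1")  # L1 has 3 classes
    m = LabelMask(labels=np.full((4, 4), 3), level="L3")
    assert m.class_names == CLASS_VOCAB["L3"]
    with pytest.raises(KeyError):
        m.class_index("bone")


# ---------------------------------------------------------------- dice
def _mask(level, arr):
    return LabelMask(labels=np.asarray(arr, dtype=np.int32), level=level)


def test_vdsc_identity_disjoint_and_half():
    a = np.zeros((8, 8), int)
    a[:2, :2] = 1
    b = np.zeros((8, 8), int)
    b[6:, 6:] = 1
    assert vdsc(_mask("L1", a), _mask("L1", a), "trabecular") == 1.0
    assert vdsc(_mask("L1", a), _mask("L1", b), "trabecular") == 0.0
    p = np.zeros((8, 8), int)
    p[0, :4] = 1
    t = np.zeros((8, 8), int)
    t[0, 2:6] = 1
    assert vdsc(_mask("L1", p), _mask("L1", t), "trabecular") == pytest.approx(0.5)


def test_vdsc_both_empty_is_one():
    z = _mask("L1", np.zeros((4, 4), int))
    assert vdsc(z, z, "cortical") == 1.0


def test_vdsc_rejects_shape_mismatch_and_unknown_class():
    a = _mask("L1", np.zeros((4, 4), int))
    b = _mask("L1", np.zeros((6, 6), int))
    with pytest.raises(ValueError):
        vdsc(a, b, "trabecular")
    with pytest.raises(KeyError):
        vdsc(a, a, "sat")


@given(data=st.data())
@settings(max_examples=50, deadline=None)
def test_vdsc_symmetric_and_bounded(data):
    shape = (6, 6)
    a = data.draw(st.lists(st.integers(0, 2), min_size=36, max_size=36))
    b = data.draw(st.lists(st.integers(0, 2), min_size=36, max_size=36))
    ma = _mask("L1", np.array(a).reshape(shape))
    mb = _mask("L1", np.array(b).reshape(shape))
    for cls in ("trabecular", "cortical"):
        d_ab = vdsc(ma, mb, cls)
        assert d_ab == vdsc(mb, ma, cls)
        assert 0.0 <= d_ab <= 1.0
        assert vdsc(ma, ma, cls) == 1.0
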