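"""L1/L3 vertebral level localization by sagittal heatmap regression.

The volume (canonical RAS, isotropic) is reduced over the right–left
axis to a 2D sagittal projection, windowed into three bone-weighted
channels ([1000, 2000], [400, 500], [800, 1900] HU), normalized to
[0, 1] and resized to a 128 (anterior–posterior) × 256
(inferior–superior) grid.  A MultiResUNet regresses a heatmap built by
placing unit impulses at the L1 and L3 centers and Gaussian-filtering
with σ = 15 px (renormalized so each run of the filter leaves the
global maximum at 1).  At inference the two most intense local maxima
are taken as the centers; the superior peak is L1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

from .nn import MultiResUNet, mse_loss, predict_batched, train_model
from .volume_io import Annotation, CTVolume

LOCALIZATION_WINDOWS: tuple[tuple[float, float], ...] = ((1000, 2000), (400, 500), (800, 1900))
GRID_SHAPE: tuple[int, int] = (128, 256)  # (AP, SI)
DEFAULT_SIGMA = 15.0


class DetectionFailure(RuntimeError):
    """Raised when fewer than two landmark peaks can be found."""


@dataclass
class ProjectionTransform:
    """Linear map between projection pixels (u, v) and volume voxels (j, k).

    Pixel centers follow the anti-aliased-resize convention: voxel
    coordinate = (pixel + 0.5) * scale - 0.5 with scale = n_in / n_out.
    u runs along the anterior–posterior axis (volume axis 1), v along
    the inferior–superior axis (volume axis 2).
    """

    n_ap: int
    n_si: int
    grid: tuple[int, int]
    spacing: tuple[float, float]  # (AP mm/voxel, SI mm/voxel)

    @property
    def scales(self) -> tuple[float, float]:
        return self.n_ap / self.grid[0], self.n_si / self.grid[1]

    def pixel_to_voxel(self, u: float, v: float) -> tuple[float, float]:
        su, sv = self.scales
        return (u + 0.5) * su - 0.5, (v + 0.5) * sv - 0.5

    def voxel_to_pixel(self, j: float, k: float) -> tuple[float, float]:
        su, sv = self.scales
        return (j + 0.5) / su - 0.5, (k + 0.5) / sv - 0.5

    def pixel_to_mm(self, u: float, v: float) -> tuple[float, float]:
        j, k = self.pixel_to_voxel(u, v)
        return j * self.spacing[0], k * self.spacing[1]


@dataclass
class ProjectionRecord:
    """3-channel [0,1] sagittal projection on the 128x256 grid."""

    channels: np.ndarray  # (grid_ap, grid_si, 3)
    transform: ProjectionTransform
    subject_id: str = ""

    def __post_init__(self):
        lo, hi = float(self.channels.min()), float(self.channels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"channel values outside [0,1]: [{lo}, {hi}]")


@dataclass
class Heatmap:
    values: np.ndarray  # (grid_ap, grid_si), non-negative
    sigma: float

    def __post_init__(self):
        if float(self.values.min()) < -1e-6:
            raise ValueError("heatmap values must be non-negative")


@dataclass
class CenterPrediction:
    """Predicted L1/L3 centers in projection-pixel, slice and mm coordinates."""

    l1_pixel: tuple[int, int]
    l3_pixel: tuple[int, int]
    l1_slice: int
    l3_slice: int
    l1_mm: float
    l3_mm: float
    peak_intensities: tuple[float, float]
    subject_id: str = ""

    def __post_init__(self):
        if self.l1_slice <= self.l3_slice:
            raise ValueError("L1 must be superior to L3")


# ---------------------------------------------------------------------------
def sagittal_project(vol: CTVolume, mode: str = "mip", slab_fraction: float = 0.5):
    """Project a canonical isotropic volume onto the sagittal plane.

    Reduces the right–left axis (axis 0) by maximum (``mode="mip"``) or
    mean intensity over a central sagittal slab covering `slab_fraction`
    of the RL extent, which suppresses ribs and arms.

    Returns ``(image, transform)`` where image has shape (n_ap, n_si)
    in HU and `transform` maps its pixels back to volume voxels/mm.
    """
    nx = vol.shape[0]
    if nx < 2:
        raise ValueError("volume too thin along the right-left axis to project")
    if not 0 < slab_fraction <= 1:
        raise ValueError("slab_fraction must be in (0, 1]")
    half = max(1, int(round(nx * slab_fraction / 2)))
    cx = nx // 2
    slab = vol.voxels[max(0, cx - half):min(nx, cx + half)]
    if mode == "mip":
        img = slab.max(axis=0)
    elif mode == "mean":
        img = slab.mean(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    transform = ProjectionTransform(
        n_ap=vol.shape[1], n_si=vol.shape[2], grid=(vol.shape[1], vol.shape[2]),
        spacing=(vol.spacing[1], vol.spacing[2]),
    )
    return img.astype(np.float32), transform


def window_channels(img: np.ndarray, windows=LOCALIZATION_WINDOWS) -> np.ndarray:
    """Stack HU windows as [0,1] channels: clip((img - lo) / (hi - lo), 0, 1)."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    chans = []
    for lo, hi in windows:
        if not lo < hi:
            raise ValueError(f"invalid window [{lo}, {hi}]")
        chans.append(np.clip((img - lo) / (hi - lo), 0.0, 1.0))
    return np.stack(chans, axis=-1).astype(np.float32)


def resize_to_grid(img: np.ndarray, transform: ProjectionTransform,
                   grid: tuple[int, int] = GRID_SHAPE, subject_id: str = "") -> ProjectionRecord:
    """Anti-aliased resize of a multi-channel projection to the model grid."""
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("projection too small to resize")
    if img.shape[:2] == tuple(grid):
        out = img.astype(np.float32)
    else:
        out = _sk_resize(img, (*grid, img.shape[2]), order=1, mode="edge",
                         anti_aliasing=True, preserve_range=True).astype(np.float32)
    out = np.clip(out, 0.0, 1.0)
    new_t = ProjectionTransform(n_ap=transform.n_ap, n_si=transform.n_si,
                                grid=tuple(grid), spacing=transform.spacing)
    return ProjectionRecord(channels=out, transform=new_t, subject_id=subject_id)


def make_target(centers, shape: tuple[int, int] = GRID_SHAPE, sigma: float = DEFAULT_SIGMA) -> Heatmap:
    """Gaussian landmark heatmap: impulses at `centers`, filtered with σ,
    renormalized so the global maximum is 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    centers = [tuple(int(round(c)) for c in ctr) for ctr in centers]
    for u, v in centers:
        if not (0 <= u < shape[0] and 0 <= v < shape[1]):
            raise ValueError(f"center {(u, v)} outside grid {shape}")
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            d = np.hypot(centers[a][0] - centers[b][0], centers[a][1] - centers[b][1])
            if d < 1.0:
                raise ValueError("degenerate target: centers closer than 1 pixel")
    img = np.zeros(shape, dtype=np.float64)
    for u, v in centers:
        img[u, v] = 1.0
    out = ndimage.gaussian_filter(img, sigma=sigma, mode="constant")
    m = out.max()
    if m > 0:
        out /= m
    return Heatmap(values=out.astype(np.float32), sigma=float(sigma))


def find_peaks(hm: Heatmap, min_separation: float | None = None,
               intensity_floor_frac: float = 0.1):
    """Local maxima of a heatmap sorted by decreasing intensity.

    Minimum peak separation defaults to 2σ; peaks below
    `intensity_floor_frac` × global max are discarded.  Ties are broken
    toward the superior (larger v) position.
    """
    if min_separation is None:
        min_separation = 2.0 * hm.sigma
    vmax = float(hm.values.max())
    if vmax <= 0:
        return []
    floor = intensity_floor_frac * vmax
    coords = peak_local_max(hm.values, min_distance=int(round(min_separation)),
                            threshold_abs=floor, exclude_border=False)
    peaks = [((int(u), int(v)), float(hm.values[u, v])) for u, v in coords]
    peaks.sort(key=lambda p: (-p[1], -p[0][1]))
    return peaks


def extract_centers(hm: Heatmap, record: ProjectionRecord, vol: CTVolume,
                    intensity_floor_frac: float = 0.1) -> CenterPrediction:
    """Two most intense peaks -> (L1, L3) by anatomical (superior first) order."""
    if hm.values.shape != record.channels.shape[:2]:
        raise ValueError("heatmap and projection shapes differ")
    peaks = find_peaks(hm, intensity_floor_frac=intensity_floor_frac)
    if len(peaks) < 2:
        raise DetectionFailure(
            f"found {len(peaks)} landmark peak(s); need 2 (L1 and L3)")
    (p_a, i_a), (p_b, i_b) = peaks[0], peaks[1]
    # superior (larger SI pixel) peak is L1
    (l1_px, l1_int), (l3_px, l3_int) = ((p_a, i_a), (p_b, i_b)) if p_a[1] > p_b[1] else ((p_b, i_b), (p_a, i_a))

    def to_slice_mm(px):
        j, k = record.transform.pixel_to_voxel(*px)
        k = min(max(k, 0.0), vol.shape[2] - 1)
        return int(round(k)), k * vol.spacing[2]

    l1_slice, l1_mm = to_slice_mm(l1_px)
    l3_slice, l3_mm = to_slice_mm(l3_px)
    if l1_slice <= l3_slice:
        raise DetectionFailure("the two strongest peaks collapse onto one axial level")
    return CenterPrediction(
        l1_pixel=l1_px, l3_pixel=l3_px,
        l1_slice=l1_slice, l3_slice=l3_slice,
        l1_mm=l1_mm, l3_mm=l3_mm,
        peak_intensities=(l1_int, l3_int),
        subject_id=record.subject_id,
    )


def localization_error(pred: CenterPrediction, truth: Annotation, vol: CTVolume):
    """SI-axis errors: (mm distance L1, mm distance L3, slice error L1, slice error L3)."""
    sz = vol.spacing[2]
    d_l1 = abs(pred.l1_mm - truth.l1_center[2] * sz)
    d_l3 = abs(pred.l3_mm - truth.l3_center[2] * sz)
    s_l1 = abs(pred.l1_slice - truth.l1_center[2])
    s_l3 = abs(pred.l3_slice - truth.l3_center[2])
    return float(d_l1), float(d_l3), int(s_l1), int(s_l3)


def _shift2d(arr: np.ndarray, du: int, dv: int) -> np.ndarray:
    """Translate a (C, H, W) array by (du, dv), zero-filling the border."""
    out = np.zeros_like(arr)
    h, w = arr.shape[-2:]
    src_u = slice(max(0, -du), min(h, h - du))
    dst_u = slice(max(0, du), min(h, h + du))
    src_v = slice(max(0, -dv), min(w, w - dv))
    dst_v = slice(max(0, dv), min(w, w + dv))
    out[..., dst_u, dst_v] = arr[..., src_u, src_v]
    return out


def shift_augment(max_u: int = 4, max_v: int = 8):
    """Batch augmentation: random rigid translation of projection and
    heatmap together, so the landmark model cannot rely on absolute
    grid position alone."""

    def _apply(xb, yb, rng):
        xs, ys = np.empty_like(xb), np.empty_like(yb)
        for i in range(xb.shape[0]):
            du = int(rng.integers(-max_u, max_u + 1))
            dv = int(rng.integers(-max_v, max_v + 1))
            xs[i] = _shift2d(xb[i], du, dv)
            ys[i] = _shift2d(yb[i], du, dv)
        return xs, ys

    return _apply


# ---------------------------------------------------------------------------
def volume_to_projection(vol: CTVolume, windows=LOCALIZATION_WINDOWS,
                         grid: tuple[int, int] = GRID_SHAPE, mode: str = "mip",
                         slab_fraction: float = 0.5) -> ProjectionRecord:
    """Full preprocessing chain: project, window, resize."""
    img, transform = sagittal_project(vol, mode=mode, slab_fraction=slab_fraction)
    return resize_to_grid(window_channels(img, windows), transform, grid=grid,
                          subject_id=vol.subject_id)


class HeatmapLocalizer(BaseEstimator):
    """sklearn-style estimator: volumes + annotations -> L1/L3 centers.

    Parameters mirror the pipeline defaults (σ = 15 px on a 128×256
    grid, MIP over the central sagittal slab, three bone windows); the
    network and optimization settings are deliberately small so the
    model trains on a single CPU.
    """

    def __init__(self, sigma: float = DEFAULT_SIGMA, windows=LOCALIZATION_WINDOWS,
                 grid: tuple[int, int] = GRID_SHAPE, projection: str = "mip",
                 slab_fraction: float = 0.5, base_filters: int = 4,
                 epochs: int = 20, batch_size: int = 4, lr: float = 2e-3,
                 val_fraction: float = 0.0, patience: int = 0, seed: int = 0,
                 augment_shift: tuple[int, int] | None = (4, 8)):
        self.sigma = sigma
        self.windows = windows
        self.grid = grid
        self.projection = projection
        self.slab_fraction = slab_fraction
        self.base_filters = base_filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed
        self.augment_shift = augment_shift

    # -- helpers --------------------------------------------------------
    def _record(self, vol: CTVolume) -> ProjectionRecord:
        return volume_to_projection(vol, windows=self.windows, grid=tuple(self.grid),
                                    mode=self.projection, slab_fraction=self.slab_fraction)

    def _target(self, record: ProjectionRecord, ann: Annotation) -> Heatmap:
        t = record.transform
        c_l1 = t.voxel_to_pixel(ann.l1_center[1], ann.l1_center[2])
        c_l3 = t.voxel_to_pixel(ann.l3_center[1], ann.l3_center[2])
        return make_target([c_l1, c_l3], shape=tuple(self.grid), sigma=self.sigma)

    # -- estimator API --------------------------------------------------
    def fit(self, X, y):
        """Train on volumes `X` (list of CTVolume) and annotations `y`."""
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        records = [self._record(v) for v in X]
        inputs = np.stack([r.channels.transpose(2, 0, 1) for r in records])
        targets = np.stack([self._target(r, a).values[None] for r, a in zip(records, y)])
        self.model_ = MultiResUNet(in_ch=inputs.shape[1],
                                   base_filters=self.base_filters, seed=self.seed)
        aug = shift_augment(*self.augment_shift) if self.augment_shift else None
        self.history_ = train_model(
            self.model_, inputs, targets, mse_loss,
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            seed=self.seed, val_fraction=self.val_fraction, patience=self.patience,
            augment=aug)
        return self

    def predict_heatmap(self, vol: CTVolume) -> tuple[Heatmap, ProjectionRecord]:
        record = self._record(vol)
        out = predict_batched(self.model_, record.channels.transpose(2, 0, 1)[None])
        return Heatmap(values=out[0, 0], sigma=self.sigma), record

    def predict_one(self, vol: CTVolume) -> CenterPrediction:
        hm, record = self.predict_heatmap(vol)
        return extract_centers(hm, record, vol)

    def predict(self, X):
        return [self.predict_one(v) for v in X]
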