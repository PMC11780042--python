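"""Synthetic thoraco-abdominal CT phantoms with known ground truth.

Each phantom is an elliptical body on an air background containing,
from the outside in: a subcutaneous fat (SAT) ring, an abdominal
muscle wall (SMA), a visceral cavity with organ-density background and
visceral fat (VAT) columns, and a posterior vertebral column of
cylindrical bodies — a high-HU cortical shell around a lower-HU
trabecular core — separated by disc gaps.  Tissue HU values are drawn
per voxel from tissue-typical normal distributions consistent with the
clinical windowing ranges (fat bounded to [-190, -30] HU, muscle
within [40, 100] HU), and global Gaussian acquisition noise is added.

The generator returns exact L1/L3 center coordinates and per-class
label masks for the corresponding axial slices, so localization,
segmentation and index quantification are all testable without
patient data.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .segmentation import LabelMask
from .volume_io import AIR_HU, Annotation, CTVolume

# internal label codes for voxel material
_AIR, _ORGAN, _SAT, _MUSCLE, _VAT, _DISC, _CORTICAL, _TRABECULAR = range(8)


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of one phantom; seed-deterministic."""

    shape: tuple[int, int, int] = (96, 96, 120)
    spacing: float = 2.0  # mm, isotropic
    # body ellipse semi-axes (voxels)
    body_rx: float = 35.0
    body_ry: float = 28.0
    sat_thickness: float = 6.0
    muscle_thickness: float = 4.0
    # vertebral column
    spine_radius: float = 8.0
    cortical_thickness: float = 2.0
    vertebra_height: int = 11
    disc_gap: int = 3
    l1_fraction: float = 0.62  # SI position of the L1 center
    rib_length: float = 10.0   # lateral rib stubs on thoracic vertebrae
    n_vat_blobs: int = 4
    # tissue HU distributions (mean, sd)
    trabecular_hu: tuple[float, float] = (160.0, 30.0)
    cortical_hu: tuple[float, float] = (1200.0, 150.0)
    fat_hu: tuple[float, float] = (-100.0, 20.0)
    fat_bounds: tuple[float, float] = (-190.0, -30.0)
    muscle_hu: tuple[float, float] = (55.0, 12.0)
    organ_hu: tuple[float, float] = (30.0, 15.0)
    disc_hu: tuple[float, float] = (80.0, 15.0)
    noise_sd: float = 10.0
    seed: int = 0
    subject_id: str = "phantom"

    def __post_init__(self):
        f_lo, f_hi = self.fat_bounds
        if not f_lo <= self.fat_hu[0] <= f_hi:
            raise ValueError("fat mean must lie inside the fat window")
        if not 40.0 <= self.muscle_hu[0] <= 100.0:
            raise ValueError("muscle mean must lie inside the muscle window")
        nx, ny, nz = self.shape
        if self.body_rx + 2 >= nx / 2 or self.body_ry + 2 >= ny / 2:
            raise ValueError("body ellipse does not fit the volume")
        if self.spine_offset_fraction() < 0.2:
            raise ValueError("spine does not fit inside the visceral cavity")
        if self.spine_radius <= self.cortical_thickness + 1:
            raise ValueError("trabecular core would be empty")

    def spine_offset_fraction(self) -> float:
        """Posterior offset of the spine center as a fraction of body_ry.

        At most 0.55 (anatomical posterior position), reduced when
        needed so the vertebra stays inside the visceral cavity: bone
        must never touch the SAT ring or the muscle wall, otherwise a
        single boundary misclassification next to the ~1200 HU shell
        corrupts the soft-tissue density statistics.
        """
        inner_ry = self.body_ry - self.sat_thickness - self.muscle_thickness
        max_offset = inner_ry - self.spine_radius - 1.5
        return min(0.55, max_offset / self.body_ry)

    def spine_center_y(self, ny: int) -> float:
        return (ny - 1) / 2.0 - self.spine_offset_fraction() * self.body_ry


def _ellipse(xx, yy, cx, cy, rx, ry):
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _vertebra_centers(spec: PhantomSpec):
    """SI centers of all vertebral bodies as (index_below_l1, z) pairs.

    Vertebrae with negative index are thoracic (superior to L1) and
    carry rib stubs — the anatomical cue that makes the L1 level
    identifiable in a projection, as in real scans.
    """
    nz = spec.shape[2]
    pitch = spec.vertebra_height + spec.disc_gap
    l1_z = int(round(spec.l1_fraction * nz))
    half = spec.vertebra_height // 2
    centers = []
    for m in range(-3, 5):  # a few thoracic vertebrae above L1, lumbar below
        z = l1_z - m * pitch
        if half + 1 <= z <= nz - half - 2:
            centers.append((m, z))
    l3_z = l1_z - 2 * pitch
    if (2, l3_z) not in centers:
        raise ValueError("L3 vertebra does not fit the volume; adjust geometry")
    if not any(m == -1 for m, _ in centers):
        raise ValueError("lowest ribbed (thoracic) vertebra does not fit the volume")
    return centers, l1_z, l3_z


def _material_slices(spec: PhantomSpec, rng: np.random.Generator):
    """2D material label map and spine masks shared by all axial slices."""
    nx, ny, _ = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    body = _ellipse(xx, yy, cx, cy, spec.body_rx, spec.body_ry)
    inner_sat = _ellipse(xx, yy, cx, cy, spec.body_rx - spec.sat_thickness,
                         spec.body_ry - spec.sat_thickness)
    inner_mus = _ellipse(xx, yy, cx, cy,
                         spec.body_rx - spec.sat_thickness - spec.muscle_thickness,
                         spec.body_ry - spec.sat_thickness - spec.muscle_thickness)

    spine_cy = spec.spine_center_y(ny)
    spine = (xx - cx) ** 2 + (yy - spine_cy) ** 2 <= spec.spine_radius ** 2
    r_trab = spec.spine_radius - spec.cortical_thickness
    trab = (xx - cx) ** 2 + (yy - spine_cy) ** 2 <= r_trab ** 2

    label = np.full((nx, ny), _AIR, dtype=np.int8)
    label[body] = _SAT
    label[inner_sat] = _MUSCLE
    label[inner_mus] = _ORGAN

    # visceral fat columns: random ellipses in the cavity, clear of the spine
    cavity = inner_mus & ~_dilate(spine, 2)
    vat = np.zeros_like(body)
    placed = 0
    for _ in range(50):
        if placed >= spec.n_vat_blobs:
            break
        bx = rng.uniform(cx - spec.body_rx * 0.6, cx + spec.body_rx * 0.6)
        by = rng.uniform(spine_cy + spec.spine_radius + 3, cy + spec.body_ry * 0.6)
        ra, rb = rng.uniform(3.5, 7.0), rng.uniform(3.5, 7.0)
        blob = _ellipse(xx, yy, bx, by, ra, rb) & cavity
        if blob.sum() >= 20:
            vat |= blob
            placed += 1
    label[vat] = _VAT
    label[spine] = _DISC  # replaced by bone at vertebral-body levels

    spine_masks = {
        "spine": spine,
        "cortical": spine & ~trab,
        "trabecular": trab,
    }
    return label, spine_masks


def _dilate(mask: np.ndarray, it: int) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_dilation(mask, iterations=it)


_HU_PARAMS = {
    _AIR: (AIR_HU, 0.0),
    _ORGAN: "organ_hu",
    _SAT: "fat_hu",
    _MUSCLE: "muscle_hu",
    _VAT: "fat_hu",
    _DISC: "disc_hu",
    _CORTICAL: "cortical_hu",
    _TRABECULAR: "trabecular_hu",
}


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, Annotation]:
    """Render one phantom volume and its exact annotation."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    label2d, spine_masks = _material_slices(spec, rng)
    centers, l1_z, l3_z = _vertebra_centers(spec)

    labels = np.repeat(label2d[:, :, None], nz, axis=2)
    half = spec.vertebra_height // 2
    cx_f = (nx - 1) / 2.0
    spine_cy = spec.spine_center_y(ny)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # rib shadows arc anterior to the column, so they stay visible in a
    # sagittal projection (the cue that identifies L1 = first rib-free level)
    rib = (np.abs(xx - cx_f) <= spec.spine_radius) & \
        (yy >= spine_cy + spec.spine_radius) & \
        (yy <= spine_cy + spec.spine_radius + spec.rib_length)
    for m, z in centers:
        sl = slice(z - half, z + half + 1)
        block = labels[:, :, sl]
        if m < 0:  # thoracic level: cortical rib stubs
            labels[:, :, z - 1:z + 2][rib, :] = _CORTICAL
            block = labels[:, :, sl]
        block[spine_masks["cortical"], :] = _CORTICAL
        block[spine_masks["trabecular"], :] = _TRABECULAR

    hu = np.empty((nx, ny, nz), dtype=np.float32)
    normals = rng.standard_normal((nx, ny, nz)).astype(np.float32)
    for code, params in _HU_PARAMS.items():
        mu, sd = params if isinstance(params, tuple) else getattr(spec, params)
        sel = labels == code
        hu[sel] = mu + sd * normals[sel]
    fat_sel = (labels == _SAT) | (labels == _VAT)
    hu[fat_sel] = np.clip(hu[fat_sel], *spec.fat_bounds)
    hu += spec.noise_sd * rng.standard_normal((nx, ny, nz)).astype(np.float32)

    vol = CTVolume(
        voxels=hu,
        spacing=(spec.spacing,) * 3,
        subject_id=spec.subject_id,
    )

    cx = (nx - 1) // 2
    spine_cy_idx = int(round(spec.spine_center_y(ny)))
    l1_mask = np.zeros((nx, ny), dtype=np.int32)
    l1_mask[spine_masks["trabecular"]] = 1
    l1_mask[spine_masks["cortical"]] = 2
    l3_labels2d = labels[:, :, l3_z]
    l3_mask = np.zeros((nx, ny), dtype=np.int32)
    l3_mask[l3_labels2d == _MUSCLE] = 1  # SMA
    l3_mask[l3_labels2d == _VAT] = 2
    l3_mask[l3_labels2d == _SAT] = 3

    ann = Annotation(
        l1_center=(cx, spine_cy_idx, l1_z),
        l3_center=(cx, spine_cy_idx, l3_z),
        l1_mask=l1_mask,
        l3_mask=l3_mask,
        subject_id=spec.subject_id,
    )
    return vol, ann


def truth_masks(ann: Annotation) -> tuple[LabelMask, LabelMask]:
    """Wrap an annotation's raw mask arrays as typed LabelMasks."""
    return (LabelMask(labels=ann.l1_mask, level="L1", subject_id=ann.subject_id),
            LabelMask(labels=ann.l3_mask, level="L3", subject_id=ann.subject_id))


def sample_spec(rng: np.random.Generator, subject_id: str, base: PhantomSpec | None = None) -> PhantomSpec:
    """Draw one subject's geometry from the population ranges.

    Ranges are expressed at the default 96×96×120 resolution and scaled
    to the base shape, so reduced-size phantoms stay proportionate.
    """
    base = base or PhantomSpec()
    sx, sy = base.shape[0] / 96.0, base.shape[1] / 96.0
    sz = base.shape[2] / 120.0
    sxy = min(sx, sy)
    return replace(
        base,
        body_rx=rng.uniform(30.0, 40.0) * sx,
        body_ry=rng.uniform(24.0, 31.0) * sy,
        sat_thickness=rng.uniform(4.0, 8.0) * sxy,
        muscle_thickness=rng.uniform(3.0, 5.0) * sxy,
        spine_radius=rng.uniform(7.0, 10.0) * sxy,
        cortical_thickness=max(1.0, base.cortical_thickness * sxy),
        vertebra_height=max(5, int(round(rng.integers(10, 14) * sz))),
        disc_gap=max(2, int(round(rng.integers(3, 5) * sz))),
        l1_fraction=rng.uniform(0.58, 0.66),
        n_vat_blobs=int(rng.integers(3, 7)),
        seed=int(rng.integers(0, 2**31 - 1)),
        subject_id=subject_id,
    )


def generate_dataset(n: int, seed: int = 0, base: PhantomSpec | None = None):
    """`n` phantoms with varied geometry; reproducible from `seed`."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        for _ in range(20):  # resample geometries that do not fit
            try:
                spec = sample_spec(rng, subject_id=f"phantom_{seed}_{i:03d}", base=base)
                out.append(generate_phantom(spec))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not sample a feasible phantom geometry")
    return out
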