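"""CT volume and annotation I/O.

Volumes are held as :class:`CTVolume`: a 3D array of Hounsfield units
with voxel spacing in mm, canonicalized to RAS+ axis order (axis 0
left→right, axis 1 posterior→anterior, axis 2 inferior→superior) so
that increasing slice index is always the superior direction.  NIfTI
files are read and written with nibabel; DICOM series directories are
read with pydicom, sorted by the projection of ImagePositionPatient on
the slice normal and rescaled to HU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

HU_PLAUSIBLE = (-1100.0, 4000.0)
AIR_HU = -1024.0


@dataclass
class CTVolume:
    """A canonicalized CT volume.

    Attributes
    ----------
    voxels : (nx, ny, nz) float array of HU values, RAS+ axis order.
    spacing : per-axis voxel size in mm, all strictly positive.
    orientation : axis-order tag; always ``"RAS"`` after canonicalization.
    subject_id : identifier used to pair volumes with annotations.
    affine : 4x4 voxel->world (mm) matrix kept for round-tripping files.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_PLAUSIBLE[0] or hi > HU_PLAUSIBLE[1]:
            warnings.warn(
                f"HU range [{lo:.0f}, {hi:.0f}] outside plausible {HU_PLAUSIBLE}",
                stacklevel=2,
            )
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def mm_position(self, index: float, axis: int = 2) -> float:
        """Physical position (mm, volume-local frame) of a voxel index."""
        return float(index) * self.spacing[axis]


@dataclass
class Annotation:
    """Ground-truth L1/L3 centers (voxel ijk) and optional slice masks."""

    l1_center: tuple[int, int, int]
    l3_center: tuple[int, int, int]
    l1_mask: np.ndarray | None = None
    l3_mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.l1_center = tuple(int(v) for v in self.l1_center)
        self.l3_center = tuple(int(v) for v in self.l3_center)
        if self.l1_center[2] <= self.l3_center[2]:
            raise ValueError(
                "L1 center must be superior to L3 center "
                f"(k={self.l1_center[2]} vs {self.l3_center[2]})"
            )


def canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    """Reorient a nibabel image to RAS+ (closest canonical)."""
    return nib.as_closest_canonical(img)


def load_volume(path: str | Path, subject_id: str | None = None) -> CTVolume:
    """Load a NIfTI file or a DICOM series directory as a canonical CTVolume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        img = _read_dicom_series(path)
    else:
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise IOError(f"cannot read volume {path}: {exc}") from exc
    img = canonicalize(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid spacing metadata {zooms}")
    return CTVolume(
        voxels=data,
        spacing=tuple(float(z) for z in zooms),
        orientation="RAS",
        subject_id=subject_id or path.stem.replace(".nii", ""),
        affine=np.asarray(img.affine),
    )


def save_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI (int16 when losslessly representable)."""
    data = vol.voxels
    if np.allclose(data, np.round(data)) and data.min() >= -32768 and data.max() <= 32767:
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _read_dicom_series(directory: Path) -> nib.Nifti1Image:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM slices in {directory}")

    first = slices[0]
    try:
        iop = np.array(first.ImageOrientationPatient, dtype=float)
        row, col = iop[:3], iop[3:]
    except Exception as exc:
        raise ValueError(f"{directory}: missing ImageOrientationPatient") from exc
    normal = np.cross(row, col)
    # order slices along the normal, not by InstanceNumber
    slices.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal)))

    arrs = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(arr * slope + intercept)
    stack = np.stack(arrs, axis=-1)  # (rows, cols, k)

    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise ValueError(f"{directory}: missing PixelSpacing")
    if len(slices) > 1:
        p0 = np.array(slices[0].ImagePositionPatient, dtype=float)
        p1 = np.array(slices[1].ImagePositionPatient, dtype=float)
        dz = float(np.dot(p1 - p0, normal))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))

    # DICOM pixel_array is (row, col); rows advance along `col` direction in
    # patient LPS space.  Build the LPS affine, convert to RAS by negating
    # the first two world axes.
    origin = np.array(first.ImagePositionPatient, dtype=float)
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col * float(ps[0])   # rows step
    affine_lps[:3, 1] = row * float(ps[1])   # cols step
    affine_lps[:3, 2] = normal * dz
    affine_lps[:3, 3] = origin
    flip = np.diag([-1.0, -1.0, 1.0, 1.0])
    affine_ras = flip @ affine_lps
    return nib.Nifti1Image(stack, affine_ras)


def resample_isotropic(vol: CTVolume, target_spacing: float = 1.0, order: int = 1) -> CTVolume:
    """Linearly resample a volume to isotropic voxels of `target_spacing` mm."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    zoom = np.array(vol.spacing) / target_spacing
    if np.allclose(zoom, 1.0):
        return replace(vol, voxels=vol.voxels.copy(),
                       spacing=(target_spacing,) * 3, affine=vol.affine.copy())
    out = ndimage.zoom(vol.voxels.astype(np.float32), zoom, order=order, mode="nearest")
    if min(out.shape) < 2:
        raise ValueError(f"resampling to {target_spacing} mm collapses the volume: {out.shape}")
    new_affine = vol.affine.copy()
    for ax in range(3):
        actual = vol.shape[ax] / out.shape[ax]  # input voxels per output voxel
        new_affine[:3, ax] = vol.affine[:3, ax] * actual
    return CTVolume(
        voxels=out,
        spacing=(target_spacing,) * 3,
        orientation=vol.orientation,
        subject_id=vol.subject_id,
        affine=new_affine,
    )


# ---------------------------------------------------------------------------
# annotation sidecars
def save_annotation(ann: Annotation, path: str | Path, mask_dir: str | Path | None = None,
                    spacing: tuple[float, float, float] | None = None) -> None:
    """Write an annotation JSON sidecar; masks (if present) as NIfTI."""
    path = Path(path)
    payload: dict = {
        "l1_center": list(ann.l1_center),
        "l3_center": list(ann.l3_center),
        "subject_id": ann.subject_id,
    }
    if mask_dir is not None and (ann.l1_mask is not None or ann.l3_mask is not None):
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        sp = spacing or (1.0, 1.0, 1.0)
        for level, mask in (("l1", ann.l1_mask), ("l3", ann.l3_mask)):
            if mask is None:
                continue
            mpath = mask_dir / f"{ann.subject_id}_{level}_mask.nii.gz"
            img = nib.Nifti1Image(mask.astype(np.int16)[..., None], np.diag([sp[0], sp[1], 1.0, 1.0]))
            nib.save(img, str(mpath))
            payload[f"{level}_mask"] = str(mpath)
    path.write_text(json.dumps(payload, indent=2))


def load_annotation(path: str | Path) -> Annotation:
    path = Path(path)
    payload = json.loads(path.read_text())
    masks = {}
    for level in ("l1", "l3"):
        mpath = payload.get(f"{level}_mask")
        if mpath:
            masks[f"{level}_mask"] = np.asanyarray(nib.load(mpath).dataobj)[..., 0].astype(np.int32)
    return Annotation(
        l1_center=tuple(payload["l1_center"]),
        l3_center=tuple(payload["l3_center"]),
        subject_id=payload.get("subject_id", path.stem),
        **masks,
    )
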