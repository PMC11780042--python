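"""End-to-end orchestration: locate L1/L3, segment the two axial
slices, quantify the seven indices; plus the k-fold training harness
and model persistence with manifest checking."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .evaluation import kfold_split, aggregate_folds, localization_summary, pre
from .indices import INDEX_COLUMNS, compute_report
from .localization import HeatmapLocalizer, localization_error
from .phantom import truth_masks
from .segmentation import CLASS_VOCAB, SlabSlice, SliceSegmenter, to_grid, vdsc
from .volume_io import Annotation, CTVolume, resample_isotropic

log = logging.getLogger("compositia")


def build_localizer(config: PipelineConfig) -> HeatmapLocalizer:
    return HeatmapLocalizer(
        sigma=config.sigma, windows=config.localization_windows,
        grid=tuple(config.localization_grid), projection=config.projection,
        slab_fraction=config.slab_fraction,
        base_filters=config.localizer_base_filters, epochs=config.localizer_epochs,
        batch_size=config.localizer_batch_size, lr=config.localizer_lr,
        val_fraction=config.val_fraction, patience=config.patience, seed=config.seed,
    )


def build_segmenter(level: str, config: PipelineConfig) -> SliceSegmenter:
    return SliceSegmenter(
        level=level, base_filters=config.segmenter_base_filters,
        epochs=config.segmenter_epochs, batch_size=config.segmenter_batch_size,
        lr=config.segmenter_lr, val_fraction=config.val_fraction,
        patience=config.patience, seed=config.seed,
    )


def extract_slice(vol: CTVolume, k: int, level: str, slice_grid: int = 512) -> SlabSlice:
    """Axial slice at index k as a model-ready SlabSlice.

    Volumes whose in-plane grid is already square and divisible by 16
    are used natively; others are center-padded/cropped to `slice_grid`.
    """
    if not 0 <= k < vol.shape[2]:
        raise ValueError(f"slice index {k} outside volume of {vol.shape[2]} slices")
    hu = vol.voxels[:, :, k]
    if not (hu.shape[0] == hu.shape[1] and hu.shape[0] % 16 == 0):
        hu = to_grid(hu, slice_grid)
    return SlabSlice(hu=hu, spacing=(vol.spacing[0], vol.spacing[1]), level=level,
                     subject_id=vol.subject_id)


@dataclass
class CompositIAPipeline:
    """Trained localizer + two segmenters applied end to end."""

    localizer: HeatmapLocalizer
    seg_l1: SliceSegmenter
    seg_l3: SliceSegmenter
    config: PipelineConfig

    def run(self, vol: CTVolume, debug_dir: str | Path | None = None):
        """-> (CenterPrediction, (l1 LabelMask, l3 LabelMask), IndexReport).

        A localization failure raises DetectionFailure; there is no
        silent fallback.
        """
        t0 = time.perf_counter()
        iso = resample_isotropic(vol, self.config.isotropic_spacing)
        hm, record = self.localizer.predict_heatmap(iso)
        from .localization import extract_centers

        centers = extract_centers(hm, record, iso)
        log.info("localized %s: L1 slice %d, L3 slice %d (%.2f s)",
                 vol.subject_id, centers.l1_slice, centers.l3_slice,
                 time.perf_counter() - t0)
        sl_l1 = extract_slice(iso, centers.l1_slice, "L1", self.config.slice_grid)
        sl_l3 = extract_slice(iso, centers.l3_slice, "L3", self.config.slice_grid)
        m_l1 = self.seg_l1.predict_one(sl_l1)
        m_l3 = self.seg_l3.predict_one(sl_l3)
        report = compute_report(m_l1, sl_l1.hu, m_l3, sl_l3.hu,
                                spacing=sl_l1.spacing, subject_id=vol.subject_id)
        if debug_dir is not None:
            self._dump_debug(Path(debug_dir), vol.subject_id, record, hm, sl_l1, sl_l3, m_l1, m_l3)
        return centers, (m_l1, m_l3), report

    def _dump_debug(self, d, sid, record, hm, sl_l1, sl_l3, m_l1, m_l3):
        d.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(d / f"{sid}_intermediates.npz",
                            projection=record.channels, heatmap=hm.values,
                            l1_hu=sl_l1.hu, l3_hu=sl_l3.hu,
                            l1_mask=m_l1.labels, l3_mask=m_l3.labels)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config_digest": self.config.digest(),
            "localization_grid": list(self.config.localization_grid),
            "class_vocab": {k: list(v) for k, v in CLASS_VOCAB.items()},
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.config.to_yaml(d / "config.yaml")
        np.savez_compressed(d / "localizer.npz", **self.localizer.model_.state_dict())
        np.savez_compressed(d / "seg_l1.npz", **self.seg_l1.model_.state_dict())
        np.savez_compressed(d / "seg_l3.npz", **self.seg_l3.model_.state_dict())

    @classmethod
    def load(cls, directory: str | Path, config: PipelineConfig | None = None) -> "CompositIAPipeline":
        d = Path(directory)
        stored = PipelineConfig.from_yaml(d / "config.yaml")
        config = config or stored
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest["config_digest"] != config.digest():
            raise ValueError(
                "model manifest does not match the supplied configuration; "
                "refusing to mix incompatible weights")
        pipe = cls(localizer=build_localizer(config),
                   seg_l1=build_segmenter("L1", config),
                   seg_l3=build_segmenter("L3", config), config=config)
        # build untrained models of the right shape, then load weights
        from .nn import MultiResUNet, UNet

        pipe.localizer.model_ = MultiResUNet(
            in_ch=len(config.localization_windows),
            base_filters=config.localizer_base_filters, seed=config.seed)
        pipe.localizer.model_.load_state_dict(dict(np.load(d / "localizer.npz")))
        pipe.localizer.model_.eval()
        for seg, name, n_cls, in_ch in ((pipe.seg_l1, "seg_l1", 3, 1), (pipe.seg_l3, "seg_l3", 4, 3)):
            seg.model_ = UNet(in_ch=in_ch, n_classes=n_cls,
                              base_filters=config.segmenter_base_filters, seed=config.seed)
            seg.model_.load_state_dict(dict(np.load(d / f"{name}.npz")))
            seg.model_.eval()
        return pipe


def run_pipeline(vol: CTVolume, pipeline: CompositIAPipeline,
                 debug_dir: str | Path | None = None):
    """Functional wrapper over :meth:`CompositIAPipeline.run`."""
    return pipeline.run(vol, debug_dir=debug_dir)


# ---------------------------------------------------------------------------
def fit_pipeline(dataset, config: PipelineConfig) -> CompositIAPipeline:
    """Train the three models on (CTVolume, Annotation) pairs."""
    vols = [resample_isotropic(v, config.isotropic_spacing) for v, _ in dataset]
    anns = [a for _, a in dataset]
    scale = np.array([v.spacing for v, _ in dataset]) / config.isotropic_spacing
    anns = [_rescale_annotation(a, s) for a, s in zip(anns, scale)]

    localizer = build_localizer(config).fit(vols, anns)
    l1_slices, l1_masks, l3_slices, l3_masks = [], [], [], []
    for v, a in zip(vols, anns):
        tm_l1, tm_l3 = truth_masks(a)
        l1_slices.append(extract_slice(v, a.l1_center[2], "L1", config.slice_grid))
        l3_slices.append(extract_slice(v, a.l3_center[2], "L3", config.slice_grid))
        l1_masks.append(tm_l1)
        l3_masks.append(tm_l3)
    seg_l1 = build_segmenter("L1", config).fit(l1_slices, l1_masks)
    seg_l3 = build_segmenter("L3", config).fit(l3_slices, l3_masks)
    return CompositIAPipeline(localizer=localizer, seg_l1=seg_l1, seg_l3=seg_l3, config=config)


def _rescale_annotation(ann: Annotation, scale) -> Annotation:
    """Map annotation voxel coordinates through an isotropic resampling."""
    if np.allclose(scale, 1.0):
        return ann
    def rs(c):
        return tuple(int(round(ci * si)) for ci, si in zip(c, scale))
    return Annotation(l1_center=rs(ann.l1_center), l3_center=rs(ann.l3_center),
                      l1_mask=ann.l1_mask, l3_mask=ann.l3_mask, subject_id=ann.subject_id)


def evaluate_pipeline(pipeline: CompositIAPipeline, dataset) -> dict:
    """Stage metrics on held-out (CTVolume, Annotation) pairs.

    Localization errors come from the localizer; Dice is scored on the
    ground-truth slice (so segmentation is assessed independently of
    localization); PRE compares the full pipeline's indices against the
    ground-truth report.
    """
    from .indices import UndefinedStatisticError
    from .localization import DetectionFailure

    cfg = pipeline.config
    err_l1, err_l3 = [], []
    dice: dict[str, list[float]] = {c: [] for lvl in ("L1", "L3") for c in CLASS_VOCAB[lvl][1:]}
    pre_rows = []
    n_failures = 0
    for vol, ann in dataset:
        iso = resample_isotropic(vol, cfg.isotropic_spacing)
        ann_iso = _rescale_annotation(ann, np.array(vol.spacing) / cfg.isotropic_spacing)
        try:
            pred, (m_l1, m_l3), report = pipeline.run(vol)
        except (DetectionFailure, UndefinedStatisticError):
            # recorded, not silently recovered; localization/PRE metrics
            # are then computed over the detected cases only
            n_failures += 1
            pred = report = None
        if pred is not None:
            d1, d3, _, _ = localization_error(pred, ann_iso, iso)
            err_l1.append(d1)
            err_l3.append(d3)
        tm_l1, tm_l3 = truth_masks(ann_iso)
        sl_l1 = extract_slice(iso, ann_iso.l1_center[2], "L1", cfg.slice_grid)
        sl_l3 = extract_slice(iso, ann_iso.l3_center[2], "L3", cfg.slice_grid)
        gm_l1 = pipeline.seg_l1.predict_one(sl_l1)
        gm_l3 = pipeline.seg_l3.predict_one(sl_l3)
        for cname in CLASS_VOCAB["L1"][1:]:
            dice[cname].append(vdsc(gm_l1, tm_l1, cname))
        for cname in CLASS_VOCAB["L3"][1:]:
            dice[cname].append(vdsc(gm_l3, tm_l3, cname))
        if report is not None:
            truth_report = compute_report(tm_l1, sl_l1.hu, tm_l3, sl_l3.hu,
                                          spacing=sl_l1.spacing, subject_id=ann.subject_id)
            pre_rows.append({c: pre(p, t) for c, p, t in
                             zip(INDEX_COLUMNS, report.values(), truth_report.values())})

    if err_l1:
        mae1, sd1, pct1 = localization_summary(err_l1)
        mae3, sd3, pct3 = localization_summary(err_l3)
    else:
        mae1 = sd1 = pct1 = mae3 = sd3 = pct3 = float("nan")
    out = {
        "mae_l1_mm": mae1, "mae_l3_mm": mae3,
        "sd_l1_mm": sd1, "sd_l3_mm": sd3,
        "pct_under_10mm_l1": pct1, "pct_under_10mm_l3": pct3,
        "n_detection_failures": float(n_failures),
    }
    for cname, vals in dice.items():
        out[f"dice_{cname}"] = float(np.mean(vals))
    for col in INDEX_COLUMNS:
        out[f"pre_{col}"] = float(np.mean([row[col] for row in pre_rows])) if pre_rows else float("nan")
    return out


def train_all(dataset, config: PipelineConfig):
    """k-fold training/evaluation plus a final train-on-all pipeline.

    Returns ``(per_fold, aggregate, final_pipeline)`` where per_fold is a
    list of metric dicts (one per fold), aggregate maps each metric to
    (mean, population sd) over folds, and final_pipeline is trained on
    the complete dataset.
    """
    if len(dataset) < config.k:
        raise ValueError(f"dataset of {len(dataset)} subjects is smaller than k={config.k}")
    index = list(range(len(dataset)))
    per_fold = []
    for train_ids, test_ids in kfold_split(index, k=config.k, seed=config.seed):
        pipe = fit_pipeline([dataset[i] for i in train_ids], config)
        per_fold.append(evaluate_pipeline(pipe, [dataset[i] for i in test_ids]))
    aggregate = {k: aggregate_folds([f[k] for f in per_fold]) for k in per_fold[0]}
    final = fit_pipeline(dataset, config)
    return per_fold, aggregate, final
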