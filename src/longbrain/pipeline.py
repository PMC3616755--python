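"""End-to-end orchestration: preprocess -> extract -> segment -> label -> roi.

Each stage writes its artifacts under ``<out>/<stage>/`` together with a
``done.json`` marker (parameter echo + wall time); a rerun skips stages
whose markers and outputs are present, so the pipeline is resumable from the
last completed stage.  A single-timepoint series runs the 3D reduction of
every stage.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import extract as ex
from . import labeling as lb
from . import levelset as ls
from . import preprocess as pp
from . import roi as roimod
from .grid import (ImageGrid, StandardSpace, read_volume, resample_standard,
                   to_ras, write_volume)
from .registration import apply_affine, groupwise_affine, warp_map_pair

STAGES = ("preprocess", "extract", "segment", "label", "roi")

_ALLOWED_KEYS = {
    "standard_shape", "standard_spacing", "seed", "subject",
    "times_months", "preprocess", "extract", "segment", "label", "roi",
}


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected."""

    standard_shape: tuple = (96, 96, 96)
    standard_spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    subject: str = "subject"
    times_months: tuple = (0.0, 6.0, 12.0, 24.0)
    preprocess: dict = field(default_factory=dict)
    extract: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    label: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def standard(self) -> StandardSpace:
        return StandardSpace(tuple(self.standard_shape),
                             tuple(self.standard_spacing))


def _done(stage_dir: Path) -> bool:
    return (stage_dir / "done.json").exists()


def _mark(stage_dir: Path, params: dict, t0: float) -> None:
    (stage_dir / "done.json").write_text(json.dumps(
        {"params": params, "seconds": round(time.time() - t0, 2)}, indent=2,
        default=str))


def _load_series(stage_dir: Path, suffix: str) -> list[ImageGrid]:
    paths = sorted(stage_dir.glob(f"*{suffix}"))
    if not paths:
        raise FileNotFoundError(f"no '*{suffix}' outputs in {stage_dir}")
    return [read_volume(p) for p in paths]


def run_pipeline(config: PipelineConfig, series_paths: list, atlas_paths: dict,
                 out_dir, resume: bool = True) -> dict:
    """Run all stages in order; returns a summary dict (also written as
    ``summary.json``).  ``atlas_paths`` must name ``template``,
    ``probability``, ``labels`` and the tissue priors ``csf``/``gm``/``wm``;
    ``cerebellum`` is optional.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    atlas = {k: read_volume(p) for k, p in atlas_paths.items()}

    # ---- preprocess
    sdir = out / "preprocess"
    if not (resume and _done(sdir)):
        sdir.mkdir(exist_ok=True)
        t0 = time.time()
        series = []
        for p in series_paths:
            img = read_volume(p)
            img = to_ras(img)
            series.append(resample_standard(img, config.standard))
        masks = None
        matched, fields, ks = pp.preprocess_series(
            series, masks,
            bias_iters=config.preprocess.get("bias_iters", 30),
            n_quantiles=config.preprocess.get("quantiles", 128))
        for i, (m, f) in enumerate(zip(matched, fields)):
            write_volume(m, sdir / f"t{i:02d}_hm.nii.gz")
            write_volume(m.like(np.exp(f.log_field).astype(np.float32)),
                         sdir / f"t{i:02d}_biasfield.nii.gz")
        (sdir / "ks_statistics.json").write_text(json.dumps(ks))
        _mark(sdir, config.preprocess, t0)
    summary["stages"]["preprocess"] = "done"

    # ---- extract
    edir = out / "extract"
    if not (resume and _done(edir)):
        edir.mkdir(exist_ok=True)
        t0 = time.time()
        series = _load_series(out / "preprocess", "_hm.nii.gz")
        w = ex.ForceWeights(**config.extract.get("weights", {}))
        res = ex.extract_series(series, atlas["template"],
                                atlas["probability"], w=w)
        masks = res.brain_masks
        if "cerebellum" in atlas:
            brain_template = atlas["template"].like(np.where(
                atlas["probability"].voxels >= 0.5,
                atlas["template"].voxels, 0.0).astype(np.float32))
            masks = ex.remove_cerebellum(res.brain_images, masks,
                                         brain_template,
                                         atlas["cerebellum"])
        for i, (msk, img) in enumerate(zip(masks, series)):
            write_volume(msk, edir / f"t{i:02d}_brainmask.nii.gz",
                         dtype=np.uint8)
            write_volume(img.like(np.where(msk.voxels > 0, img.voxels, 0.0)
                                  .astype(np.float32)),
                         edir / f"t{i:02d}_brain.nii.gz")
        np.save(edir / "affines.npy", np.asarray(res.affines))
        _mark(edir, config.extract, t0)
    summary["stages"]["extract"] = "done"

    # ---- segment
    gdir = out / "segment"
    if not (resume and _done(gdir)):
        gdir.mkdir(exist_ok=True)
        t0 = time.time()
        brains = _load_series(edir, "_brain.nii.gz")
        brain_template = atlas["template"].like(np.where(
            atlas["probability"].voxels >= 0.5, atlas["template"].voxels,
            0.0).astype(np.float32))
        prior_list = []
        for b in brains:
            warped = {}
            _, pr = warp_map_pair(
                brain_template,
                atlas["csf"], b)
            warped["csf"] = pr
            for name in ("gm", "wm"):
                _, pr = warp_map_pair(brain_template, atlas[name], b)
                warped[name] = pr
            prior_list.append(warped)
        w = ls.SegWeights(**config.segment.get("weights", {}))
        if config.segment.get("no_temporal"):
            w.lambda_temporal_thick = 0.0
        labels, thicks = ls.segment_series_4d(
            brains, prior_list, w,
            outer_iters=config.segment.get("outer_iters", 2))
        for i, (lab, th) in enumerate(zip(labels, thicks)):
            write_volume(lab, gdir / f"t{i:02d}_seg.nii.gz", dtype=np.uint8)
            write_volume(lab.like(th.thickness),
                         gdir / f"t{i:02d}_thickness.nii.gz")
        _mark(gdir, config.segment, t0)
    summary["stages"]["segment"] = "done"

    # ---- label
    ldir = out / "label"
    if not (resume and _done(ldir)):
        ldir.mkdir(exist_ok=True)
        t0 = time.time()
        brains = _load_series(edir, "_brain.nii.gz")
        ref = brains[0]
        if len(brains) >= 2:
            to_common, _ = groupwise_affine(brains)
        else:
            to_common = [np.eye(4)]
        aligned = [apply_affine(b, np.linalg.inv(a), ref)
                   for b, a in zip(brains, to_common)]
        if len(aligned) >= 2:
            fields, mean = lb.groupwise_register(
                aligned, rounds=config.label.get("rounds", 3),
                bandwidth=config.label.get("bandwidth", 1.0))
        else:
            fields, mean = [lb.DeformationField.zero(ref)], aligned[0]
        brain_template = atlas["template"].like(np.where(
            atlas["probability"].voxels >= 0.5, atlas["template"].voxels,
            0.0).astype(np.float32))
        f_m2a = lb.register_atlas_to_mean(brain_template, mean)
        for i, (f_m2t, a) in enumerate(zip(fields, to_common)):
            f_t2m = f_m2t.invert()
            f_t2a = lb.compose(f_t2m, f_m2a)
            lab_common = lb.propagate_labels(atlas["labels"], f_t2a)
            lab_native = apply_affine(lab_common, a, brains[i], order=0)
            msk = read_volume(edir / f"t{i:02d}_brainmask.nii.gz")
            lab_native.voxels = np.where(msk.voxels > 0, lab_native.voxels,
                                         0).astype(np.int16)
            write_volume(lab_native, ldir / f"t{i:02d}_labels.nii.gz",
                         dtype=np.int16)
        _mark(ldir, config.label, t0)
    summary["stages"]["label"] = "done"

    # ---- roi
    rdir = out / "roi"
    if not (resume and _done(rdir)):
        rdir.mkdir(exist_ok=True)
        t0 = time.time()
        labels = _load_series(ldir, "_labels.nii.gz")
        segs = _load_series(gdir, "_seg.nii.gz")
        roi_defs = config.roi.get("rois")
        if not roi_defs:
            ids = sorted(int(v) for v in
                         np.unique(atlas["labels"].voxels) if v > 0)
            roi_defs = {f"roi{v:02d}": [v] for v in ids}
        tissue = config.roi.get("tissue_id")
        table = roimod.build_table(
            config.subject, list(config.times_months)[:len(labels)],
            labels, roi_defs,
            seg_series=segs if tissue is not None else None,
            tissue_id=tissue)
        roimod.export_table(table, rdir / "volumes.csv")
        _mark(rdir, config.roi, t0)
    summary["stages"]["roi"] = "done"

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
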