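"""ROI volumetry over time: volumes, tissue-masked volumes, trends, export.

A "ROI" is a named union of basic atlas labels (a parcel or combination of
parcels, e.g. a hippocampus label masked with the GM segmentation).
Longitudinal volumes are normalized by baseline and summarized by an
ordinary-least-squares linear trend in units of (normalized volume)/month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ImageGrid

TABLE_COLUMNS = ["subject", "timepoint_months", "roi_id", "roi_name",
                 "volume_mm3", "normalized_volume"]


@dataclass
class ROITable:
    """Long-format volumetry table; one row per (subject, timepoint, ROI)."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TABLE_COLUMNS))

    def add(self, subject: str, timepoint: float, roi_id: int, roi_name: str,
            volume: float, normalized: float) -> None:
        if volume < 0:
            raise ValueError("volumes must be nonnegative")
        self.frame.loc[len(self.frame)] = [subject, float(timepoint),
                                           int(roi_id), roi_name,
                                           float(volume), float(normalized)]


def measure_volumes(labels: ImageGrid, roi_defs: dict) -> dict:
    """Volume (mm^3) of each ROI, a union of basic label ids.

    Shared voxels between overlapping basic labels are impossible (a voxel
    has one label), so union volumes follow by summing unique-voxel counts.
    """
    lab = np.asarray(labels.voxels)
    present = set(np.unique(lab).tolist())
    voxel_volume = float(np.prod(labels.spacing))
    counts = {int(v): int(c) for v, c in
              zip(*np.unique(lab, return_counts=True))}
    out = {}
    for roi_id, basics in roi_defs.items():
        basics = set(int(b) for b in basics)
        unknown = basics - present
        if unknown:
            raise KeyError(f"ROI {roi_id!r} references absent basic "
                           f"label ids {sorted(unknown)}")
        out[roi_id] = voxel_volume * sum(counts.get(b, 0) for b in basics)
    return out


def mask_roi_with_tissue(labels: ImageGrid, seg: ImageGrid,
                         roi_ids, tissue_id: int) -> ImageGrid:
    """Voxelwise AND of ROI membership with a tissue class (e.g. the
    hippocampus parcel masked by the GM map)."""
    if labels.shape != seg.shape:
        raise ValueError("label and segmentation geometry differ")
    lab = np.asarray(labels.voxels)
    tis = np.asarray(seg.voxels)
    roi = np.isin(lab, np.asarray(list(roi_ids)))
    return labels.like((roi & (tis == tissue_id)).astype(np.uint8))


def normalize_and_trend(volumes, times):
    """Baseline-normalize a volume series and fit an OLS linear trend.

    Baseline is the earliest timepoint; the slope is in units of normalized
    volume per month.  Returns (normalized array, slope, intercept).
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if volumes.shape != times.shape:
        raise ValueError("volumes and times must align")
    base = volumes[np.argmin(times)]
    if base <= 0:
        raise ValueError("baseline volume must be positive")
    normalized = volumes / base
    if len(volumes) < 2:
        return normalized, 0.0, float(normalized[0])
    slope, intercept = np.polyfit(times, normalized, 1)
    return normalized, float(slope), float(intercept)


def build_table(subject: str, times, label_series, roi_defs: dict,
                roi_names: dict | None = None,
                seg_series=None, tissue_id: int | None = None) -> ROITable:
    """Volumetry table for one subject's labeled series.

    With ``seg_series`` and ``tissue_id`` given, each ROI is additionally
    restricted to that tissue class before measurement.
    """
    table = ROITable()
    roi_names = roi_names or {}
    per_roi: dict = {rid: [] for rid in roi_defs}
    for labels, seg in zip(label_series,
                           seg_series or [None] * len(label_series)):
        if seg is not None and tissue_id is not None:
            vox_vol = float(np.prod(labels.spacing))
            vols = {}
            for rid, basics in roi_defs.items():
                m = mask_roi_with_tissue(labels, seg, basics, tissue_id)
                vols[rid] = float(m.voxels.sum()) * vox_vol
        else:
            vols = measure_volumes(labels, roi_defs)
        for rid in roi_defs:
            per_roi[rid].append(vols[rid])
    for rid, series in per_roi.items():
        normalized, _, _ = normalize_and_trend(series, times)
        for t, v, n in zip(times, series, normalized):
            table.add(subject, t, rid if isinstance(rid, int) else -1,
                      str(roi_names.get(rid, rid)), v, n)
    return table


def export_table(table: ROITable, path) -> None:
    """Write the table as CSV with the fixed header, >= 6 significant
    digits, round-trippable through :func:`import_table`."""
    table.frame.to_csv(path, index=False, float_format="%.8g")


def import_table(path) -> ROITable:
    frame = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    return ROITable(frame[TABLE_COLUMNS])
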