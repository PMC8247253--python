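"""Lesion-mask algebra: NAWM construction, FW-quartile subregions, regional
metric extraction, ICV-corrected volumes and lesion probability maps.

NAWM (normal-appearing white matter) is the WM mask minus the WMH mask,
eroded to keep partial-volume voxels near lesion and tissue borders out of
the reference region. WMH masks are split into four subregions FWq1..FWq4 by
the within-lesion quartiles of the free-water map, FWq1 holding the lowest
25% of FW values. A lesion probability map (LPM) is the voxelwise average of
binary lesion masks across subjects on the shared grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskSet",
    "LPMVolume",
    "make_nawm",
    "split_fw_quartiles",
    "regional_means",
    "corrected_volume",
    "build_lpm",
]

log = logging.getLogger(__name__)


@dataclass
class MaskSet:
    """Binary region masks for one subject: WM, WMH, NAWM and FWq1..FWq4."""

    wm: np.ndarray
    wmh: np.ndarray
    nawm: np.ndarray
    fwq: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    def validate(self) -> None:
        assert not np.any(self.nawm & self.wmh), "NAWM overlaps WMH"
        assert not np.any(self.nawm & ~self.wm), "NAWM outside WM"
        union = np.zeros_like(self.wmh)
        for i, q in enumerate(self.fwq):
            for other in self.fwq[i + 1 :]:
                assert not np.any(q & other), "FWq sub-masks overlap"
            union |= q
        assert np.array_equal(union, self.wmh), "FWq sub-masks do not partition WMH"

    def regions(self) -> dict:
        return {
            "WMH": self.wmh,
            "NAWM": self.nawm,
            **{f"FWq{i + 1}": q for i, q in enumerate(self.fwq)},
        }


@dataclass
class LPMVolume:
    """Lesion probability map: per-voxel lesion frequency across subjects."""

    probability: np.ndarray
    n_subjects: int
    peak_probability: float
    peak_cluster_size: float  # mm^3


def make_nawm(wm: np.ndarray, wmh: np.ndarray, erode_voxels: int = 2) -> np.ndarray:
    """(WM - WMH) eroded ``erode_voxels`` times with a 6-connected element."""
    wm = wm.astype(bool)
    wmh = wmh.astype(bool)
    if wm.shape != wmh.shape:
        raise ValueError("WM and WMH masks must share a grid")
    if np.any(wmh & ~wm):
        log.warning("WMH mask extends outside WM; intersecting")
        wmh = wmh & wm
    nawm = wm & ~wmh
    if erode_voxels > 0 and nawm.any():
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        nawm = ndimage.binary_erosion(nawm, struct, iterations=erode_voxels)
    if not nawm.any():
        log.warning("NAWM mask is empty after erosion")
    return nawm


def split_fw_quartiles(fw: np.ndarray, wmh: np.ndarray):
    """Split WMH into FWq1..FWq4 at the 25/50/75th FW percentiles.

    Voxels are assigned by half-open intervals [q_{k-1}, q_k), the top
    interval closed; a voxel exactly at a boundary goes to the lower
    quartile. With all FW values equal, everything lands in FWq1.
    """
    wmh = wmh.astype(bool)
    n = int(wmh.sum())
    if n < 4:
        raise ValueError(f"WMH mask has {n} voxels; need at least 4 for quartiles")
    vals = fw[wmh]
    if np.any(~np.isfinite(vals)):
        raise ValueError("FW map is undefined (non-finite) inside the WMH mask")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    # ties at a boundary go to the lower quartile, so each interval is
    # closed above: (-inf, q1], (q1, q2], (q2, q3], (q3, inf)
    sels = [vals <= q1, (vals > q1) & (vals <= q2), (vals > q2) & (vals <= q3), vals > q3]
    out = []
    for sel in sels:
        m = np.zeros_like(wmh)
        m[wmh] = sel
        out.append(m)
    return tuple(out)


def regional_means(metric_maps: dict, masks: MaskSet) -> dict:
    """One row of per-region metric means: {"metric_region": value, ...}.

    Non-finite voxels are excluded from each mean (and counted in
    ``"<metric>_<region>_n_missing"`` if any); empty regions yield NaN.
    """
    row = {}
    for region_name, region in masks.regions().items():
        for metric_name, mp in metric_maps.items():
            key = f"{metric_name}_{region_name}"
            vals = mp[region.astype(bool)]
            finite = np.isfinite(vals)
            if vals.size == 0 or not finite.any():
                log.warning("region %s empty for metric %s", region_name, metric_name)
                row[key] = np.nan
                continue
            row[key] = float(vals[finite].mean())
            if (~finite).any():
                row[f"{key}_n_missing"] = int((~finite).sum())
    return row


def corrected_volume(mask: np.ndarray, voxel_size, icv: float) -> float:
    """Mask volume as a fraction of intracranial volume (mm^3 over mm^3)."""
    if icv <= 0:
        raise ValueError("ICV must be positive")
    voxel_volume = float(np.prod(voxel_size))
    return float(mask.astype(bool).sum()) * voxel_volume / icv


def build_lpm(masks: list, voxel_size=(1.0, 1.0, 1.0)) -> LPMVolume:
    """Voxelwise mean of binary lesion masks across subjects.

    The peak cluster is the largest 26-connected component of voxels within
    1e-9 of the peak probability, reported as a volume in mm^3.
    """
    if len(masks) == 0:
        raise ValueError("need at least one subject mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"grid mismatch: {m.shape} vs {shape}")
    stack = np.stack([m.astype(float) for m in masks])
    prob = stack.mean(axis=0)
    peak = float(prob.max())
    at_peak = prob >= peak - 1e-9
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, nlab = ndimage.label(at_peak, structure=struct)
    sizes = ndimage.sum_labels(np.ones(shape), labels, index=np.arange(1, nlab + 1))
    cluster = float(sizes.max()) * float(np.prod(voxel_size)) if nlab else 0.0
    return LPMVolume(prob, len(masks), peak, cluster)
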