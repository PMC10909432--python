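"""Hypointense-voxel quantification of MPIO binding.

The statistic: estimate the mean and standard deviation of the signal in
the contralateral (normal) striatum, flag every voxel whose intensity falls
*more than* ``k`` standard deviations below that mean (strict inequality;
k = 3 by default), count flagged voxels per hemisphere for the pre- and
post-contrast scans, and report the post-minus-pre difference per
hemisphere. Because tumours contain naturally hypointense tissue that is
present in both scans, the difference isolates the contrast-induced
(MPIO) component; an apparently negative difference is attributed to the
technique's noise floor and clipped to zero.

Each scan derives its own threshold from its own contralateral ROI; no
inter-scan intensity normalisation is applied. The standard deviation uses
the sample (n−1) definition. Counting is voxelwise — no connectivity or
cluster filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiMaskSet",
    "RoiStats",
    "HypoResult",
    "NoiseFloor",
    "roi_stats",
    "detect_hypointense",
    "mpio_induced_voxels",
    "noise_floor",
    "cohort_table",
]


@dataclass
class RoiMaskSet:
    """Co-registered ipsilateral (tumour-bearing) and contralateral masks."""

    ipsi: np.ndarray
    contra: np.ndarray

    def __post_init__(self) -> None:
        self.ipsi = np.asarray(self.ipsi, dtype=bool)
        self.contra = np.asarray(self.contra, dtype=bool)
        if self.ipsi.shape != self.contra.shape:
            raise ValueError("ipsi and contra masks must share a grid")
        if not self.ipsi.any() or not self.contra.any():
            raise ValueError("both masks must be non-empty")
        if np.any(self.ipsi & self.contra):
            raise ValueError("ipsi and contra masks overlap")


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    n_voxels: int


@dataclass
class HypoResult:
    """Per-case hypointensity quantification (both hemispheres)."""

    threshold_pre: float
    threshold_post: float
    n_hypo_ipsi_pre: int
    n_hypo_ipsi_post: int
    n_hypo_contra_pre: int
    n_hypo_contra_post: int
    diff_raw_ipsi: int
    diff_clipped_ipsi: int
    diff_raw_contra: int
    diff_clipped_contra: int
    k: float = 3.0
    hypo_masks: dict = field(default_factory=dict, repr=False)


def roi_stats(volume: np.ndarray, mask: np.ndarray, ddof: int = 1) -> RoiStats:
    """Mean and sample standard deviation of the voxels under a mask."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(volume, dtype=float)[mask]
    if values.size == 0:
        raise ValueError("ROI mask is empty")
    if values.size <= ddof:
        raise ValueError(f"need more than {ddof} voxels for the SD (got {values.size})")
    return RoiStats(mean=float(values.mean()), sd=float(values.std(ddof=ddof)), n_voxels=int(values.size))


def detect_hypointense(
    volume: np.ndarray,
    contra_stats: RoiStats,
    target_mask: np.ndarray,
    k: float = 3.0,
) -> tuple[int, np.ndarray]:
    """Flag voxels more than ``k`` SD below the contralateral mean.

    A voxel is hypointense iff ``value < mean - k*sd`` (strict). Returns the
    count within ``target_mask`` and the boolean hypointensity mask
    restricted to it.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    threshold = contra_stats.mean - k * contra_stats.sd
    flagged = (np.asarray(volume, dtype=float) < threshold) & np.asarray(target_mask, dtype=bool)
    return int(flagged.sum()), flagged


def mpio_induced_voxels(
    pre_volume: np.ndarray,
    post_volume: np.ndarray,
    masks: RoiMaskSet,
    k: float = 3.0,
    keep_masks: bool = False,
) -> HypoResult:
    """Post-minus-pre hypointense-voxel difference per hemisphere.

    Each scan is thresholded against its own contralateral statistics.
    ``diff_clipped = max(diff_raw, 0)`` implements the zero-assignment rule
    for apparently negative differences.
    """
    pre_volume = np.asarray(pre_volume, dtype=float)
    post_volume = np.asarray(post_volume, dtype=float)
    if pre_volume.shape != post_volume.shape or pre_volume.shape != masks.ipsi.shape:
        raise ValueError("pre/post volumes and masks must share a grid")
    stats_pre = roi_stats(pre_volume, masks.contra)
    stats_post = roi_stats(post_volume, masks.contra)
    counts = {}
    hypo_masks = {}
    for scan, volume, stats in (("pre", pre_volume, stats_pre), ("post", post_volume, stats_post)):
        for hemi, mask in (("ipsi", masks.ipsi), ("contra", masks.contra)):
            n, m = detect_hypointense(volume, stats, mask, k=k)
            counts[f"{hemi}_{scan}"] = n
            if keep_masks:
                hypo_masks[f"{hemi}_{scan}"] = m
    diff_ipsi = counts["ipsi_post"] - counts["ipsi_pre"]
    diff_contra = counts["contra_post"] - counts["contra_pre"]
    return HypoResult(
        threshold_pre=stats_pre.mean - k * stats_pre.sd,
        threshold_post=stats_post.mean - k * stats_post.sd,
        n_hypo_ipsi_pre=counts["ipsi_pre"],
        n_hypo_ipsi_post=counts["ipsi_post"],
        n_hypo_contra_pre=counts["contra_pre"],
        n_hypo_contra_post=counts["contra_post"],
        diff_raw_ipsi=diff_ipsi,
        diff_clipped_ipsi=max(diff_ipsi, 0),
        diff_raw_contra=diff_contra,
        diff_clipped_contra=max(diff_contra, 0),
        k=k,
        hypo_masks=hypo_masks,
    )


@dataclass(frozen=True)
class NoiseFloor:
    """Detection limit estimated from control (non-binding) differences."""

    mean: float
    sd: float
    fraction_of_roi: float
    n: int


def noise_floor(control_diffs, contra_roi_voxels: int) -> NoiseFloor:
    """Mean ± sample SD of control-group raw differences, and the mean as a
    fraction of the contralateral ROI volume."""
    diffs = np.asarray(list(control_diffs), dtype=float)
    if diffs.size == 0:
        raise ValueError("need at least one control difference")
    if contra_roi_voxels <= 0:
        raise ValueError("contra ROI voxel count must be positive")
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    mean = float(diffs.mean())
    return NoiseFloor(mean=mean, sd=sd, fraction_of_roi=mean / contra_roi_voxels, n=int(diffs.size))


_TABLE_COLUMNS = [
    "case_id",
    "scenario",
    "timepoint",
    "hemisphere",
    "n_hypo_pre",
    "n_hypo_post",
    "diff_raw",
    "diff_clipped",
    "threshold_pre",
    "threshold_post",
    "k",
]


def cohort_table(results, metadata=None) -> pd.DataFrame:
    """Tidy per-case, per-hemisphere table of hypointensity results.

    ``metadata`` is an optional parallel sequence of dicts with keys among
    ``case_id``, ``scenario``, ``timepoint``. Rows are ordered by input
    position, ipsilateral hemisphere first — deterministic for identical
    inputs.
    """
    results = list(results)
    metadata = list(metadata) if metadata is not None else [{}] * len(results)
    if len(metadata) != len(results):
        raise ValueError("metadata length must match results length")
    rows = []
    for i, (res, meta) in enumerate(zip(results, metadata)):
        for hemi in ("ipsi", "contra"):
            rows.append(
                {
                    "case_id": meta.get("case_id", i),
                    "scenario": meta.get("scenario", ""),
                    "timepoint": meta.get("timepoint", ""),
                    "hemisphere": hemi,
                    "n_hypo_pre": getattr(res, f"n_hypo_{hemi}_pre"),
                    "n_hypo_post": getattr(res, f"n_hypo_{hemi}_post"),
                    "diff_raw": getattr(res, f"diff_raw_{hemi}"),
                    "diff_clipped": getattr(res, f"diff_clipped_{hemi}"),
                    "threshold_pre": res.threshold_pre,
                    "threshold_post": res.threshold_post,
                    "k": res.k,
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
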