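"""Histology quantification: iron blobs, perivascular distances, PPC.

Operators for Perls' Prussian blue / DAB-stained micrographs:

* segment the blue (ferric iron) colour class into connected blobs with
  physical centroids and areas;
* classify each blob as a single ~1 μm MPIO bead or an iron aggregation
  (intracellular iron in a macrophage) by an area rule;
* macrophage-centre-to-nearest-vessel-lumen-centre distance statistics
  (median, fraction within 25 μm, cumulative histogram);
* endothelium-normalised bound-MPIO density and per-field-of-view counts;
* positive-pixel area fractions with fixed intensity windows
  (moderate [185, 202], strong < 10 on a 0-255 scale), the windows used by
  whole-slide positive-pixel-count software for DAB quantification.

Distances are 2D centre-to-centre (tissue sections); the lumen radius is
not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .synth.histology import SINGLE_BEAD_AREA_UM2

__all__ = [
    "IronBlob",
    "DistanceStats",
    "PositivePixelParams",
    "PositivePixelResult",
    "segment_iron",
    "classify_blob",
    "vessel_distance_stats",
    "mpio_density",
    "count_per_fov",
    "positive_pixel_fraction",
]


@dataclass
class IronBlob:
    """A connected iron-stained region: centroid (x, y) and area in μm."""

    centroid: tuple[float, float]
    area: float  # μm²
    n_pixels: int
    blob_class: str | None = None  # "single_mpio" | "aggregation"


def segment_iron(
    image: np.ndarray,
    pixel_size: float | None = None,
    colour_class: str = "blue",
    margin: int = 30,
) -> list[IronBlob]:
    """Segment the iron (blue) colour class into connected blobs.

    A pixel belongs to the blue class when its blue value exceeds the
    larger of its red and green values by at least ``margin`` (the pink
    counterstain and the brown vessel stain are both red-dominant, so this
    separates the classes cleanly). Components use 8-connectivity.

    ``pixel_size`` (μm/px) is required to express centroids and areas in
    physical units; omitting it is an error, not a silent pixel-unit
    fallback.
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel_size (μm per pixel) metadata is required")
    if colour_class != "blue":
        raise ValueError("only the blue (iron) colour class is implemented")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image")
    rgb = image.astype(int)
    mask = rgb[..., 2] - np.maximum(rgb[..., 0], rgb[..., 1]) >= margin
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return []
    # vectorised per-label pixel counts and centroids
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    counts = np.bincount(lab, minlength=n + 1)[1:]
    sum_r = np.bincount(lab, weights=rows, minlength=n + 1)[1:]
    sum_c = np.bincount(lab, weights=cols, minlength=n + 1)[1:]
    blobs = [
        IronBlob(
            centroid=(sc / ct * pixel_size, sr / ct * pixel_size),  # (x, y) μm
            area=float(ct) * pixel_size**2,
            n_pixels=int(ct),
        )
        for ct, sr, sc in zip(counts, sum_r, sum_c)
    ]
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def classify_blob(
    blob: IronBlob | float,
    single_bead_diameter: float = 1.0,
    aggregation_factor: float = 2.0,
) -> str:
    """Classify a blob as ``single_mpio`` or ``aggregation`` by area.

    A blob is an aggregation iff its area is at least ``aggregation_factor``
    times the area of one bead, ``pi * (d/2)^2`` — the smallest area
    inconsistent with a single bead. The boundary case counts as an
    aggregation (>=). Scalars are treated as areas in μm².
    """
    area = blob.area if isinstance(blob, IronBlob) else float(blob)
    if area <= 0:
        raise ValueError("blob area must be positive")
    bead_area = np.pi * (single_bead_diameter / 2.0) ** 2
    label = "aggregation" if area >= aggregation_factor * bead_area else "single_mpio"
    if isinstance(blob, IronBlob):
        blob.blob_class = label
    return label


@dataclass
class DistanceStats:
    """Nearest-lumen-centre distance distribution of iron-laden macrophages."""

    distances: np.ndarray  # μm, one per macrophage
    median: float  # μm
    frac_within_25um: float
    bin_edges: np.ndarray  # μm
    cumulative_fraction: np.ndarray  # per right bin edge


def vessel_distance_stats(
    macrophage_centres: np.ndarray,
    vessel_lumen_centres: np.ndarray,
    bin_width: float = 5.0,
    within_um: float = 25.0,
) -> DistanceStats:
    """Distance from each macrophage centre to the nearest lumen centre.

    Returns the full distance vector, the median, the fraction at or below
    ``within_um`` (default 25 μm) and a cumulative histogram with
    ``bin_width`` μm bins.
    """
    vessels = np.asarray(vessel_lumen_centres, dtype=float).reshape(-1, 2)
    if vessels.shape[0] == 0:
        raise ValueError("at least one vessel lumen centre is required")
    macs = np.asarray(macrophage_centres, dtype=float).reshape(-1, 2)
    if macs.shape[0] == 0:
        distances = np.empty(0)
    else:
        distances, _ = cKDTree(vessels).query(macs)
        distances = np.asarray(distances, dtype=float)
    top = float(distances.max()) if distances.size else bin_width
    edges = np.arange(0.0, np.ceil(top / bin_width) * bin_width + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    cumulative = counts.cumsum() / max(distances.size, 1)
    return DistanceStats(
        distances=distances,
        median=float(np.median(distances)) if distances.size else float("nan"),
        frac_within_25um=float((distances <= within_um).mean()) if distances.size else float("nan"),
        bin_edges=edges,
        cumulative_fraction=cumulative,
    )


def mpio_density(blobs, endothelium_area_mm2: float) -> float:
    """Single (endothelium-bound) MPIO per mm² of endothelium."""
    if endothelium_area_mm2 <= 0:
        raise ValueError("endothelium area must be positive")
    singles = sum(
        1 for b in blobs if (b.blob_class if isinstance(b, IronBlob) else b) == "single_mpio"
    )
    return singles / endothelium_area_mm2


def count_per_fov(
    images,
    pixel_size: float,
    single_bead_diameter: float = 1.0,
    aggregation_factor: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Segment and classify each field of view; tabulate counts.

    Returns a per-FOV table (single/aggregation/total counts) and a summary
    dict with the mean and sample SD of the per-FOV totals.
    """
    images = list(images)
    if not images:
        raise ValueError("at least one field of view is required")
    rows = []
    for i, image in enumerate(images):
        blobs = segment_iron(image, pixel_size=pixel_size)
        for b in blobs:
            classify_blob(b, single_bead_diameter, aggregation_factor)
        n_single = sum(1 for b in blobs if b.blob_class == "single_mpio")
        rows.append(
            {
                "fov": i,
                "n_single_mpio": n_single,
                "n_aggregation": len(blobs) - n_single,
                "n_total": len(blobs),
            }
        )
    table = pd.DataFrame(rows, columns=["fov", "n_single_mpio", "n_aggregation", "n_total"])
    totals = table["n_total"].to_numpy(dtype=float)
    summary = {
        "mean": float(totals.mean()),
        "sd": float(totals.std(ddof=1)) if totals.size > 1 else 0.0,
        "n_fov": int(totals.size),
    }
    return table, summary


@dataclass(frozen=True)
class PositivePixelParams:
    """Intensity windows of the positive-pixel classification (0-255 scale)."""

    moderate_low: int = 185
    moderate_high: int = 202
    strong_max: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.moderate_low <= self.moderate_high <= 255:
            raise ValueError("moderate window must lie within the 0-255 scale")
        if not 0 <= self.strong_max < self.moderate_low:
            raise ValueError("strong_max must fall below the moderate window")


@dataclass(frozen=True)
class PositivePixelResult:
    moderate_fraction: float
    strong_fraction: float
    positive_fraction: float
    n_pixels: int


def positive_pixel_fraction(
    image: np.ndarray,
    params: PositivePixelParams | None = None,
    roi_mask: np.ndarray | None = None,
) -> PositivePixelResult:
    """Positive-pixel area fractions over an ROI.

    RGB input is collapsed to intensity with the Rec.601 luma
    (0.299 R + 0.587 G + 0.114 B). A pixel is *moderate* when its intensity
    lies in [moderate_low, moderate_high] (inclusive) and *strong* when it
    is strictly below ``strong_max``; the positive fraction is their sum.
    """
    params = params or PositivePixelParams()
    image = np.asarray(image)
    if image.ndim == 3:
        intensity = (
            0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
        )
    else:
        intensity = image.astype(float)
    if roi_mask is not None:
        intensity = intensity[np.asarray(roi_mask, dtype=bool)]
    values = intensity.ravel()
    if values.size == 0:
        raise ValueError("ROI contains no pixels")
    moderate = float(((values >= params.moderate_low) & (values <= params.moderate_high)).mean())
    strong = float((values < params.strong_max).mean())
    return PositivePixelResult(
        moderate_fraction=moderate,
        strong_fraction=strong,
        positive_fraction=moderate + strong,
        n_pixels=int(values.size),
    )
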