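"""Per-fiber morphometry: lesser (minimum Feret) diameter and
cross-sectional area, and per-section aggregates.

The lesser diameter of a fiber profile is the minimum caliper width of its
convex hull — the "maximum diameter across the lesser aspect" convention of
classical muscle histology, chosen because it is robust to oblique
sectioning. Areas count hole-filled pixels: interior unstained spots in a
fiber profile are staining artifacts, a myofiber cross-section being simply
connected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import closing, disk

from . import _polygon
from .evaluation import coefficient_of_variance
from .io import CalibratedImage, LabelMask
from .segmentation import labels_to_regions, stain_separation

__all__ = [
    "FiberRecord",
    "SectionSummary",
    "min_feret_diameter",
    "max_feret_diameter",
    "fiber_area",
    "measure_section",
    "bin_diameters",
    "tissue_support",
]

logger = logging.getLogger(__name__)

#: Stain-score floor above which a pixel counts as stained tissue.
TISSUE_SCORE_FLOOR = 0.05
#: Radius (µm) of the morphological closing that bridges endomysial gaps
#: when delineating the tissue support for fiber-density normalization.
TISSUE_CLOSING_RADIUS_UM = 5.0


@dataclass
class FiberRecord:
    """One fiber's identity and metrics."""

    source_id: str
    fiber_id: int
    lesser_diameter_um: float
    area_um2: float
    centroid_x_px: float
    centroid_y_px: float


@dataclass
class SectionSummary:
    """Per-image aggregate of fiber metrics.

    ``fibers_per_mm2`` uses the stained-tissue area as denominator (the
    density is normalized to section area, not to the full image frame);
    ``fibers_per_mm2_image`` is also reported with the full image area as
    denominator for comparison.
    """

    source_id: str
    n_fibers: int
    mean_diameter_um: float
    sem_diameter_um: float
    cv_diameter_percent: float
    mean_area_um2: float
    sem_area_um2: float
    fibers_per_mm2: float
    tissue_area_mm2: float
    image_area_mm2: float
    fibers_per_mm2_image: float


def min_feret_diameter(polygon_px: np.ndarray, px_per_um: float) -> float:
    """Minimum Feret (caliper) diameter of a boundary polygon, in µm.

    Computed by rotating calipers over the convex hull: for each hull edge,
    the farthest vertex distance to the edge's supporting line; the answer
    is the minimum over edges. A degenerate (collinear) polygon returns
    width 0 with a warning.
    """
    poly = np.asarray(polygon_px, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (N >= 3, 2) vertex array")
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    width = _polygon.min_feret_px(poly)
    if width == 0.0:
        logger.warning("degenerate (collinear) polygon; returning width 0")
    return width / px_per_um


def max_feret_diameter(polygon_px: np.ndarray, px_per_um: float) -> float:
    """Maximum Feret diameter (largest caliper span) in µm."""
    poly = np.asarray(polygon_px, dtype=float)
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    return _polygon.max_feret_px(poly) / px_per_um


def fiber_area(pixel_coords: np.ndarray, px_per_um: float) -> float:
    """Cross-sectional area (µm²) of a fiber's pixel set, holes filled."""
    coords = np.asarray(pixel_coords)
    if coords.size == 0:
        raise ValueError("pixel set must be nonempty")
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    rmin, cmin = coords.min(axis=0)
    local = coords - [rmin, cmin]
    shape = local.max(axis=0) + 1
    raster = np.zeros(shape, dtype=bool)
    raster[local[:, 0], local[:, 1]] = True
    filled = ndi.binary_fill_holes(raster)
    return float(filled.sum()) / px_per_um**2


def tissue_support(
    mask: LabelMask,
    image: CalibratedImage | None = None,
    score_floor: float = TISSUE_SCORE_FLOOR,
    closing_radius_um: float = TISSUE_CLOSING_RADIUS_UM,
) -> np.ndarray:
    """Boolean raster of pixels considered part of the tissue section.

    With the stained image available: pixels whose stain score exceeds a
    low floor, plus all labeled pixels. Without it: the labeled pixels
    alone. Either support is then morphologically closed with a disk of
    ``closing_radius_um`` to bridge endomysial gaps.
    """
    support = mask.labels > 0
    if image is not None:
        support = support | (stain_separation(image) > score_floor)
    radius_px = int(round(closing_radius_um * mask.px_per_um))
    if radius_px >= 1 and support.any():
        footprint = disk(radius_px, decomposition="sequence")
        support = closing(support, footprint).astype(bool)
    return support


def measure_section(
    mask: LabelMask,
    source_id: str,
    image: CalibratedImage | None = None,
    connectivity: int = 8,
) -> tuple[list[FiberRecord], SectionSummary]:
    """Measure every fiber in a (filtered) label mask.

    Returns one :class:`FiberRecord` per label plus the per-section
    aggregate. An empty mask yields an empty record list and a summary with
    NaN means. Aggregates depend only on the multiset of fibers, not on
    label order.
    """
    px = mask.px_per_um
    records: list[FiberRecord] = []
    for region in labels_to_regions(mask, connectivity=connectivity):
        coords = region.coords
        area = fiber_area(coords, px)
        diameter = min_feret_diameter(region.polygon, px)
        records.append(
            FiberRecord(
                source_id=source_id,
                fiber_id=region.label,
                lesser_diameter_um=diameter,
                area_um2=area,
                centroid_x_px=float(coords[:, 1].mean()),
                centroid_y_px=float(coords[:, 0].mean()),
            )
        )

    n = len(records)
    diameters = np.array([r.lesser_diameter_um for r in records])
    areas = np.array([r.area_um2 for r in records])
    nan = float("nan")

    support = tissue_support(mask, image)
    tissue_area_mm2 = float(support.sum()) / (px**2 * 1e6)
    image_area_mm2 = mask.labels.size / (px**2 * 1e6)

    summary = SectionSummary(
        source_id=source_id,
        n_fibers=n,
        mean_diameter_um=float(diameters.mean()) if n else nan,
        sem_diameter_um=float(diameters.std(ddof=1) / math.sqrt(n)) if n > 1 else nan,
        cv_diameter_percent=(
            coefficient_of_variance(diameters)
            if n > 1 and diameters.mean() != 0
            else nan
        ),
        mean_area_um2=float(areas.mean()) if n else nan,
        sem_area_um2=float(areas.std(ddof=1) / math.sqrt(n)) if n > 1 else nan,
        fibers_per_mm2=n / tissue_area_mm2 if tissue_area_mm2 > 0 else nan,
        tissue_area_mm2=tissue_area_mm2,
        image_area_mm2=image_area_mm2,
        fibers_per_mm2_image=n / image_area_mm2 if image_area_mm2 > 0 else nan,
    )
    return records, summary


def bin_diameters(
    records: Sequence, bin_width_um: float = 5.0
) -> pd.DataFrame:
    """Histogram fiber diameters into left-closed bins [0, w), [w, 2w), ….

    Accepts :class:`FiberRecord` sequences or raw diameter values. Returns a
    table with columns ``bin_left_um``, ``bin_right_um``, ``count``,
    ``percent``; percentages sum to 100 for nonempty input.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    values = np.array(
        [getattr(r, "lesser_diameter_um", r) for r in records], dtype=float
    )
    columns = ["bin_left_um", "bin_right_um", "count", "percent"]
    if values.size == 0:
        return pd.DataFrame(columns=columns)
    n_bins = int(values.max() // bin_width_um) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram closes the last bin on the right; values at the final
    # edge cannot occur since the edge lies strictly above the maximum,
    # except when max is an exact multiple of the width — then it falls in
    # its own left-closed bin by construction of n_bins.
    return pd.DataFrame(
        {
            "bin_left_um": edges[:-1],
            "bin_right_um": edges[1:],
            "count": counts,
            "percent": counts / counts.sum() * 100.0,
        }
    )
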