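"""Histopathological quantification of lymphocytic aggregates.

Implements the measurements used to grade salivary-gland inflammation on
immunofluorescence fields:

* marker-positive areas and T/B intersection areas (raster or polygon route),
* aggregate detection as connected components of the T OR B positive mask,
* nucleus counting inside an aggregate (DAPI local maxima, or a positive-area
  to nominal-nucleus-area ratio),
* inflammatory foci (aggregates with more than 50 lymphocytes) and the focus
  score ``(n_foci / gland area in mm²) x 4`` — foci per 4 mm² of gland,
* aggregate area fraction: percent of gland area occupied by aggregates,
* T/B segregation scoring: ``index = 1 - intersection / min(T area, B area)``
  with a configurable call threshold, and the prevalence of segregated
  aggregates,
* per-field positive-cell counts and double-positive percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPolygon, Polygon
from skimage.feature import peak_local_max
from skimage.measure import label as _label

from .imgio import MultiplexImage, RegionSet, mask_to_regions
from .pixclass import ThresholdSpec, clean_mask, global_threshold

__all__ = [
    "FOCUS_SCORE_FACTOR",
    "FOCUS_MIN_LYMPHOCYTES",
    "AggregateFootprint",
    "AggregateMetrics",
    "GlandMetrics",
    "FieldCellCounts",
    "marker_area",
    "marker_area_mm2",
    "intersection_area",
    "detect_aggregates",
    "count_nuclei",
    "detect_foci",
    "focus_score",
    "aggregate_area_fraction",
    "gland_area",
    "segregation_index",
    "segregation_classify",
    "segregated_prevalence_pct",
    "field_cell_counts",
    "quantify_field",
]

#: Focus-score normalization: foci per mm² are scaled to foci per 4 mm².
FOCUS_SCORE_FACTOR = 4.0

#: An inflammatory focus is an infiltrate of MORE THAN this many lymphocytes.
FOCUS_MIN_LYMPHOCYTES = 50


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def marker_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Positive area in µm²: true-pixel count times pixel area."""
    return float(np.count_nonzero(mask)) * pixel_size_um**2


def marker_area_mm2(mask: np.ndarray, pixel_size_um: float) -> float:
    return marker_area(mask, pixel_size_um) / 1e6


def intersection_area(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pixel_size_um: float,
    mode: str = "raster",
) -> float:
    """Area (µm²) where both markers are positive.

    ``mode="raster"`` measures the logical AND; ``mode="polygon"`` intersects
    the polygonized region sets.  The two agree exactly because
    polygonization traces pixel boundaries.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    if mode == "raster":
        return marker_area(mask_a & mask_b, pixel_size_um)
    if mode == "polygon":
        ra = mask_to_regions(mask_a, pixel_size_um)
        rb = mask_to_regions(mask_b, pixel_size_um)
        union_a = shapely_union([r.geometry for r in ra])
        union_b = shapely_union([r.geometry for r in rb])
        return union_a.intersection(union_b).area * pixel_size_um**2
    raise ValueError("mode must be 'raster' or 'polygon'")


def shapely_union(geoms: Sequence) -> Polygon | MultiPolygon:
    from shapely.ops import unary_union

    if not geoms:
        return Polygon()
    return unary_union(list(geoms))


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------

@dataclass
class AggregateFootprint:
    """One detected aggregate: a connected component of the T OR B mask,
    carrying its bounding box and clipped per-marker sub-masks."""

    aggregate_id: int
    slice_rc: tuple[slice, slice]
    mask: np.ndarray          # union footprint, local to slice_rc
    t_mask: np.ndarray        # T-positive within the footprint
    b_mask: np.ndarray        # B-positive within the footprint
    area_um2: float

    @property
    def centroid_xy(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        r0, c0 = self.slice_rc[0].start, self.slice_rc[1].start
        return (float(cc.mean() + c0), float(rr.mean() + r0))


def detect_aggregates(
    mask_t: np.ndarray,
    mask_b: np.ndarray,
    pixel_size_um: float,
    min_aggregate_area_um2: float = 0.0,
) -> list[AggregateFootprint]:
    """Detect aggregates as 8-connected components of T OR B, keeping those
    with area >= ``min_aggregate_area_um2``."""
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_t.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_t.shape} vs {mask_b.shape}")
    union = mask_t | mask_b
    lab, n = _label(union, connectivity=2, return_num=True)
    out: list[AggregateFootprint] = []
    pa = pixel_size_um**2
    from scipy.ndimage import find_objects

    for comp, sl in enumerate(find_objects(lab), start=1):
        if sl is None:
            continue
        local = lab[sl] == comp
        area = float(local.sum()) * pa
        if area < min_aggregate_area_um2:
            continue
        out.append(
            AggregateFootprint(
                aggregate_id=len(out),
                slice_rc=sl,
                mask=local,
                t_mask=mask_t[sl] & local,
                b_mask=mask_b[sl] & local,
                area_um2=area,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Nucleus counting
# ---------------------------------------------------------------------------

def count_nuclei(
    dapi: np.ndarray,
    footprint: AggregateFootprint,
    nucleus_radius_um: float,
    pixel_size_um: float,
    method: str = "peaks",
    dapi_threshold: float | None = None,
    peak_threshold_rel: float = 0.5,
) -> int:
    """Approximate the number of nuclei inside an aggregate footprint.

    ``method="peaks"`` counts local maxima of the Gaussian-smoothed DAPI
    signal inside the footprint, enforcing a minimum Euclidean peak
    separation of two nucleus radii.  ``method="area_ratio"`` divides the
    DAPI-positive area inside the footprint by the nominal nucleus area
    (``dapi_threshold`` defaults to the midpoint of the patch's intensity
    range).  Both are approximations of a manual lymphocyte count: peaks
    merge in densely packed infiltrates, and the area ratio inherits the
    raster discretization of the nucleus footprint.
    """
    if not nucleus_radius_um > 0:
        raise ValueError("nucleus_radius_um must be positive")
    r_px = nucleus_radius_um / pixel_size_um
    patch = np.asarray(dapi, dtype=float)[footprint.slice_rc]
    inside = footprint.mask
    if not inside.any():
        return 0

    if method == "area_ratio":
        if dapi_threshold is None:
            vals = patch[inside]
            dapi_threshold = 0.5 * (float(vals.min()) + float(vals.max()))
        positive = (patch >= dapi_threshold) & inside
        return int(round(positive.sum() / (math.pi * r_px**2)))

    if method != "peaks":
        raise ValueError("method must be 'peaks' or 'area_ratio'")

    sm = gaussian_filter(patch, sigma=0.5 * r_px)
    coords = peak_local_max(
        sm,
        min_distance=1,
        threshold_rel=peak_threshold_rel,
        labels=inside.astype(int),
        exclude_border=False,
    )
    if coords.size == 0:
        return 0
    # greedy suppression: keep peaks in decreasing intensity, enforcing a
    # minimum Euclidean separation of two nucleus radii
    order = np.argsort(-sm[coords[:, 0], coords[:, 1]], kind="stable")
    coords = coords[order].astype(float)
    kept: list[np.ndarray] = []
    min_sep = 2.0 * r_px
    for p in coords:
        if all(np.hypot(*(p - q)) >= min_sep for q in kept):
            kept.append(p)
    return len(kept)


# ---------------------------------------------------------------------------
# Foci and scores
# ---------------------------------------------------------------------------

def detect_foci(
    nucleus_counts: Sequence[int], min_lymphocytes: int = FOCUS_MIN_LYMPHOCYTES
) -> list[int]:
    """Indices of aggregates qualifying as inflammatory foci: strictly more
    than ``min_lymphocytes`` nuclei (a count of exactly 50 is excluded)."""
    return [i for i, n in enumerate(nucleus_counts) if n > min_lymphocytes]


def focus_score(n_foci: int, gland_area_mm2: float) -> float:
    """Focus score = (number of foci / gland area in mm²) x 4."""
    if not gland_area_mm2 > 0:
        raise ValueError("gland_area_mm2 must be positive")
    if n_foci < 0:
        raise ValueError("n_foci must be non-negative")
    return (n_foci / gland_area_mm2) * FOCUS_SCORE_FACTOR


def aggregate_area_fraction(
    total_aggregate_area_mm2: float, gland_area_mm2: float
) -> float:
    """Percent of the gland area occupied by inflammatory aggregates."""
    if not gland_area_mm2 > 0:
        raise ValueError("gland_area_mm2 must be positive")
    if total_aggregate_area_mm2 < 0:
        raise ValueError("aggregate area must be non-negative")
    if total_aggregate_area_mm2 > gland_area_mm2 * (1 + 1e-9):
        raise ValueError(
            f"aggregate area {total_aggregate_area_mm2} mm² exceeds gland area "
            f"{gland_area_mm2} mm²: inconsistent segmentation"
        )
    return 100.0 * total_aggregate_area_mm2 / gland_area_mm2


def gland_area(
    gland: Polygon | MultiPolygon | RegionSet | np.ndarray, pixel_size_um: float
) -> float:
    """Gland area in mm² from a polygon annotation (the semi-manual perimeter
    path), a RegionSet, or a binary mask."""
    if isinstance(gland, RegionSet):
        return gland.total_area_um2 / 1e6
    if isinstance(gland, (Polygon, MultiPolygon)):
        if not gland.is_valid:
            raise ValueError("gland polygon is invalid (self-intersecting?)")
        if gland.area <= 0:
            raise ValueError("gland polygon is degenerate (zero area)")
        return gland.area * pixel_size_um**2 / 1e6
    mask = np.asarray(gland, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("gland mask must be 2-D with at least one positive pixel")
    return marker_area_mm2(mask, pixel_size_um)


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

@dataclass
class AggregateMetrics:
    """Measured metrics of one aggregate.  ``segregation_index`` is NaN and
    ``segregated`` is None when both marker areas are zero (undefined)."""

    aggregate_id: int
    t_area_um2: float
    b_area_um2: float
    intersection_area_um2: float
    nucleus_count: int
    segregation_index: float = float("nan")
    segregated: bool | None = None

    def __post_init__(self) -> None:
        m = min(self.t_area_um2, self.b_area_um2)
        if self.intersection_area_um2 > m * (1 + 1e-9) + 1e-12:
            raise ValueError(
                "intersection area exceeds the smaller marker area "
                f"({self.intersection_area_um2} > {m})"
            )


def segregation_index(
    t_area_um2: float, b_area_um2: float, intersection_area_um2: float
) -> float:
    """1 - intersection / min(T, B) when both areas are positive; 1.0 when
    exactly one marker area is zero; NaN (undefined) when both are zero."""
    if t_area_um2 == 0 and b_area_um2 == 0:
        return float("nan")
    m = min(t_area_um2, b_area_um2)
    if m == 0:
        return 1.0
    return 1.0 - intersection_area_um2 / m


def segregation_classify(
    metrics: AggregateMetrics, index_threshold: float = 0.5
) -> AggregateMetrics:
    """Fill in the segregation index and the segregated call
    (``index >= index_threshold``); undefined aggregates are flagged with
    ``segregated=None``."""
    idx = segregation_index(
        metrics.t_area_um2, metrics.b_area_um2, metrics.intersection_area_um2
    )
    seg = None if math.isnan(idx) else bool(idx >= index_threshold)
    return replace(metrics, segregation_index=idx, segregated=seg)


def segregated_prevalence_pct(metrics: Iterable[AggregateMetrics]) -> float:
    """Percent of aggregates called segregated, over aggregates with a
    defined call.  NaN when no aggregate has a defined call."""
    calls = [m.segregated for m in metrics if m.segregated is not None]
    if not calls:
        return float("nan")
    return 100.0 * sum(calls) / len(calls)


# ---------------------------------------------------------------------------
# Per-field cell counts
# ---------------------------------------------------------------------------

@dataclass
class FieldCellCounts:
    """Positive cell counts per field.  ``pct_double_positive`` is None when
    there are no marker-A-positive cells."""

    n_cells_marker_a: int
    n_cells_marker_a_and_b: int
    pct_double_positive: float | None

    def __post_init__(self) -> None:
        if self.n_cells_marker_a_and_b > self.n_cells_marker_a:
            raise ValueError("double-positive count exceeds single-positive count")


def field_cell_counts(
    positions_xy: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> FieldCellCounts:
    """Count cells positive for marker A and for both markers.  A cell is
    positive for a marker when its nucleus position (x, y in pixel
    coordinates) falls on a positive pixel of that marker's mask."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    pos = np.asarray(positions_xy, dtype=float).reshape(-1, 2)
    cols = np.clip(pos[:, 0].astype(int), 0, mask_a.shape[1] - 1)
    rows = np.clip(pos[:, 1].astype(int), 0, mask_a.shape[0] - 1)
    in_a = mask_a[rows, cols]
    in_ab = in_a & mask_b[rows, cols]
    n_a, n_ab = int(in_a.sum()), int(in_ab.sum())
    pct = 100.0 * n_ab / n_a if n_a > 0 else None
    return FieldCellCounts(n_a, n_ab, pct)


# ---------------------------------------------------------------------------
# Per-field composition
# ---------------------------------------------------------------------------

@dataclass
class GlandMetrics:
    """Per-specimen summary: focus score, aggregate area fraction, the
    per-aggregate metrics and the segregated prevalence."""

    gland_area_mm2: float
    n_foci: int
    focus_score: float
    aggregate_area_fraction_pct: float
    aggregates: list[AggregateMetrics]
    segregated_prevalence_pct: float
    t_area_um2: float
    b_area_um2: float
    intersection_area_um2: float


def quantify_field(
    image: MultiplexImage,
    t_threshold: ThresholdSpec,
    b_threshold: ThresholdSpec,
    dapi_channel: str = "DAPI",
    gland: Polygon | MultiPolygon | np.ndarray | None = None,
    min_aggregate_area_um2: float = 500.0,
    min_object_area_um2: float = 0.0,
    min_lymphocytes: int = FOCUS_MIN_LYMPHOCYTES,
    index_threshold: float = 0.5,
    nucleus_radius_um: float = 3.0,
    nucleus_method: str = "peaks",
) -> GlandMetrics:
    """Run the whole per-field measurement chain: threshold the two marker
    channels, detect aggregates, count nuclei, call foci and segregation, and
    assemble the gland-level summary.

    When ``gland`` is None the field itself is the evaluated area (the
    fixed-field protocol); supplying a gland annotation switches to
    whole-gland normalization.
    """
    px = image.pixel_size_um
    mask_t = global_threshold(image, t_threshold)
    mask_b = global_threshold(image, b_threshold)
    if min_object_area_um2 > 0:
        mask_t = clean_mask(mask_t, min_object_area_um2, pixel_size_um=px)
        mask_b = clean_mask(mask_b, min_object_area_um2, pixel_size_um=px)

    footprints = detect_aggregates(mask_t, mask_b, px, min_aggregate_area_um2)
    dapi = image.channel(dapi_channel)

    agg_metrics: list[AggregateMetrics] = []
    for fp in footprints:
        n_nuc = count_nuclei(
            dapi, fp, nucleus_radius_um, px, method=nucleus_method
        )
        m = AggregateMetrics(
            aggregate_id=fp.aggregate_id,
            t_area_um2=marker_area(fp.t_mask, px),
            b_area_um2=marker_area(fp.b_mask, px),
            intersection_area_um2=marker_area(fp.t_mask & fp.b_mask, px),
            nucleus_count=n_nuc,
        )
        agg_metrics.append(segregation_classify(m, index_threshold))

    if gland is not None:
        area_mm2 = gland_area(gland, px)
    else:
        area_mm2 = image.field_area_um2 / 1e6

    foci = detect_foci([m.nucleus_count for m in agg_metrics], min_lymphocytes)
    total_agg_mm2 = sum(fp.area_um2 for fp in footprints) / 1e6
    return GlandMetrics(
        gland_area_mm2=area_mm2,
        n_foci=len(foci),
        focus_score=focus_score(len(foci), area_mm2),
        aggregate_area_fraction_pct=aggregate_area_fraction(total_agg_mm2, area_mm2),
        aggregates=agg_metrics,
        segregated_prevalence_pct=segregated_prevalence_pct(agg_metrics),
        t_area_um2=marker_area(mask_t, px),
        b_area_um2=marker_area(mask_b, px),
        intersection_area_um2=intersection_area(mask_t, mask_b, px),
    )
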