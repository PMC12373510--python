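"""Synthetic salivary-gland immunofluorescence fields with planted ground
truth.

The simulator emulates the imaging substrate of viral-induced murine
sialadenitis: a fixed-area fluorescence field (DAPI plus a T-cell marker such
as CD3 and a B-cell marker such as B220) containing a controllable number of
lymphocytic aggregates.  Each aggregate is a disc-shaped cluster of stamped
nuclei; every nucleus is assigned T or B identity by a Bernoulli draw, and in
``segregated`` mode the two identities occupy disjoint sub-clusters a
controllable distance apart, mimicking the T/B zonation of ectopic lymphoid
structures.  Marker signal is stamped over the *cell* footprint (a disc wider
than the nucleus, as membrane/cytoplasmic stains are), DAPI over the nucleus
disc; background and additive Gaussian noise are overlaid last.

Every field carries an exhaustive :class:`GroundTruth` measured from the
noise-free label rasters themselves (not analytically approximated), so each
downstream quantification stage has an exact oracle: per-aggregate T/B/
intersection areas, nucleus counts, segregation labels, focus count, focus
score and aggregate area fraction.

The default field is 1392 x 1040 px with the pixel pitch chosen so that the
field covers exactly 1,229,054.6934 µm² — the fixed evaluated area at which
per-field measurements are directly comparable between images.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.draw import disk as _disk

from .imgio import MultiplexImage, write_tiff

__all__ = [
    "FIELD_AREA_UM2",
    "DEFAULT_FIELD_WIDTH_PX",
    "DEFAULT_FIELD_HEIGHT_PX",
    "DEFAULT_PIXEL_SIZE_UM",
    "SimulationConfig",
    "AggregateTruth",
    "GroundTruth",
    "FieldRecord",
    "simulate_field",
    "simulate_cohort",
    "save_field",
    "cohort_truth_tables",
    "AggregatePlacementError",
]

#: Fixed physical area of one evaluated field, in µm².  All per-field area
#: measurements are directly comparable at this area.
FIELD_AREA_UM2 = 1_229_054.6934

DEFAULT_FIELD_WIDTH_PX = 1392
DEFAULT_FIELD_HEIGHT_PX = 1040

#: Pixel pitch derived from the fixed field area and the default grid, so the
#: default field covers FIELD_AREA_UM2 exactly (to float rounding).
DEFAULT_PIXEL_SIZE_UM = math.sqrt(
    FIELD_AREA_UM2 / (DEFAULT_FIELD_WIDTH_PX * DEFAULT_FIELD_HEIGHT_PX)
)

#: Target fraction of a cluster disc covered by nucleus-exclusion discs during
#: dart-throwing placement; well below the ~0.55 random sequential adsorption
#: saturation so placement succeeds within bounded retries.
_PACKING_FRACTION = 0.35

#: Extra placement slack, in units of the nucleus spacing, reserved around
#: each cluster disc (dart-throwing may grow a crowded disc by this much; the
#: aggregate envelope accounts for it so aggregates stay disjoint).
_ENVELOPE_SLACK = 1.5


class AggregatePlacementError(RuntimeError):
    """Raised when an aggregate cannot be placed inside the gland without
    overlapping previously placed aggregates within the retry budget."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated gland field.

    ``nuclei_per_aggregate`` is either a fixed integer or an inclusive
    ``(low, high)`` range sampled uniformly per aggregate.  ``t_fraction`` is
    the probability that a nucleus carries the T marker; the rest carry the B
    marker.  Under ``segregation_mode="segregated"`` the T and B nuclei are
    placed in two sub-clusters whose centres are ``separation_factor`` x the
    aggregate radius apart; under ``"mixed"`` all nuclei share one disc.
    ``marker_intensity`` is a single value for all channels or a per-channel
    mapping.  Intensities are arbitrary fluorescence units.
    """

    field_width_px: int = DEFAULT_FIELD_WIDTH_PX
    field_height_px: int = DEFAULT_FIELD_HEIGHT_PX
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    gland_polygon: Polygon | None = None
    n_aggregates: int = 4
    nuclei_per_aggregate: int | tuple[int, int] = (60, 120)
    t_fraction: float = 0.6
    segregation_mode: str = "segregated"
    separation_factor: float = 1.2
    nucleus_radius_um: float = 3.0
    cell_radius_factor: float = 3.0
    nucleus_spacing_factor: float = 2.2
    channel_names: tuple[str, str, str] = ("DAPI", "CD3", "B220")
    marker_intensity: float | Mapping[str, float] = 200.0
    background_intensity: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be non-negative")
        if not 0.0 <= self.t_fraction <= 1.0:
            raise ValueError("t_fraction must lie in [0, 1]")
        if self.segregation_mode not in ("segregated", "mixed"):
            raise ValueError("segregation_mode must be 'segregated' or 'mixed'")
        if self.separation_factor < 0:
            raise ValueError("separation_factor must be >= 0")
        if not self.nucleus_radius_um > 0:
            raise ValueError("nucleus_radius_um must be positive")
        if self.cell_radius_factor < 1.0:
            raise ValueError("cell_radius_factor must be >= 1")
        if self.nucleus_spacing_factor < 2.0:
            raise ValueError(
                "nucleus_spacing_factor must be >= 2 (nuclei must not overlap)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.background_intensity < 0:
            raise ValueError("background_intensity must be non-negative")
        if len(set(self.channel_names)) != 3:
            raise ValueError("three distinct channel names required (DAPI, T, B)")
        nr = self.nuclei_per_aggregate
        if isinstance(nr, tuple):
            if len(nr) != 2 or nr[0] < 0 or nr[1] < nr[0]:
                raise ValueError("nuclei_per_aggregate range must be (low, high), 0 <= low <= high")
        elif nr < 0:
            raise ValueError("nuclei_per_aggregate must be non-negative")

    @property
    def field_area_um2(self) -> float:
        """Physical area of the field in µm² (width x height x pixel area)."""
        return self.field_width_px * self.field_height_px * self.pixel_size_um**2

    @property
    def dapi_channel(self) -> str:
        return self.channel_names[0]

    @property
    def t_channel(self) -> str:
        return self.channel_names[1]

    @property
    def b_channel(self) -> str:
        return self.channel_names[2]

    def intensity_of(self, channel: str) -> float:
        if isinstance(self.marker_intensity, Mapping):
            try:
                return float(self.marker_intensity[channel])
            except KeyError:
                raise KeyError(f"no marker_intensity given for channel {channel!r}") from None
        return float(self.marker_intensity)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class AggregateTruth:
    """Planted truth for one aggregate, measured from its noise-free label
    rasters.  ``nucleus_centers`` are (x, y) pixel coordinates;
    ``nucleus_is_t`` the per-nucleus identities."""

    aggregate_id: int
    nucleus_count: int
    t_area_um2: float
    b_area_um2: float
    intersection_area_um2: float
    union_area_um2: float
    segregated: bool
    center_xy: tuple[float, float]
    nucleus_centers: np.ndarray = field(repr=False, default=None)
    nucleus_is_t: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "aggregate_id": self.aggregate_id,
            "nucleus_count": self.nucleus_count,
            "t_area_um2": self.t_area_um2,
            "b_area_um2": self.b_area_um2,
            "intersection_area_um2": self.intersection_area_um2,
            "union_area_um2": self.union_area_um2,
            "segregated": self.segregated,
            "center_x": self.center_xy[0],
            "center_y": self.center_xy[1],
        }


@dataclass
class GroundTruth:
    """Exhaustive planted truth for one field.

    ``n_foci`` counts aggregates with strictly more than ``focus_min_nuclei``
    nuclei (the inflammatory-focus rule: an infiltrate of more than 50
    lymphocytes), and ``true_focus_score`` is foci per mm² of gland scaled by
    4, i.e. foci per 4 mm².
    """

    gland_area_mm2: float
    aggregates: list[AggregateTruth]
    focus_min_nuclei: int = 50

    @property
    def n_foci(self) -> int:
        return sum(1 for a in self.aggregates if a.nucleus_count > self.focus_min_nuclei)

    @property
    def total_aggregate_area_um2(self) -> float:
        return float(sum(a.union_area_um2 for a in self.aggregates))

    @property
    def true_focus_score(self) -> float:
        return (self.n_foci / self.gland_area_mm2) * 4.0

    @property
    def true_aggregate_area_fraction_pct(self) -> float:
        return 100.0 * (self.total_aggregate_area_um2 / 1e6) / self.gland_area_mm2

    def to_dict(self) -> dict:
        return {
            "gland_area_mm2": self.gland_area_mm2,
            "focus_min_nuclei": self.focus_min_nuclei,
            "n_foci": self.n_foci,
            "true_focus_score": self.true_focus_score,
            "true_aggregate_area_fraction_pct": self.true_aggregate_area_fraction_pct,
            "total_aggregate_area_um2": self.total_aggregate_area_um2,
            "aggregates": [a.to_dict() for a in self.aggregates],
        }


@dataclass
class FieldRecord:
    """One simulated field within a cohort."""

    group: str
    field_index: int
    image: MultiplexImage
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _cluster_radius_px(n: int, spacing_px: float) -> float:
    """Radius of a disc that accommodates ``n`` nucleus centres with mutual
    distance >= spacing at the target packing fraction."""
    if n <= 0:
        return 0.0
    return (spacing_px / 2.0) * math.sqrt(max(n, 1) / _PACKING_FRACTION)


def _place_centers_in_disc(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    spacing: float,
    existing: np.ndarray | None = None,
    max_tries: int = 500,
) -> np.ndarray:
    """Dart-throwing placement of ``n`` points in a disc with a minimum
    mutual distance (also kept from ``existing`` points).  When the disc is
    too crowded — e.g. a small minority sub-cluster squeezed against the
    majority cluster — the disc grows in bounded steps up to
    ``radius + 1.5 x spacing`` (the same slack the aggregate envelope
    reserves).  Deterministic given the generator state."""
    pts: list[np.ndarray] = [] if existing is None else [q for q in existing]
    n_existing = len(pts)
    max_radius = radius + _ENVELOPE_SLACK * spacing
    for k in range(n):
        placed = False
        while not placed:
            for _ in range(max_tries):
                u = rng.uniform(0.0, 1.0)
                theta = rng.uniform(0.0, 2.0 * math.pi)
                r = radius * math.sqrt(u)
                p = center + r * np.array([math.cos(theta), math.sin(theta)])
                if all(np.hypot(*(p - q)) >= spacing for q in pts):
                    pts.append(p)
                    placed = True
                    break
            else:
                if radius >= max_radius:
                    raise AggregatePlacementError(
                        f"could not place nucleus {k} of {n} within "
                        f"{max_tries} tries at maximum radius {max_radius:.1f}"
                    )
                radius = min(radius + 0.5 * spacing, max_radius)
    return np.array(pts[n_existing:]).reshape(n, 2)


def _stamp_discs(
    raster: np.ndarray, centers: np.ndarray, radius_px: float
) -> None:
    for x, y in centers:
        rr, cc = _disk((y, x), radius_px, shape=raster.shape)
        raster[rr, cc] = True


def _gland_geometry(config: SimulationConfig) -> Polygon:
    if config.gland_polygon is not None:
        g = config.gland_polygon
        if not g.is_valid or g.area <= 0:
            raise ValueError("gland_polygon must be a valid non-degenerate polygon")
        return g
    return Polygon(
        [
            (0.0, 0.0),
            (config.field_width_px, 0.0),
            (config.field_width_px, config.field_height_px),
            (0.0, config.field_height_px),
        ]
    )


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------

def simulate_field(
    config: SimulationConfig, seed: int | None = None
) -> tuple[MultiplexImage, GroundTruth]:
    """Simulate one field: stamp aggregates, build the three channels, and
    measure the ground truth from the noise-free label rasters.

    Identical ``(config, seed)`` produce bit-identical images and truths.

    Raises
    ------
    AggregatePlacementError
        If an aggregate cannot be placed without overlap within 1000 retries
        (the failing aggregate index is named).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    px = config.pixel_size_um
    h, w = config.field_height_px, config.field_width_px
    r_nuc = config.nucleus_radius_um / px
    r_cell = r_nuc * config.cell_radius_factor
    spacing = r_nuc * config.nucleus_spacing_factor
    gland = _gland_geometry(config)

    dapi_mask = np.zeros((h, w), dtype=bool)
    t_mask = np.zeros((h, w), dtype=bool)
    b_mask = np.zeros((h, w), dtype=bool)

    # per-aggregate envelope radii for non-overlap bookkeeping
    placed: list[tuple[np.ndarray, float]] = []
    aggregates: list[AggregateTruth] = []

    for idx in range(config.n_aggregates):
        nr = config.nuclei_per_aggregate
        if isinstance(nr, tuple):
            n_nuc = int(rng.integers(nr[0], nr[1] + 1))
        else:
            n_nuc = int(nr)

        is_t = rng.random(n_nuc) < config.t_fraction
        n_t, n_b = int(is_t.sum()), int((~is_t).sum())
        r_agg = _cluster_radius_px(n_nuc, spacing)

        slack = _ENVELOPE_SLACK * spacing
        if config.segregation_mode == "segregated":
            r_t = _cluster_radius_px(n_t, spacing)
            r_b = _cluster_radius_px(n_b, spacing)
            d = config.separation_factor * r_agg
            envelope = d / 2.0 + max(r_t, r_b) + slack + r_cell
        else:
            envelope = r_agg + slack + r_cell

        # place the aggregate centre: inside the gland, envelope fully inside,
        # disjoint from previously placed aggregates (gap of one cell diameter)
        minx, miny, maxx, maxy = gland.bounds
        for attempt in range(1000):
            c = np.array(
                [rng.uniform(minx, maxx), rng.uniform(miny, maxy)]
            )
            p = Point(c)
            if not gland.contains(p) or gland.boundary.distance(p) < envelope:
                continue
            if all(
                np.hypot(*(c - c2)) >= envelope + e2 + 2 * r_cell
                for c2, e2 in placed
            ):
                break
        else:
            raise AggregatePlacementError(
                f"aggregate {idx}: no admissible position after 1000 retries "
                f"(envelope radius {envelope:.1f} px)"
            )
        placed.append((c, envelope))

        if config.segregation_mode == "segregated":
            theta = rng.uniform(0.0, 2.0 * math.pi)
            offset = np.array([math.cos(theta), math.sin(theta)]) * (d / 2.0)
            t_centers = _place_centers_in_disc(rng, n_t, c - offset, r_t, spacing)
            b_centers = _place_centers_in_disc(
                rng, n_b, c + offset, r_b, spacing, existing=t_centers
            )
        else:
            all_centers = _place_centers_in_disc(rng, n_nuc, c, r_agg, spacing)
            t_centers = all_centers[is_t]
            b_centers = all_centers[~is_t]

        # stamp into per-aggregate local rasters for exact truth bookkeeping;
        # the bounding box covers every placed cell disc (clipped identically
        # to the field, so local and global rasters agree)
        centers_all = (
            np.concatenate([t_centers, b_centers])
            if n_nuc
            else np.zeros((0, 2))
        )
        pad = r_cell + 2
        if n_nuc:
            lo_c = max(int(centers_all[:, 0].min() - pad), 0)
            hi_c = min(int(centers_all[:, 0].max() + pad) + 1, w)
            lo_r = max(int(centers_all[:, 1].min() - pad), 0)
            hi_r = min(int(centers_all[:, 1].max() + pad) + 1, h)
        else:
            lo_r = lo_c = 0
            hi_r, hi_c = 1, 1
        local_shape = (hi_r - lo_r, hi_c - lo_c)
        loc_t = np.zeros(local_shape, dtype=bool)
        loc_b = np.zeros(local_shape, dtype=bool)
        shift = np.array([lo_c, lo_r])
        _stamp_discs(loc_t, t_centers - shift, r_cell)
        _stamp_discs(loc_b, b_centers - shift, r_cell)
        identities = np.concatenate(
            [np.ones(n_t, dtype=bool), np.zeros(n_b, dtype=bool)]
        )
        _stamp_discs(dapi_mask, centers_all, r_nuc)
        t_mask[lo_r:hi_r, lo_c:hi_c] |= loc_t
        b_mask[lo_r:hi_r, lo_c:hi_c] |= loc_b

        pa = px * px
        aggregates.append(
            AggregateTruth(
                aggregate_id=idx,
                nucleus_count=n_nuc,
                t_area_um2=float(loc_t.sum()) * pa,
                b_area_um2=float(loc_b.sum()) * pa,
                intersection_area_um2=float((loc_t & loc_b).sum()) * pa,
                union_area_um2=float((loc_t | loc_b).sum()) * pa,
                segregated=config.segregation_mode == "segregated",
                center_xy=(float(c[0]), float(c[1])),
                nucleus_centers=centers_all,
                nucleus_is_t=identities,
            )
        )

    bg = config.background_intensity
    channels: dict[str, np.ndarray] = {}
    for name, mask in (
        (config.dapi_channel, dapi_mask),
        (config.t_channel, t_mask),
        (config.b_channel, b_mask),
    ):
        ch = np.full((h, w), bg, dtype=np.float32)
        ch[mask] += config.intensity_of(name)
        if config.noise_sd > 0:
            ch += rng.normal(0.0, config.noise_sd, size=(h, w)).astype(np.float32)
            np.clip(ch, 0.0, None, out=ch)
        channels[name] = ch

    gland_area_mm2 = (
        gland.area * px * px / 1e6
        if config.gland_polygon is not None
        else w * h * px * px / 1e6
    )
    truth = GroundTruth(gland_area_mm2=gland_area_mm2, aggregates=aggregates)
    return MultiplexImage(channels, px), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _field_seed(seed: int, group: str, field_index: int) -> int:
    """Stable per-field sub-seed derived from (seed, group name, index)."""
    crc = zlib.crc32(group.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=[int(seed), crc, int(field_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    group_configs: Mapping[str, SimulationConfig] | Sequence[tuple[str, SimulationConfig]],
    n_fields_per_group: int,
    seed: int = 0,
) -> list[FieldRecord]:
    """Simulate ``n_fields_per_group`` fields for each named group with
    deterministic per-field sub-seeding derived from (seed, group, index)."""
    if not isinstance(group_configs, Mapping):
        names = [g for g, _ in group_configs]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate group names: {sorted(names)}")
        group_configs = dict(group_configs)
    if not group_configs:
        raise ValueError("at least one group is required")
    if n_fields_per_group < 1:
        raise ValueError("n_fields_per_group must be >= 1")
    records = []
    for group, config in group_configs.items():
        for i in range(n_fields_per_group):
            img, truth = simulate_field(config, seed=_field_seed(seed, group, i))
            records.append(FieldRecord(group, i, img, truth))
    return records


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_field(
    image: MultiplexImage, truth: GroundTruth, out_dir: str | Path, name: str
) -> tuple[Path, Path]:
    """Write one field as a multi-channel TIFF plus a JSON ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{name}.tiff"
    js = out / f"{name}.truth.json"
    write_tiff(image, tif)
    js.write_text(json.dumps(truth.to_dict(), indent=1))
    return tif, js


def cohort_truth_tables(
    records: Iterable[FieldRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool a cohort's truths into tidy tables: one row per field and one row
    per aggregate."""
    field_rows, agg_rows = [], []
    for rec in records:
        t = rec.truth
        field_rows.append(
            {
                "group": rec.group,
                "field_index": rec.field_index,
                "gland_area_mm2": t.gland_area_mm2,
                "n_aggregates": len(t.aggregates),
                "n_foci": t.n_foci,
                "true_focus_score": t.true_focus_score,
                "true_aggregate_area_fraction_pct": t.true_aggregate_area_fraction_pct,
            }
        )
        for a in t.aggregates:
            agg_rows.append(
                {"group": rec.group, "field_index": rec.field_index, **a.to_dict()}
            )
    return pd.DataFrame(field_rows), pd.DataFrame(agg_rows)
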