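"""Image and region I/O: multi-channel TIFF fields, GeoJSON regions, and
pixel-exact conversion between binary masks and polygon regions.

Conventions
-----------
Pixel coordinates are 0-based with the origin at the top-left corner and the
y axis increasing downward (image convention).  Polygon vertices lie on pixel
*corners*: pixel ``(row i, col j)`` covers the unit square
``x in [j, j+1], y in [i, i+1]``.  Because vertices sit on the integer grid,
polygonization and rasterization are mutually exact inverses and polygon area
equals the pixel count of the component it traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union
from skimage.measure import label as _label_components

__all__ = [
    "MultiplexImage",
    "Region",
    "RegionSet",
    "write_tiff",
    "read_tiff",
    "write_geojson",
    "read_geojson",
    "mask_to_regions",
    "regions_to_mask",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MultiplexImage:
    """A calibrated multi-channel fluorescence field.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"DAPI"``, ``"CD3"``, ``"B220"``) to a
        2-D array of non-negative intensities.  All channels must share one
        shape.
    pixel_size_um
        Physical pixel edge length in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiplexImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        (shp,) = shapes
        if len(shp) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shp}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def height_px(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def field_area_um2(self) -> float:
        """Physical area of the full field in µm²."""
        return self.width_px * self.height_px * self.pixel_size_um**2

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available channels: "
                f"{sorted(self.channels)}"
            ) from None


@dataclass
class Region:
    """A labelled planar region (polygon, possibly with holes, or multipolygon)
    in pixel coordinates, with its physical area."""

    geometry: Polygon | MultiPolygon
    label: str
    area_um2: float

    def __post_init__(self) -> None:
        if not isinstance(self.geometry, (Polygon, MultiPolygon)):
            raise TypeError(
                f"region geometry must be Polygon or MultiPolygon, "
                f"got {type(self.geometry).__name__}"
            )
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.label!r}: invalid (self-intersecting?) geometry")


@dataclass
class RegionSet:
    """A collection of labelled regions sharing one pixel calibration."""

    regions: list[Region] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        for r in self.regions:
            expect = r.geometry.area * self.pixel_size_um**2
            if expect > 0 and abs(r.area_um2 - expect) > 1e-6 * expect:
                raise ValueError(
                    f"region {r.label!r}: stored area {r.area_um2} differs from "
                    f"geometric area {expect}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def total_area_um2(self) -> float:
        return float(sum(r.area_um2 for r in self.regions))

    @classmethod
    def from_geometries(
        cls,
        geometries: Sequence[Polygon | MultiPolygon],
        pixel_size_um: float,
        labels: Sequence[str] | None = None,
    ) -> "RegionSet":
        if labels is None:
            labels = [f"region_{i}" for i in range(len(geometries))]
        regs = [
            Region(g, lab, g.area * pixel_size_um**2)
            for g, lab in zip(geometries, labels, strict=True)
        ]
        return cls(regs, pixel_size_um)


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_tiff(image: MultiplexImage, path: str | Path) -> None:
    """Write a multi-channel TIFF with channel names and pixel calibration
    stored in the image description (tifffile "shaped" JSON metadata)."""
    names = image.channel_names
    stack = np.stack([image.channels[n] for n in names], axis=0)
    planar = {"planarconfig": "separate"} if len(names) > 1 else {}
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        **planar,
        metadata={
            "axes": "CYX",
            "channel_names": names,
            "pixel_size_um": image.pixel_size_um,
        },
    )


def read_tiff(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
) -> MultiplexImage:
    """Read a multi-channel TIFF written by :func:`write_tiff` (or any plain
    2-D/3-D TIFF given explicit ``channel_names`` and ``pixel_size_um``).

    Raises
    ------
    ValueError
        If the file carries no pixel-size metadata and ``pixel_size_um`` is
        not supplied.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta: Mapping = {}
        if tf.shaped_metadata:
            meta = tf.shaped_metadata[0]

    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {data.shape}")

    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no pixel-size metadata found; pass pixel_size_um "
            "explicitly to calibrate the image"
        )

    if channel_names is None:
        channel_names = meta.get("channel_names")
    if channel_names is None:
        channel_names = [f"channel_{i}" for i in range(data.shape[0])]
    if len(channel_names) != data.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names supplied for "
            f"{data.shape[0]} channels"
        )

    channels = {str(n): data[i] for i, n in enumerate(channel_names)}
    return MultiplexImage(channels, float(pixel_size_um))


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(regions: RegionSet, path: str | Path) -> None:
    """Write regions as a GeoJSON FeatureCollection (QuPath-style: one feature
    per region, label under the ``label`` property, pixel coordinates,
    y increasing downward)."""
    features = []
    for r in regions:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {"label": r.label, "area_um2": r.area_um2},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "pixel_size_um": regions.pixel_size_um,
    }
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path, pixel_size_um: float | None = None) -> RegionSet:
    """Read a FeatureCollection of polygons back into a :class:`RegionSet`.

    Raises
    ------
    ValueError
        If a feature carries a non-polygon geometry (the offending feature
        index is named).
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    if pixel_size_um is None:
        pixel_size_um = doc.get("pixel_size_um", 1.0)
    regions = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise ValueError(
                f"{path}: feature {i} has non-polygon geometry "
                f"{geom.geom_type!r}"
            )
        props = feat.get("properties") or {}
        lab = str(props.get("label", f"region_{i}"))
        area = float(props.get("area_um2", geom.area * pixel_size_um**2))
        regions.append(Region(geom, lab, area))
    return RegionSet(regions, float(pixel_size_um))


# ---------------------------------------------------------------------------
# Mask <-> polygon conversion
# ---------------------------------------------------------------------------

def _component_polygon(rows: np.ndarray, cols: np.ndarray) -> Polygon | MultiPolygon:
    """Exact polygon of a set of pixels, as the union of per-row run
    rectangles.  Vertices are integers (pixel corners), so the polygon area
    equals the pixel count exactly."""
    boxes = []
    for r in np.unique(rows):
        cs = np.sort(cols[rows == r])
        # split into maximal horizontal runs
        breaks = np.nonzero(np.diff(cs) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(cs) - 1]))
        for s, e in zip(starts, ends):
            boxes.append(box(float(cs[s]), float(r), float(cs[e] + 1), float(r + 1)))
    geom = unary_union(boxes)
    if isinstance(geom, (Polygon, MultiPolygon)):
        return geom
    raise RuntimeError(f"unexpected geometry from pixel union: {geom.geom_type}")


def mask_to_regions(
    mask: np.ndarray,
    pixel_size_um: float,
    connectivity: int = 8,
    min_area_um2: float = 0.0,
) -> RegionSet:
    """Polygonize a binary mask: one region per connected component.

    Components smaller than ``min_area_um2`` are dropped.  The traced polygon
    follows pixel boundaries exactly, so each region's area equals its pixel
    count times the pixel area.  8-connected components that touch only at a
    pixel corner polygonize to a MultiPolygon.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    lab = _label_components(mask, connectivity=1 if connectivity == 4 else 2)
    geoms = []
    labels = []
    for comp in range(1, lab.max() + 1):
        rows, cols = np.nonzero(lab == comp)
        area = len(rows) * pixel_size_um**2
        if area < min_area_um2:
            continue
        geoms.append(_component_polygon(rows, cols))
        labels.append(f"region_{len(labels)}")
    return RegionSet.from_geometries(geoms, pixel_size_um, labels)


def regions_to_mask(regions: RegionSet, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize regions back to a binary mask of the given (rows, cols)
    shape.  A pixel is set when its centre lies inside a region; for polygons
    traced by :func:`mask_to_regions` this inverts the polygonization exactly
    (pixel centres are at half-integers, never on the integer-grid boundary).
    """
    out = np.zeros(shape, dtype=bool)
    for r in regions:
        minx, miny, maxx, maxy = r.geometry.bounds
        c0 = max(int(np.floor(minx)), 0)
        r0 = max(int(np.floor(miny)), 0)
        c1 = min(int(np.ceil(maxx)), shape[1])
        r1 = min(int(np.ceil(maxy)), shape[0])
        if c1 <= c0 or r1 <= r0:
            continue
        cc, rr = np.meshgrid(
            np.arange(c0, c1, dtype=float) + 0.5,
            np.arange(r0, r1, dtype=float) + 0.5,
        )
        inside = shapely.contains_xy(r.geometry, cc.ravel(), rr.ravel())
        out[r0:r1, c0:c1] |= inside.reshape(rr.shape)
    return out
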