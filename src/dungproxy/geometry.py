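"""UAV footprint geometry, flight routes, and spatial exclusion rules.

The fixed-point aerial survey design revisits preset waypoints at two
flight heights: a high "Rectangle" route (20 m, large footprints, coarse
ground sampling distance) and a low "Belt" route (2 m, small footprints,
sub-centimetre GSD).  This module maps camera and flight-height parameters
to ground coverage, lays out waypoint grids, and applies the spatial
exclusion rules used in household-pasture surveys: a buffer along the
fence (edge effects, fuel collection) and a buffer around the campsite
(dung collection and drying), plus exclusion of images dominated by
riverbed.

Coordinates are planar metres (x east, y north) in a local CRS whose
origin is the south-west corner of the pasture bounding box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, box


class InvalidCameraError(ValueError):
    """Camera parameters that cannot produce a footprint."""


@dataclass(frozen=True)
class CameraModel:
    """Physical sensor and lens parameters of an onboard camera.

    All linear dimensions in millimetres; pixel counts are the image size
    along the same axes as the sensor width/length.
    """

    sensor_width_mm: float
    sensor_length_mm: float
    focal_length_mm: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self) -> None:
        for name in ("sensor_width_mm", "sensor_length_mm", "focal_length_mm",
                     "image_width_px", "image_height_px"):
            if getattr(self, name) <= 0:
                raise InvalidCameraError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Footprint:
    """Axis-aligned ground rectangle covered by one aerial image.

    ``width_m`` spans east-west (x), ``length_m`` north-south (y).  UAV yaw
    is ignored: repeated fixed-point captures are treated as axis-aligned.
    """

    center_xy: tuple[float, float]
    width_m: float
    length_m: float

    def __post_init__(self) -> None:
        if self.width_m < 0 or self.length_m < 0:
            raise ValueError("footprint dimensions must be >= 0")

    @property
    def area_m2(self) -> float:
        return self.width_m * self.length_m

    def polygon(self) -> Polygon:
        cx, cy = self.center_xy
        return box(cx - self.width_m / 2, cy - self.length_m / 2,
                   cx + self.width_m / 2, cy + self.length_m / 2)


@dataclass
class FlightRoute:
    """An ordered set of waypoint centres flown at a fixed height."""

    route_kind: str                     # "Rectangle" | "Belt"
    waypoints: list[tuple[float, float]]
    flight_height_m: float
    extent: tuple[float, float]         # (width_m, length_m) of routed area
    outside_pasture: list[int] = field(default_factory=list)


#: Default route layouts: (grid cols x rows, extent width x length, height).
#: Rectangle: 12 waypoints over 100 m x 200 m at 20 m.
#: Belt: 16 waypoints over 40 m x 40 m at 2 m.
ROUTE_DEFAULTS = {
    "Rectangle": {"grid": (3, 4), "extent": (100.0, 200.0), "flight_height_m": 20.0},
    "Belt": {"grid": (4, 4), "extent": (40.0, 40.0), "flight_height_m": 2.0},
}


@dataclass
class PastureGeometry:
    """A fenced household pasture with its campsite concentrator.

    The effective sampling region is the boundary shrunk by the fence
    buffer, minus a disc around the campsite.
    """

    boundary: Polygon
    campsite: Point
    riverbed: Polygon | None = None
    fence_buffer_m: float = 50.0
    campsite_buffer_m: float = 150.0

    def __post_init__(self) -> None:
        if self.fence_buffer_m < 0 or self.campsite_buffer_m < 0:
            raise ValueError("buffers must be >= 0")
        if not self.boundary.covers(self.campsite):
            raise ValueError("campsite must lie inside the pasture boundary")

    def effective_region(self) -> Polygon:
        region = self.boundary.buffer(-self.fence_buffer_m)
        if self.campsite_buffer_m > 0:
            region = region.difference(self.campsite.buffer(self.campsite_buffer_m))
        if region.is_empty or region.area <= 0:
            raise ValueError("exclusion buffers leave an empty effective region")
        return region

    @property
    def area_ha(self) -> float:
        return self.boundary.area / 1e4


def footprint_dimensions(camera: CameraModel, flight_height_m: float) -> tuple[float, float]:
    """Ground coverage (width, length) in metres of one image.

    Width = S_w * H / (f * 1000) with H in mm, i.e. the familiar pinhole
    scaling width = sensor_width * height / focal_length once units cancel.
    """
    if flight_height_m < 0:
        raise ValueError("flight height must be >= 0")
    h_mm = flight_height_m * 1000.0
    width = camera.sensor_width_mm * h_mm / camera.focal_length_mm / 1000.0
    length = camera.sensor_length_mm * h_mm / camera.focal_length_mm / 1000.0
    return width, length


def ground_sampling_distance(camera: CameraModel, flight_height_m: float) -> float:
    """Ground length of one image pixel, in cm per pixel."""
    if flight_height_m <= 0:
        raise ValueError("flight height must be > 0 for a GSD")
    width, _ = footprint_dimensions(camera, flight_height_m)
    return width * 100.0 / camera.image_width_px


def footprint_at(camera: CameraModel, flight_height_m: float,
                 center_xy: tuple[float, float]) -> Footprint:
    """Footprint of an image captured at ``center_xy`` from the given height."""
    width, length = footprint_dimensions(camera, flight_height_m)
    return Footprint(center_xy=tuple(center_xy), width_m=width, length_m=length)


def generate_route(kind: str, anchor_xy: tuple[float, float],
                   grid: tuple[int, int] | None = None,
                   extent: tuple[float, float] | None = None,
                   flight_height_m: float | None = None,
                   pasture: PastureGeometry | None = None) -> FlightRoute:
    """Lay out an evenly spaced waypoint grid centred on ``anchor_xy``.

    Defaults reproduce the survey design: Rectangle = 3 x 4 grid over
    100 m x 200 m at 20 m (12 waypoints); Belt = 4 x 4 over 40 m x 40 m at
    2 m (16 waypoints).  If a pasture is given and some waypoints fall
    outside its boundary, a warning is issued and their indices recorded.
    """
    if kind not in ROUTE_DEFAULTS:
        raise ValueError(f"unknown route kind {kind!r}")
    defaults = ROUTE_DEFAULTS[kind]
    ncols, nrows = grid if grid is not None else defaults["grid"]
    ext_w, ext_l = extent if extent is not None else defaults["extent"]
    height = flight_height_m if flight_height_m is not None else defaults["flight_height_m"]
    if ncols < 1 or nrows < 1:
        raise ValueError("grid must be at least 1 x 1")

    ax, ay = anchor_xy
    dx, dy = ext_w / ncols, ext_l / nrows
    waypoints = [
        (ax - ext_w / 2 + (i + 0.5) * dx, ay - ext_l / 2 + (j + 0.5) * dy)
        for j in range(nrows) for i in range(ncols)
    ]
    outside: list[int] = []
    if pasture is not None:
        outside = [i for i, (x, y) in enumerate(waypoints)
                   if not pasture.boundary.covers(Point(x, y))]
        if outside:
            warnings.warn(
                f"{len(outside)} of {len(waypoints)} waypoints fall outside "
                "the pasture boundary", stacklevel=2)
    return FlightRoute(route_kind=kind, waypoints=waypoints,
                       flight_height_m=height, extent=(ext_w, ext_l),
                       outside_pasture=outside)


def apply_exclusion_zones(
    pasture: PastureGeometry,
    waypoints: list[tuple[float, float]],
) -> tuple[list[tuple[float, float]], Polygon]:
    """Drop waypoints in the fence or campsite buffer; return the effective region.

    A waypoint is retained iff its footprint centre lies inside the
    effective sampling region (boundary minus both buffers).
    """
    region = pasture.effective_region()
    retained = [wp for wp in waypoints if region.covers(Point(wp))]
    return retained, region


def waypoint_exclusion_reasons(
    pasture: PastureGeometry,
    waypoints: list[tuple[float, float]],
) -> list[str]:
    """Per-waypoint exclusion label: '', 'fence_buffer' or 'campsite_buffer'."""
    inner = pasture.boundary.buffer(-pasture.fence_buffer_m)
    reasons = []
    for wp in waypoints:
        p = Point(wp)
        if not inner.covers(p):
            reasons.append("fence_buffer")
        elif p.distance(pasture.campsite) < pasture.campsite_buffer_m:
            reasons.append("campsite_buffer")
        else:
            reasons.append("")
    return reasons


def riverbed_overlap_fraction(footprint: Footprint, riverbed_polygon: Polygon) -> float:
    """Fraction of the image footprint covered by riverbed."""
    if footprint.area_m2 <= 0:
        raise ValueError("degenerate footprint with zero area")
    if riverbed_polygon is None or riverbed_polygon.is_empty:
        return 0.0
    poly = footprint.polygon()
    return poly.intersection(riverbed_polygon).area / poly.area


def riverbed_image_filter(footprint: Footprint, riverbed_polygon: Polygon | None,
                          threshold: float = 0.5) -> str:
    """Keep or exclude an image footprint by riverbed coverage.

    Returns ``"exclude"`` iff the riverbed covers at least ``threshold`` of
    the footprint area (tie at exactly the threshold excludes: near-half
    riverbed coverage is the documented reason for dropping such images),
    else ``"keep"``.
    """
    frac = riverbed_overlap_fraction(footprint, riverbed_polygon) \
        if riverbed_polygon is not None else 0.0
    return "exclude" if frac >= threshold else "keep"
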