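"""Montage geometry: aperture centroid finding, ROI transforms, tile planning.

Coordinate conventions used throughout the package:

* stage coordinates are in micrometres, x to the right, y up;
* pixel coordinates have their origin at the top-left corner, row-major,
  so a positive stage move in y shifts scene content *down* in the image;
* all rectangles are half-open: ``[x, x + w) x [y, y + h)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, field_validator

from .errors import CentroidError

log = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "ROISpec",
    "StageROI",
    "MontagePlan",
    "SupertilePlan",
    "transform_roi",
    "inverse_transform_roi",
    "plan_montage",
    "min_overlap_under_error",
    "plan_supertile",
    "find_aperture_centroid",
    "frame_megapixels",
    "area_of_view_um2",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in stage micrometres (y up)."""

    x: float
    y: float
    w: float
    h: float

    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x1 and self.y <= py < self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            other.x >= self.x
            and other.y >= self.y
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )


class ROISpec(BaseModel):
    """Region of interest defined relative to the aperture centroid.

    Offsets are physical distances (µm) from the aperture centroid; the
    rotation is applied about the ROI centre.
    """

    offset_um: tuple[float, float] = (0.0, 0.0)
    size_um: tuple[float, float]
    rotation_deg: float = 0.0

    @field_validator("size_um")
    @classmethod
    def _positive_size(cls, v: tuple[float, float]) -> tuple[float, float]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("ROI size must be positive in both axes")
        return v


@dataclass(frozen=True)
class StageROI:
    """An ROI resolved into absolute stage coordinates."""

    center_um: tuple[float, float]
    size_um: tuple[float, float]
    rotation_deg: float = 0.0

    @property
    def bounding_rect(self) -> Rect:
        """Axis-aligned bounding rectangle of the (possibly rotated) ROI."""
        w, h = self.size_um
        th = math.radians(self.rotation_deg)
        bw = abs(w * math.cos(th)) + abs(h * math.sin(th))
        bh = abs(w * math.sin(th)) + abs(h * math.cos(th))
        cx, cy = self.center_um
        return Rect(cx - bw / 2.0, cy - bh / 2.0, bw, bh)


def normalize_angle_deg(angle: float) -> float:
    """Normalize an angle to the half-open interval (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def _rot(vec: tuple[float, float], deg: float) -> tuple[float, float]:
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return (c * vec[0] - s * vec[1], s * vec[0] + c * vec[1])


def transform_roi(
    roi: ROISpec,
    centroid_stage_um: tuple[float, float],
    beam_rotation_deg: float = 0.0,
) -> StageROI:
    """Resolve an aperture-relative ROI into absolute stage coordinates.

    The ROI offset vector is rotated by the magnification-specific beam
    rotation and translated to the measured aperture centroid; the ROI's
    own rotation composes with the beam rotation to give the final
    orientation about the ROI centre.
    """
    dx, dy = _rot(roi.offset_um, beam_rotation_deg)
    return StageROI(
        center_um=(centroid_stage_um[0] + dx, centroid_stage_um[1] + dy),
        size_um=roi.size_um,
        rotation_deg=normalize_angle_deg(roi.rotation_deg + beam_rotation_deg),
    )


def inverse_transform_roi(
    stage_roi: StageROI,
    centroid_stage_um: tuple[float, float],
    beam_rotation_deg: float = 0.0,
) -> ROISpec:
    """Invert :func:`transform_roi`; composing the two is the identity."""
    rel = (
        stage_roi.center_um[0] - centroid_stage_um[0],
        stage_roi.center_um[1] - centroid_stage_um[1],
    )
    return ROISpec(
        offset_um=_rot(rel, -beam_rotation_deg),
        size_um=stage_roi.size_um,
        rotation_deg=normalize_angle_deg(stage_roi.rotation_deg - beam_rotation_deg),
    )


@dataclass
class MontagePlan:
    """Ordered raster grid of ideal tile stage positions.

    Tiles are centred on the ROI so any overhang is symmetric; visiting
    order is row-major (row 0 at the top of the ROI, columns left to
    right), optionally serpentine.
    """

    fov_um: float
    overlap_frac: float
    n_cols: int
    n_rows: int
    tile_centers_um: list[tuple[float, float]] = field(repr=False)
    ideal_neighbor_offset_px: tuple[float, float] | None = None
    serpentine: bool = False

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def step_um(self) -> float:
        return self.fov_um * (1.0 - self.overlap_frac)

    def tile_rect(self, row: int, col: int) -> Rect:
        cx, cy = self.tile_centers_um[row * self.n_cols + col]
        return Rect(cx - self.fov_um / 2.0, cy - self.fov_um / 2.0, self.fov_um, self.fov_um)

    def index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def to_dict(self) -> dict:
        return {
            "fov_um": self.fov_um,
            "overlap_frac": self.overlap_frac,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "tile_centers_um": [list(c) for c in self.tile_centers_um],
            "ideal_neighbor_offset_px": (
                list(self.ideal_neighbor_offset_px)
                if self.ideal_neighbor_offset_px is not None
                else None
            ),
            "serpentine": self.serpentine,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MontagePlan":
        return cls(
            fov_um=d["fov_um"],
            overlap_frac=d["overlap_frac"],
            n_cols=d["n_cols"],
            n_rows=d["n_rows"],
            tile_centers_um=[tuple(c) for c in d["tile_centers_um"]],
            ideal_neighbor_offset_px=(
                tuple(d["ideal_neighbor_offset_px"])
                if d.get("ideal_neighbor_offset_px") is not None
                else None
            ),
            serpentine=d.get("serpentine", False),
        )


def _tiles_per_axis(extent: float, fov: float, step: float) -> int:
    if extent <= fov:
        return 1
    return 1 + math.ceil((extent - fov) / step)


def plan_montage(
    roi_stage: StageROI | Rect,
    fov_um: float,
    overlap_frac: float,
    frame_px: int | None = None,
    serpentine: bool = False,
) -> MontagePlan:
    """Plan a raster montage covering ``roi_stage`` with square tiles.

    The step between neighbouring tile centres is ``fov × (1 − overlap)``;
    per axis the tile count is 1 if the ROI extent fits in one field of
    view and ``1 + ceil((extent − fov)/step)`` otherwise, which guarantees
    the planned tiles cover the ROI with at least the requested linear
    overlap between ideal neighbours.
    """
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    if fov_um <= 0:
        raise ValueError("fov_um must be positive")
    rect = roi_stage.bounding_rect if isinstance(roi_stage, StageROI) else roi_stage

    step = fov_um * (1.0 - overlap_frac)
    n_cols = _tiles_per_axis(rect.w, fov_um, step)
    n_rows = _tiles_per_axis(rect.h, fov_um, step)

    span_x = fov_um + (n_cols - 1) * step
    span_y = fov_um + (n_rows - 1) * step
    x0 = rect.cx - span_x / 2.0 + fov_um / 2.0
    # row 0 is the top row (largest y); stage y is up.
    y0 = rect.cy + span_y / 2.0 - fov_um / 2.0

    centers: list[tuple[float, float]] = []
    for r in range(n_rows):
        cols = range(n_cols)
        if serpentine and r % 2 == 1:
            cols = range(n_cols - 1, -1, -1)
        for c in cols:
            centers.append((x0 + c * step, y0 - r * step))

    offset_px = None
    if frame_px is not None:
        offset_px = (frame_px * (1.0 - overlap_frac), frame_px * (1.0 - overlap_frac))
    return MontagePlan(
        fov_um=fov_um,
        overlap_frac=overlap_frac,
        n_cols=n_cols,
        n_rows=n_rows,
        tile_centers_um=centers,
        ideal_neighbor_offset_px=offset_px,
        serpentine=serpentine,
    )


def min_overlap_under_error(
    overlap_frac: float,
    max_err_frac_per_tile: float,
    stitching_min: float = 0.07,
) -> float:
    """Worst-case realized linear overlap when both neighbouring tiles are
    displaced by the maximum per-tile positioning error (in opposite
    directions), floored at zero.

    A nominal 13% overlap with a 3% worst-case per-tile error still
    guarantees the 7% overlap needed for stitching feature matches.
    """
    if not (0.0 <= overlap_frac < 1.0) or not (0.0 <= max_err_frac_per_tile < 1.0):
        raise ValueError("arguments must be in [0, 1)")
    worst = max(0.0, overlap_frac - 2.0 * max_err_frac_per_tile)
    if worst < stitching_min:
        warnings.warn(
            f"worst-case overlap {worst:.3f} is below the stitching minimum "
            f"{stitching_min:.3f}",
            stacklevel=2,
        )
    return worst


@dataclass(frozen=True)
class SupertilePlan:
    """Composite-image geometry for an n x n beam-deflection sub-grid
    acquired at a single stage position."""

    subtile_px: int
    grid_n: int
    overlap_frac: float
    composite_px_side: int
    stage_moves_eliminated: int

    @property
    def megapixels(self) -> float:
        return self.composite_px_side**2 / 1e6


def plan_supertile(subtile_px: int, grid_n: int, overlap_frac: float) -> SupertilePlan:
    """Geometry of a supertile: the composite side grows by one subtile
    stride, ``subtile × (1 − overlap)``, per extra grid position."""
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    side = int(round(subtile_px * (1.0 + (grid_n - 1) * (1.0 - overlap_frac))))
    return SupertilePlan(
        subtile_px=subtile_px,
        grid_n=grid_n,
        overlap_frac=overlap_frac,
        composite_px_side=side,
        stage_moves_eliminated=grid_n**2 - 1,
    )


def frame_megapixels(frame_px: int) -> float:
    """Pixels per square camera frame, in megapixels."""
    return frame_px**2 / 1e6


def area_of_view_um2(fov_um_side: float) -> float:
    """Area of view of a square field, in µm^2."""
    return fov_um_side**2


# ---------------------------------------------------------------------------
# Aperture centroid finding
# ---------------------------------------------------------------------------


def _probe_brightness(scope, x_um: float, y_um: float, probe_px: int) -> float:
    scope.move_stage((x_um, y_um))
    frame = scope.render_frame(size_px=probe_px)
    return float(np.mean(frame.pixels))


def find_aperture_centroid(
    scope,
    intensity_threshold: float | None = None,
    tol_um: float = 1.0,
    search_range_um: float | None = None,
    probe_px: int = 32,
) -> tuple[float, float]:
    """Locate the aperture centroid in stage coordinates.

    For each of the four aperture edges (top, bottom, left, right) a
    binary search over stage positions finds the bright-to-dark
    transition to within ``tol_um``; the centroid is the midpoint of
    opposing edges.  The frame budget is bounded by
    ``4 × ceil(log2(range / tol)) + constant`` probe renders.
    """
    if intensity_threshold is None:
        # midpoint between open-aperture signal and opaque tape
        intensity_threshold = float(scope.beam.dark_level + 0.3 * scope.beam.signal_full)
    if search_range_um is None:
        b = scope.stage.bounds
        search_range_um = max(b.w, b.h) / 2.0

    x0, y0 = scope.stage.position
    if _probe_brightness(scope, x0, y0, probe_px) < intensity_threshold:
        raise CentroidError(
            "starting stage position is not inside the aperture (dark probe)"
        )

    edges: dict[str, float] = {}
    for name, axis, sign in (
        ("right", 0, +1.0),
        ("left", 0, -1.0),
        ("top", 1, +1.0),
        ("bottom", 1, -1.0),
    ):
        lo = 0.0  # distance from start, known bright
        hi = search_range_um  # candidate dark side
        pt = [x0, y0]
        pt[axis] = (x0, y0)[axis] + sign * hi
        bounds = scope.stage.bounds
        # clamp the outer probe to the stage range
        pt[0] = min(max(pt[0], bounds.x), bounds.x1 - 1e-9)
        pt[1] = min(max(pt[1], bounds.y), bounds.y1 - 1e-9)
        hi = abs(pt[axis] - (x0, y0)[axis])
        if _probe_brightness(scope, pt[0], pt[1], probe_px) >= intensity_threshold:
            raise CentroidError(
                f"{name} edge: bright-to-dark transition not bracketed within "
                f"{search_range_um:.0f} um"
            )
        while hi - lo > tol_um:
            mid = (lo + hi) / 2.0
            pt = [x0, y0]
            pt[axis] = (x0, y0)[axis] + sign * mid
            if _probe_brightness(scope, pt[0], pt[1], probe_px) >= intensity_threshold:
                lo = mid
            else:
                hi = mid
        edges[name] = (x0, y0)[axis] + sign * (lo + hi) / 2.0

    cx = (edges["left"] + edges["right"]) / 2.0
    cy = (edges["bottom"] + edges["top"]) / 2.0
    scope.move_stage((cx, cy))
    log.debug("aperture centroid at (%.2f, %.2f) um", cx, cy)
    return (cx, cy)
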