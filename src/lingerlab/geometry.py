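"""Y-bifurcation coordinate frame, regions of interest, and lateral coordinates.

The device is a symmetric diverging bifurcation: a parent microchannel of
rectangular cross-section (width ``W``, height ``H``) splits into two daughter
channels of the same cross-section at a branch angle of 120 degrees.  The
analysis frame places the intersection center at the origin with the parent
axis along +x (flow in +x); the two daughter axes point downstream at
``±branch_angle/2`` from +x and are mirror images across the parent centerline
(the separation axis, here the x-axis).

Four regions of interest (ROIs) partition the analysed field of view: a
rectangular ROI in the parent and in each daughter, each of length
``roi_length`` starting ``roi_offset`` from the intersection center, plus the
central intersection region.  The bifurcation apex — the wall vertex at the
flow divider — is the intersection point of the two daughters' distal walls
and lies on the separation axis downstream of the origin.

Lateral positions are expressed as the normalised coordinate ``y* = y/W`` in
[-0.5, 0.5].  In the daughters the convention follows the flow direction:
proximal wall at y* = -0.5, distal wall (the one meeting the apex) at
y* = +0.5.  In the parent, positive y* points toward daughter 1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon


class InvalidConfigurationError(ValueError):
    """A geometry or analysis parameter violates its constraints."""


class OutOfChannelError(ValueError):
    """A position lies laterally outside the channel it was assigned to."""


class NotApplicableError(ValueError):
    """The requested quantity is undefined for this trajectory."""


class RoiLabel(enum.Enum):
    PARENT = "parent"
    DAUGHTER1 = "daughter1"
    DAUGHTER2 = "daughter2"
    INTERSECTION = "intersection"
    OUTSIDE = "outside"


#: ROI labels carrying a well-defined lateral coordinate.
CHANNEL_ROIS = (RoiLabel.PARENT, RoiLabel.DAUGHTER1, RoiLabel.DAUGHTER2)


@dataclass(frozen=True)
class BifurcationGeometry:
    """Fully resolved geometry of the symmetric Y-bifurcation.

    Lengths in micrometres, angles in degrees.  Defaults reproduce the
    reference microfluidic device: W = 9.6 um, H = 8 um channels of length
    120 um meeting at 120 degrees, with 33.2 um ROIs offset 5.5 um from the
    intersection center.
    """

    width: float = 9.6
    height: float = 8.0
    channel_length: float = 120.0
    branch_angle: float = 120.0
    roi_length: float = 33.2
    roi_offset: float = 5.5

    # derived, filled in __post_init__
    apex: np.ndarray = field(init=False, repr=False, compare=False)
    intersection_center: np.ndarray = field(init=False, repr=False, compare=False)
    parent_axis: np.ndarray = field(init=False, repr=False, compare=False)
    daughter1_axis: np.ndarray = field(init=False, repr=False, compare=False)
    daughter2_axis: np.ndarray = field(init=False, repr=False, compare=False)
    intersection_polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("width", "height", "channel_length", "roi_length"):
            if not getattr(self, name) > 0:
                raise InvalidConfigurationError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.roi_offset < 0:
            raise InvalidConfigurationError(f"roi_offset must be >= 0, got {self.roi_offset!r}")
        if not 0 < self.branch_angle < 180:
            raise InvalidConfigurationError(
                f"branch_angle must be in (0, 180) degrees, got {self.branch_angle!r}"
            )
        half = math.radians(self.branch_angle) / 2.0
        d1 = np.array([math.cos(half), math.sin(half)])
        d2 = np.array([math.cos(half), -math.sin(half)])
        object.__setattr__(self, "parent_axis", np.array([1.0, 0.0]))
        object.__setattr__(self, "daughter1_axis", d1)
        object.__setattr__(self, "daughter2_axis", d2)
        object.__setattr__(self, "intersection_center", np.zeros(2))
        # Apex: intersection of the two daughters' distal walls (each offset
        # W/2 from its axis toward the separation axis); lies on the x-axis.
        object.__setattr__(self, "apex", np.array([self.width / 2.0 / math.sin(half), 0.0]))
        object.__setattr__(self, "intersection_polygon", self._build_intersection_polygon())

    def _build_intersection_polygon(self) -> Polygon:
        """Convex region bounded by the three ROI near-edges and channel walls."""
        w2 = self.width / 2.0
        s0 = self.roi_offset
        corners = []
        # parent near edge at x = -roi_offset
        corners.append((-s0, +w2))
        corners.append((-s0, -w2))
        for d in (self.daughter1_axis, self.daughter2_axis):
            n = np.array([-d[1], d[0]])  # left normal
            for sgn in (+1.0, -1.0):
                p = s0 * d + sgn * w2 * n
                corners.append((p[0], p[1]))
        return Polygon(corners).convex_hull

    # -- axis bookkeeping -------------------------------------------------

    def channel_axis(self, roi: RoiLabel) -> np.ndarray:
        if roi is RoiLabel.PARENT:
            return self.parent_axis
        if roi is RoiLabel.DAUGHTER1:
            return self.daughter1_axis
        if roi is RoiLabel.DAUGHTER2:
            return self.daughter2_axis
        raise ValueError(f"{roi} has no channel axis")

    def axial_lateral(self, position, roi: RoiLabel) -> tuple[float, float]:
        """Signed (axial, lateral) coordinates of a point in a channel frame.

        Axial grows downstream.  Lateral is the signed offset from the channel
        axis along the axis' left normal (counter-clockwise).  For the parent
        the axial coordinate of points upstream of the intersection center is
        negative.
        """
        p = np.asarray(position, dtype=float)
        d = self.channel_axis(roi)
        n = np.array([-d[1], d[0]])
        return float(p @ d), float(p @ n)

    def roi_axial_range(self, roi: RoiLabel) -> tuple[float, float]:
        """Downstream axial extent [near, far] of a channel ROI."""
        if roi is RoiLabel.PARENT:
            return (-self.roi_offset - self.roi_length, -self.roi_offset)
        return (self.roi_offset, self.roi_offset + self.roi_length)

    def roi_volume(self) -> float:
        """Volume (um^3) of one channel ROI: roi_length * W * H."""
        return self.roi_length * self.width * self.height


def make_default_geometry(overrides: dict | None = None) -> BifurcationGeometry:
    """Build the reference bifurcation geometry, optionally overriding fields.

    Parameters
    ----------
    overrides
        Mapping of :class:`BifurcationGeometry` field names (``width``,
        ``height``, ``channel_length``, ``branch_angle``, ``roi_length``,
        ``roi_offset``) to replacement values.

    Raises
    ------
    InvalidConfigurationError
        If an override names an unknown field or violates an invariant.
    """
    overrides = dict(overrides or {})
    allowed = {"width", "height", "channel_length", "branch_angle", "roi_length", "roi_offset"}
    unknown = set(overrides) - allowed
    if unknown:
        raise InvalidConfigurationError(f"unknown geometry override(s): {sorted(unknown)}")
    return BifurcationGeometry(**overrides)


def assign_roi(position, geom: BifurcationGeometry) -> RoiLabel:
    """Label the region of interest containing a point (OUTSIDE is the catch-all)."""
    p = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    w2 = geom.width / 2.0
    for roi in CHANNEL_ROIS:
        a, c = geom.axial_lateral(p, roi)
        lo, hi = geom.roi_axial_range(roi)
        if lo <= a <= hi and abs(c) <= w2:
            return roi
    if geom.intersection_polygon.covers(Point(p[0], p[1])):
        return RoiLabel.INTERSECTION
    return RoiLabel.OUTSIDE


def assign_roi_array(xy: np.ndarray, geom: BifurcationGeometry) -> np.ndarray:
    """Vectorised :func:`assign_roi` over an (n, 2) array; returns object array of RoiLabel."""
    xy = np.asarray(xy, dtype=float)
    out = np.full(len(xy), RoiLabel.OUTSIDE, dtype=object)
    w2 = geom.width / 2.0
    unassigned = np.ones(len(xy), dtype=bool)
    for roi in CHANNEL_ROIS:
        d = geom.channel_axis(roi)
        n = np.array([-d[1], d[0]])
        a = xy @ d
        c = xy @ n
        lo, hi = geom.roi_axial_range(roi)
        hit = unassigned & (a >= lo) & (a <= hi) & (np.abs(c) <= w2)
        out[hit] = roi
        unassigned &= ~hit
    if unassigned.any():
        import shapely

        idx = np.flatnonzero(unassigned)
        # intersects == covers for a point: boundary points count as inside
        inside = shapely.intersects_xy(geom.intersection_polygon, xy[idx, 0], xy[idx, 1])
        out[idx[inside]] = RoiLabel.INTERSECTION
    return out


def lateral_coordinate(
    position,
    geom: BifurcationGeometry,
    roi: RoiLabel,
    *,
    tolerance: float = 1e-9,
) -> float:
    """Normalised lateral coordinate y* = y/W in [-0.5, 0.5] within a channel.

    Sign conventions: in the daughters the proximal wall is y* = -0.5 and the
    distal wall (meeting the apex) is y* = +0.5; in the parent, positive y*
    points toward daughter 1.

    Parameters
    ----------
    tolerance
        Permitted lateral overshoot beyond the walls, in fractions of W;
        positions further out raise :class:`OutOfChannelError`.
    """
    if roi not in CHANNEL_ROIS:
        raise ValueError(f"lateral coordinate undefined for {roi}")
    _, c = geom.axial_lateral(position, roi)
    if roi is RoiLabel.PARENT:
        y_star = c / geom.width
    elif roi is RoiLabel.DAUGHTER1:
        # distal wall of daughter 1 sits at lateral offset -W/2 (toward the
        # separation axis); flip the sign so it maps to +0.5
        y_star = -c / geom.width
    else:
        y_star = +c / geom.width
    if abs(y_star) > 0.5 + tolerance:
        raise OutOfChannelError(
            f"position lies {abs(y_star):.3f} channel widths from the {roi.value} axis"
        )
    return float(np.clip(y_star, -0.5, 0.5))


def apex_distance(position, geom: BifurcationGeometry) -> float:
    """Euclidean in-plane distance (um) from a point to the bifurcation apex."""
    p = np.asarray(position, dtype=float)
    return float(np.hypot(p[0] - geom.apex[0], p[1] - geom.apex[1]))


def crossed_separation_axis(traj, geom: BifurcationGeometry, *, dead_band: float = 0.0) -> bool:
    """Whether a cell crossed the parent-vessel symmetry axis.

    Considers only frames whose centroid lies in the PARENT ROI; the cell
    crossed iff the signed lateral coordinate changes sign between two
    consecutive such frames.  Frames with |y*| <= ``dead_band`` are dropped
    before the sign comparison (they neither count as a crossing themselves
    nor suppress one); the default dead band of 0 drops only exact zeros.
    """
    xy = traj.positions()
    labels = assign_roi_array(xy, geom)
    in_parent = labels == RoiLabel.PARENT
    if not in_parent.any():
        raise NotApplicableError(f"trajectory {traj.rbc_id!r} has no frames in the parent ROI")
    y_star = xy[in_parent, 1] / geom.width
    y_star = y_star[np.abs(y_star) > dead_band]
    if len(y_star) < 2:
        return False
    signs = np.sign(y_star)
    return bool(np.any(signs[1:] != signs[:-1]))
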