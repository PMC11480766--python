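"""Per-cell lingering metrics and classification under four criteria.

A lingering red blood cell (LRBC) pauses at the apex of a diverging
bifurcation instead of transiting directly into a daughter branch.  Four
criteria are implemented and compared:

``tau``
    Relative residence time: the time a cell spends inside the intersection
    region, normalised by a convective reference time t_ref = L / u_out0,
    where L is the path length from the parent-ROI exit to the apex and on to
    a daughter-ROI entry, and u_out0 is the mean cell speed at the parent
    outlet.  A cell lingers iff tau > threshold (default 2.0, strict).
``min_velocity``
    Minimum speed inside the intersection below a threshold, usually the
    local minimum of the velocity density over all intersection samples.
``min_distance``
    Minimum apex distance below a threshold (default the cell radius,
    3.05 um).
``rashidi``
    Conjunction of the two: close to the apex AND slow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from scipy.signal import argrelextrema

from .geometry import (
    BifurcationGeometry,
    NotApplicableError,
    RoiLabel,
    apex_distance,
    assign_roi_array,
)
from .tracks import ExperimentTable, Trajectory

logger = logging.getLogger("lingerlab")

LRBC = "LRBC"
NLRBC = "NLRBC"

#: Default classification thresholds; values match the reference experiment.
DEFAULT_TAU_THRESHOLD = 2.0
DEFAULT_R_RBC = 3.05  # um, rabbit RBC radius
SENSITIVITY_TAU_THRESHOLDS = (1.7, 2.0, 2.3)

CRITERIA = ("tau", "min_velocity", "min_distance", "rashidi")


class DegenerateDataError(ValueError):
    pass


class NoThresholdError(ValueError):
    """The velocity density has no interior local minimum between two modes."""


@dataclass(frozen=True)
class ReferenceScale:
    """Convective reference scale for the relative residence time."""

    L: float  # um
    u_out0: float  # mm/s
    t_ref: float  # s

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.u_out0 > 0 and self.t_ref > 0):
            raise DegenerateDataError("reference scale requires positive L, u_out0, t_ref")


@dataclass
class ClassificationRecord:
    """Lingering metrics for one cell, plus labels per criterion."""

    rbc_id: str
    ds_min: float  # um, min apex distance over intersection frames
    u_min: float  # mm/s, min speed over intersection frames
    t_r: float  # s, intersection residence time
    tau: float  # t_r / t_ref
    entry_frame: int  # first frame inside the intersection
    exit_frame: int  # last frame inside the intersection
    labels: dict[str, str] = field(default_factory=dict)

    def label(self, criterion: str) -> str:
        return self.labels[criterion]


def reference_length(geom: BifurcationGeometry) -> float:
    """L: parent-ROI exit -> apex -> daughter-ROI entry along straight segments (um).

    Measured along channel axes; the symmetric geometry makes either daughter
    equivalent.
    """
    parent_exit = np.array([geom.roi_axial_range(RoiLabel.PARENT)[1], 0.0])
    d_lo = geom.roi_axial_range(RoiLabel.DAUGHTER1)[0]
    daughter_entry = d_lo * geom.daughter1_axis
    return float(
        np.linalg.norm(geom.apex - parent_exit) + np.linalg.norm(daughter_entry - geom.apex)
    )


def reference_time(table: ExperimentTable, geom: BifurcationGeometry) -> ReferenceScale:
    """Reference scale t_ref = L / u_out0 from the tracked population.

    u_out0 is the mean over cells of each cell's speed at its last frame
    inside the parent ROI (one sample per cell, equal weights).
    """
    L = reference_length(geom)
    outlet_speeds = []
    for traj in table:
        labels = assign_roi_array(traj.positions(), geom)
        idx = np.flatnonzero(labels == RoiLabel.PARENT)
        if len(idx):
            outlet_speeds.append(traj.u[idx[-1]])
    if not outlet_speeds:
        raise DegenerateDataError("no cell has frames in the parent ROI")
    u_out0 = float(np.mean(outlet_speeds))
    if u_out0 <= 0:
        raise DegenerateDataError("mean parent-outlet speed is zero")
    # L um / (u mm/s) = L um / (1e3 u um/s)
    return ReferenceScale(L=L, u_out0=u_out0, t_ref=L / (u_out0 * 1e3))


def intersection_residence_time(
    traj: Trajectory, geom: BifurcationGeometry, fps: float
) -> float:
    """Residence time t_r (s): intersection frame count / fps (re-entries included)."""
    labels = assign_roi_array(traj.positions(), geom)
    n = int(np.sum(labels == RoiLabel.INTERSECTION))
    if n == 0:
        raise NotApplicableError(f"cell {traj.rbc_id!r} never enters the intersection")
    return n / fps


def compute_records(
    table: ExperimentTable,
    geom: BifurcationGeometry,
    scale: ReferenceScale | None = None,
) -> list[ClassificationRecord]:
    """Per-cell metrics (ds_min, u_min, t_r, tau) for every cell that enters I.

    Cells that never enter the intersection (e.g. tracking gaps) are excluded
    and logged.
    """
    if scale is None:
        scale = reference_time(table, geom)
    records = []
    excluded = []
    for traj in table:
        xy = traj.positions()
        labels = assign_roi_array(xy, geom)
        idx = np.flatnonzero(labels == RoiLabel.INTERSECTION)
        if len(idx) == 0:
            excluded.append(traj.rbc_id)
            continue
        ds = np.array([apex_distance(p, geom) for p in xy[idx]])
        t_r = len(idx) / table.fps
        records.append(
            ClassificationRecord(
                rbc_id=traj.rbc_id,
                ds_min=float(ds.min()),
                u_min=float(traj.u[idx].min()),
                t_r=t_r,
                tau=t_r / scale.t_ref,
                entry_frame=int(traj.frame[idx[0]]),
                exit_frame=int(traj.frame[idx[-1]]),
            )
        )
    if excluded:
        logger.info(
            "%d cell(s) excluded from lingering analysis (never entered the intersection)",
            len(excluded),
        )
        logger.debug("excluded cells: %s", ", ".join(excluded))
    return records


def intersection_speed_samples(table: ExperimentTable, geom: BifurcationGeometry) -> np.ndarray:
    """All per-frame speeds (mm/s) recorded inside the intersection region."""
    samples = []
    for traj in table:
        labels = assign_roi_array(traj.positions(), geom)
        samples.append(traj.u[labels == RoiLabel.INTERSECTION])
    return np.concatenate(samples) if samples else np.array([])


def velocity_pdf_threshold(
    u_samples: np.ndarray, *, bandwidth: str | float = "silverman", grid_size: int = 512
) -> float:
    """Velocity threshold: the density valley between the two dominant speed modes.

    A Gaussian kernel density (Silverman bandwidth by default) is evaluated on
    a ``grid_size``-point grid over [0, max(u)]; the estimate returns the
    lowest-velocity local minimum lying strictly between the two largest
    modes.  Deterministic given the samples and the bandwidth rule.

    Raises
    ------
    NoThresholdError
        If the density has fewer than two modes (no interior valley).
    """
    u = np.asarray(u_samples, dtype=float)
    if len(u) < 50:
        raise ValueError(f"need >= 50 speed samples, got {len(u)}")
    kde = _stats.gaussian_kde(u, bw_method=bandwidth)
    grid = np.linspace(0.0, float(u.max()), grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        raise NoThresholdError("velocity density is unimodal; supply a threshold explicitly")
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    minima = argrelextrema(dens, np.less)[0]
    between = minima[(minima > lo) & (minima < hi)]
    if len(between) == 0:
        raise NoThresholdError("no density valley between the two dominant modes")
    return float(grid[between.min()])


def classify(
    records: list[ClassificationRecord],
    criterion: str,
    *,
    tau_threshold: float = DEFAULT_TAU_THRESHOLD,
    r_rbc: float = DEFAULT_R_RBC,
    u_threshold: float | None = None,
    d_threshold: float | None = None,
) -> list[ClassificationRecord]:
    """Label records LRBC/NLRBC under one criterion (labels stored in-place).

    tau: LRBC iff tau > tau_threshold (strict; ties are NLRBC).
    min_velocity: LRBC iff u_min < u_threshold.
    min_distance: LRBC iff ds_min < d_threshold (default r_rbc).
    rashidi: LRBC iff ds_min < r_rbc AND u_min < u_threshold.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    if criterion in ("min_velocity", "rashidi") and u_threshold is None:
        raise ValueError(f"criterion {criterion!r} requires u_threshold")
    if d_threshold is None:
        d_threshold = r_rbc
    for rec in records:
        for name, value in (("ds_min", rec.ds_min), ("u_min", rec.u_min), ("tau", rec.tau)):
            if value is None or not np.isfinite(value):
                raise ValueError(f"cell {rec.rbc_id!r}: metric {name} missing or non-finite")
        if criterion == "tau":
            is_l = rec.tau > tau_threshold
        elif criterion == "min_velocity":
            is_l = rec.u_min < u_threshold
        elif criterion == "min_distance":
            is_l = rec.ds_min < d_threshold
        else:  # rashidi
            is_l = (rec.ds_min < r_rbc) and (rec.u_min < u_threshold)
        rec.labels[criterion] = LRBC if is_l else NLRBC
    return records


def lingering_frequency(records: list[ClassificationRecord], criterion: str = "tau") -> float:
    """Fraction of analysed cells labelled LRBC under one criterion."""
    if not records:
        raise ValueError("no classification records")
    labels = [rec.labels[criterion] for rec in records]
    return labels.count(LRBC) / len(labels)


def threshold_sensitivity(
    records: list[ClassificationRecord],
    thresholds=SENSITIVITY_TAU_THRESHOLDS,
) -> dict[float, float]:
    """Lingering frequency as a function of the tau cutoff (non-increasing)."""
    out = {}
    n = len(records)
    if n == 0:
        raise ValueError("no classification records")
    taus = np.array([rec.tau for rec in records])
    for thr in thresholds:
        if not thr > 0:
            raise ValueError(f"tau threshold must be positive, got {thr}")
        out[float(thr)] = float(np.sum(taus > thr) / n)
    return out
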