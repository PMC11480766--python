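"""Synthetic RBC track generator with ground-truth lingering labels.

Generates per-frame track tables with the statistical structure the analysis
assumes, so every downstream stage (classification, fluxes, lateral
distributions, mixture fitting) is testable without microscopy video.

The kinematics are phenomenological, not fluid-dynamic: each cell follows a
piecewise-linear path through the parent ROI, the intersection, and one
daughter ROI, sampled at the acquisition frame rate.  Lingerers enter near
the parent centerline, decelerate on approach to the apex, hold position
within a cell radius of the apex for a dwell time drawn uniformly from the
configured range, then exit hugging the distal wall of a daughter at reduced
speed.  Non-lingerers enter with a bimodal (off-center) lateral distribution
and transit the intersection at cruise speed; those entering near the
centerline are routed close around the apex, producing the "grazing"
non-lingerers that defeat a pure minimum-distance classification.  Defaults
emulate the reference experiment: 378 cells at 395 frames/s, mean speed
0.67 mm/s, dwell times 45-238 ms, lingering fraction 0.11, symmetric branch
choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BifurcationGeometry, make_default_geometry
from .tracks import ExperimentTable, Trajectory


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ParentLateralModel:
    """Two-component lateral-entry mixture in the parent vessel (y* units).

    Lingerers enter near the centerline (normal, ``center_sd``); non-lingerers
    enter off-center on either side (folded normal at ``bimodal_mean`` with
    ``bimodal_sd``), leaving a cell-depleted layer at the walls
    (``wall_margin``).  Defaults put ~95% of lingerers and ~52% of
    non-lingerers inside the central band |y*| < 1/8.
    """

    center_sd: float = 0.0625
    center_min: float = 0.04  # keep lingerers off the exact axis so jitter cannot flip signs
    bimodal_mean: float = 0.12
    bimodal_sd: float = 0.08
    bimodal_min: float = 0.03
    wall_margin: float = 0.08  # cell-depleted layer next to each wall


@dataclass(frozen=True)
class DaughterMargination:
    """Lateral exit distributions in the daughter vessels (y* units).

    Calibrated to the daughter-outlet profiles, where the composite-mixture
    analysis is defined: lingerers press against the distal wall (skewness
    index 0.50, essentially all mass in the distal band), non-lingerers are
    moderately distal-shifted (skewness index ~0.30, ~45% of cells in the
    distal band y* > 1/8).
    """

    lingerer_mean: float = 0.42
    lingerer_sd: float = 0.04
    nonlingerer_mean: float = 0.11
    nonlingerer_sd: float = 0.13


@dataclass(frozen=True)
class SyntheticConfig:
    geometry: BifurcationGeometry = field(default_factory=make_default_geometry)
    n_rbc: int = 378
    gamma_true: float = 0.11
    fps: float = 395.0
    n_frames: int = 4000
    u_mean: float = 0.67  # mm/s
    u_cv: float = 0.10  # per-cell cruise-speed coefficient of variation
    dwell_range: tuple[float, float] = (45.0, 238.0)  # ms
    hold_speed: float = 0.03  # mm/s apparent speed while pinned at the apex
    daughter_speed_factor: float = 0.5  # flow split: daughter speed / parent cruise speed
    exit_speed_factor: float = 0.35  # lingerer daughter-branch speed / cruise speed
    decel_zone: float = 6.0  # um over which a lingerer ramps down approaching the apex
    accel_zone: float = 4.0  # um over which a lingerer ramps back up after release
    graze_band: float = 0.07  # |y*| below which a non-lingerer is routed around the apex
    graze_distance: float = 2.0  # um closest approach of grazing non-lingerers to the apex
    parent_lateral_model: ParentLateralModel = field(default_factory=ParentLateralModel)
    daughter_margination: DaughterMargination = field(default_factory=DaughterMargination)
    noise_sd: float = 0.10  # um positional jitter
    speed_noise_cv: float = 0.03  # multiplicative per-frame speed noise
    sa_cross_prob_nl: float = 0.012
    sa_cross_prob_l: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_true <= 1.0:
            raise SyntheticConfigError(f"gamma_true must be in [0, 1], got {self.gamma_true}")
        if not self.dwell_range[0] < self.dwell_range[1]:
            raise SyntheticConfigError(f"dwell_range min must be < max, got {self.dwell_range}")
        if not self.u_mean > 0:
            raise SyntheticConfigError("u_mean must be positive")
        if not self.fps > 0:
            raise SyntheticConfigError("fps must be positive")
        if self.dwell_range[0] < 1000.0 / self.fps:
            import warnings

            warnings.warn(
                "minimum dwell time is shorter than one frame at the configured fps",
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruthRecord:
    rbc_id: str
    is_lingerer: bool
    branch: str  # "daughter1" | "daughter2"
    dwell_ms: float  # 0 for non-lingerers
    entry_y_star: float
    exit_y_star: float
    crossed_sa: bool


@dataclass
class GroundTruth:
    records: dict[str, GroundTruthRecord]

    def __getitem__(self, rbc_id: str) -> GroundTruthRecord:
        return self.records[rbc_id]

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def lingering_fraction(self) -> float:
        return sum(r.is_lingerer for r in self) / len(self)


# ---------------------------------------------------------------------------
# sampling helpers


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled normal restricted to [lo, hi] (bounds well inside ~4 sd)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi))) if size else float(np.clip(mean, lo, hi))
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out if size is not None else float(out[0])


def _sample_parent_entry(rng, cfg: SyntheticConfig, is_lingerer: bool) -> float:
    m = cfg.parent_lateral_model
    hi = 0.5 - m.wall_margin
    if is_lingerer:
        mag = abs(_truncated_normal(rng, 0.0, m.center_sd, -hi, hi))
        mag = max(mag, m.center_min)
        return float(np.sign(rng.random() - 0.5) or 1.0) * mag
    mag = abs(_truncated_normal(rng, m.bimodal_mean, m.bimodal_sd, -hi, hi))
    mag = float(np.clip(mag, m.bimodal_min, hi))
    return float(np.sign(rng.random() - 0.5) or 1.0) * mag


def _sample_daughter_exit(rng, cfg: SyntheticConfig, is_lingerer: bool) -> float:
    m = cfg.daughter_margination
    if is_lingerer:
        return _truncated_normal(rng, m.lingerer_mean, m.lingerer_sd, -0.5, 0.5)
    return _truncated_normal(rng, m.nonlingerer_mean, m.nonlingerer_sd, -0.5, 0.5)


def sample_ldf_pair(cfg: SyntheticConfig, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw lingerer / non-lingerer daughter-vessel lateral positions directly.

    Both sample sets lie in [-0.5, 0.5]; lingerer samples concentrate against
    the distal wall, non-lingerer samples are broader.  Deterministic given
    the config seed.
    """
    if n_samples < 1:
        raise SyntheticConfigError("n_samples must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.daughter_margination
    ling = _truncated_normal(rng, m.lingerer_mean, m.lingerer_sd, -0.5, 0.5, size=n_samples)
    non = _truncated_normal(rng, m.nonlingerer_mean, m.nonlingerer_sd, -0.5, 0.5, size=n_samples)
    return np.asarray(ling), np.asarray(non)


# ---------------------------------------------------------------------------
# kinematic path construction


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(points) - 2)
    seg_len = cum[i + 1] - cum[i]
    f = 0.0 if seg_len == 0 else (s - cum[i]) / seg_len
    return points[i] + f * (points[i + 1] - points[i])


def _daughter_point(geom: BifurcationGeometry, branch: str, axial: float, y_star: float) -> np.ndarray:
    from .geometry import RoiLabel

    roi = RoiLabel.DAUGHTER1 if branch == "daughter1" else RoiLabel.DAUGHTER2
    d = geom.channel_axis(roi)
    n = np.array([-d[1], d[0]])
    # invert the daughter sign conventions of geometry.lateral_coordinate
    c = -y_star * geom.width if branch == "daughter1" else +y_star * geom.width
    return axial * d + c * n


def _simulate_cell(rng, cfg: SyntheticConfig, rbc_id: str):
    """Build one cell's per-frame samples; returns (Trajectory minus offset, GroundTruthRecord)."""
    geom = cfg.geometry
    is_lingerer = rng.random() < cfg.gamma_true
    branch = "daughter1" if rng.random() < 0.5 else "daughter2"
    cruise = max(0.15 * cfg.u_mean, rng.normal(cfg.u_mean, cfg.u_cv * cfg.u_mean))

    entry = _sample_parent_entry(rng, cfg, is_lingerer)
    exit_y = _sample_daughter_exit(rng, cfg, is_lingerer)
    cross_p = cfg.sa_cross_prob_l if is_lingerer else cfg.sa_cross_prob_nl
    crosses = rng.random() < cross_p
    # lateral position at the parent-ROI outlet: crossing cells drift to the
    # opposite side, others hold their entry side
    if crosses:
        out_lat = -math.copysign(max(abs(entry), 0.08), entry)
    else:
        out_lat = entry

    from .geometry import RoiLabel

    par_lo, par_hi = geom.roi_axial_range(RoiLabel.PARENT)
    d_lo, d_hi = geom.roi_axial_range(RoiLabel.DAUGHTER1)

    W = geom.width
    a_start = par_lo - 2.0  # start slightly upstream of the parent ROI
    p_in = np.array([a_start, entry * W])
    p_mid = np.array([(par_lo + par_hi) / 2.0, entry * W])
    p_out = np.array([par_hi, out_lat * W])
    d_entry = _daughter_point(geom, branch, d_lo, exit_y)
    d_exit = _daughter_point(geom, branch, d_hi + 2.0, exit_y)

    if is_lingerer:
        dwell_ms = rng.uniform(*cfg.dwell_range)
        # pinned just off the apex on the parent side, biased toward the branch taken
        side = 1.0 if branch == "daughter1" else -1.0
        hold = geom.apex + np.array([-1.2, side * 0.8])
        path = np.array([p_in, p_mid, p_out, hold, d_entry, d_exit])
    else:
        dwell_ms = 0.0
        if abs(out_lat) < cfg.graze_band:
            # near-axis cells sweep close around the apex without slowing
            side = 1.0 if branch == "daughter1" else -1.0
            graze = geom.apex + np.array(
                [-cfg.graze_distance * 0.4, side * cfg.graze_distance]
            )
            path = np.array([p_in, p_mid, p_out, graze, d_entry, d_exit])
        else:
            path = np.array([p_in, p_mid, p_out, d_entry, d_exit])

    cum = _polyline_arclength(path)
    total = cum[-1]
    s_branch = float(cum[-2])  # arc position of the daughter-ROI entry waypoint
    branch_speed = cfg.daughter_speed_factor * cruise  # flow halves at the split
    dt = 1.0 / cfg.fps
    # speed profile along arc length (um coordinates, speeds mm/s -> um/s x1e3)
    if is_lingerer:
        s_hold = float(cum[3])  # arc position of the hold point
        hold_frames = max(1, int(round(dwell_ms * 1e-3 * cfg.fps)))
    else:
        s_hold = None
        hold_frames = 0

    positions = []
    speeds = []
    s = 0.0
    held = 0
    released = False
    max_steps = int(cfg.fps * 20)  # safety: no cell takes more than 20 s
    for _ in range(max_steps):
        positions.append(_point_at(path, cum, s))
        if s_hold is not None and not released:
            dist_to_hold = s_hold - s
            if dist_to_hold <= 1e-9:
                if held < hold_frames:
                    speed = cfg.hold_speed
                    held += 1
                    speeds.append(speed)
                    # creep forward imperceptibly while pinned
                    s += cfg.hold_speed * 1e3 * dt * 0.2
                    continue
                released = True
                speed = cfg.hold_speed
            elif dist_to_hold < cfg.decel_zone:
                frac = dist_to_hold / cfg.decel_zone
                speed = cfg.hold_speed + (cruise - cfg.hold_speed) * frac
            else:
                speed = cruise
        elif s_hold is not None and released:
            target = cfg.exit_speed_factor * cruise
            dist_from_hold = s - s_hold
            if dist_from_hold < cfg.accel_zone:
                frac = dist_from_hold / cfg.accel_zone
                speed = cfg.hold_speed + (target - cfg.hold_speed) * frac
            else:
                speed = target
        elif s > s_branch:
            # past the flow divider the flow (and the cell) slows to the branch speed
            frac = min(1.0, (s - s_branch) / cfg.accel_zone)
            speed = cruise + (branch_speed - cruise) * frac
        else:
            speed = cruise
        speeds.append(speed)
        s += speed * 1e3 * dt
        if s >= total:
            break
    positions = np.asarray(positions)
    speeds = np.asarray(speeds)

    # measurement noise
    positions = positions + rng.normal(0.0, cfg.noise_sd, size=positions.shape)
    speeds = speeds * np.exp(rng.normal(0.0, cfg.speed_noise_cv, size=len(speeds)))

    # circularity: discocyte ~0.92 in the parent; lingerers fold at the apex
    # (deep drop) and relax logistically along the daughter; non-lingerers
    # elongate mildly in the intersection
    n = len(positions)
    circ = np.full(n, 0.92) + rng.normal(0.0, 0.015, size=n)
    axial = positions @ np.array([1.0, 0.0])
    in_branch = _polyline_arclength(positions)  # monotone-ish proxy for progress
    if is_lingerer:
        s_arr = np.minimum(np.maximum(in_branch, 0.0), total)
        rel = (s_arr - s_hold) / 15.0
        folded = 0.45 + 0.40 / (1.0 + np.exp(-2.5 * (rel - 1.0)))
        near = np.abs(s_arr - s_hold) < (cfg.decel_zone + 2.0)
        circ = np.where(s_arr >= s_hold - cfg.decel_zone, folded, circ)
        circ[near & (s_arr <= s_hold)] = 0.45
        circ = circ + rng.normal(0.0, 0.01, size=n)
    else:
        mid = (axial > par_hi - 2) & (axial < d_lo + 8)
        circ[mid] -= 0.06
    circ = np.clip(circ, 0.05, 1.0)

    # orientation: direction of motion folded to [-90, 90)
    vel = np.gradient(positions, axis=0)
    angles = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    angles = ((angles + 90.0) % 180.0) - 90.0
    angles = angles + rng.normal(0.0, 4.0, size=n)
    angles = ((angles + 90.0) % 180.0) - 90.0

    truth = GroundTruthRecord(
        rbc_id=rbc_id,
        is_lingerer=bool(is_lingerer),
        branch=branch,
        dwell_ms=float(dwell_ms),
        entry_y_star=float(entry),
        exit_y_star=float(exit_y),
        crossed_sa=bool(crosses),
    )
    return positions, speeds, circ, angles, truth


def generate_experiment(cfg: SyntheticConfig) -> tuple[ExperimentTable, GroundTruth]:
    """Generate a full synthetic acquisition with ground-truth labels.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    tables.  Each cell receives a random start frame so that lingering events
    of different cells can overlap in time (needed for the concurrent-
    lingering grouping downstream).
    """
    if cfg.n_rbc <= 0:
        raise SyntheticConfigError("n_rbc must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_rbc))
    trajectories = []
    truth_records: dict[str, GroundTruthRecord] = {}
    for i in range(cfg.n_rbc):
        rbc_id = f"rbc{i:0{width}d}"
        positions, speeds, circ, angles, truth = _simulate_cell(rng, cfg, rbc_id)
        n = len(positions)
        max_offset = max(0, cfg.n_frames - n - 1)
        offset = int(rng.integers(0, max_offset + 1))
        frames = offset + np.arange(n)
        trajectories.append(
            Trajectory(
                rbc_id=rbc_id,
                frame=frames,
                x=positions[:, 0],
                y=positions[:, 1],
                u=speeds,
                circularity=circ,
                orientation=angles,
            )
        )
        truth_records[rbc_id] = truth
    table = ExperimentTable(
        trajectories=trajectories,
        fps=cfg.fps,
        n_frames=cfg.n_frames,
        provenance=f"lingerlab synthetic (seed={cfg.seed}, gamma_true={cfg.gamma_true})",
    )
    return table, GroundTruth(records=truth_records)


def write_ground_truth(truth: GroundTruth, path) -> None:
    import pandas as pd

    rows = [
        {
            "rbc_id": r.rbc_id,
            "is_lingerer": int(r.is_lingerer),
            "branch": r.branch,
            "dwell_ms": r.dwell_ms,
            "entry_y_star": r.entry_y_star,
            "exit_y_star": r.exit_y_star,
            "crossed_sa": int(r.crossed_sa),
        }
        for r in truth
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_ground_truth(path) -> GroundTruth:
    import pandas as pd

    df = pd.read_csv(path)
    records = {
        str(row.rbc_id): GroundTruthRecord(
            rbc_id=str(row.rbc_id),
            is_lingerer=bool(row.is_lingerer),
            branch=str(row.branch),
            dwell_ms=float(row.dwell_ms),
            entry_y_star=float(row.entry_y_star),
            exit_y_star=float(row.exit_y_star),
            crossed_sa=bool(row.crossed_sa),
        )
        for row in df.itertuples()
    }
    return GroundTruth(records=records)
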