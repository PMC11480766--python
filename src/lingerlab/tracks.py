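"""Reading, validating, and writing per-frame RBC track tables and reports.

The interchange format is a comma-separated UTF-8 table with one row per cell
per frame and header columns ``rbc_id, frame, x_um, y_um, u_mm_s`` plus the
optional shape columns ``circularity`` and ``orientation_deg``.  Positions are
in micrometres, speeds in mm/s, orientations in degrees in [-90, 90).  Time is
derived as frame / fps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REPORT_SCHEMA_VERSION = "1.0"

MANDATORY_COLUMNS = ("rbc_id", "frame", "x_um", "y_um", "u_mm_s")
OPTIONAL_COLUMNS = ("circularity", "orientation_deg")

DEFAULT_FPS = 395.0
DEFAULT_N_FRAMES = 4000


class TrackFormatError(ValueError):
    """The track file does not conform to the interchange format."""


class TrackValidationError(ValueError):
    """The track table violates a per-trajectory invariant."""


@dataclass
class Trajectory:
    """Ordered per-frame track of a single red blood cell."""

    rbc_id: str
    frame: np.ndarray  # int, strictly increasing
    x: np.ndarray  # um
    y: np.ndarray  # um
    u: np.ndarray  # mm/s
    circularity: np.ndarray | None = None
    orientation: np.ndarray | None = None  # degrees

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        for name in ("x", "y", "u"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.frame) < 2:
            raise TrackValidationError(f"cell {self.rbc_id!r}: a trajectory needs >= 2 points")
        if np.any(np.diff(self.frame) <= 0):
            raise TrackValidationError(
                f"cell {self.rbc_id!r}: frame indices must be strictly increasing"
            )
        if np.any(self.u < 0):
            raise TrackValidationError(f"cell {self.rbc_id!r}: negative speed")

    def __len__(self) -> int:
        return len(self.frame)

    def positions(self) -> np.ndarray:
        """(n, 2) centroid array in um."""
        return np.column_stack([self.x, self.y])

    def times(self, fps: float) -> np.ndarray:
        return self.frame / fps


@dataclass
class ExperimentTable:
    """A set of tracked cells from one acquisition."""

    trajectories: list[Trajectory]
    fps: float = DEFAULT_FPS
    n_frames: int = DEFAULT_N_FRAMES
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise TrackValidationError(f"fps must be positive, got {self.fps}")
        for traj in self.trajectories:
            if traj.frame[-1] >= self.n_frames:
                raise TrackValidationError(
                    f"cell {traj.rbc_id!r}: max frame {traj.frame[-1]} >= n_frames {self.n_frames}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


def read_tracks(path, fps: float = DEFAULT_FPS, n_frames: int | None = None) -> ExperimentTable:
    """Read and validate a delimited track table.

    Rows are grouped by ``rbc_id`` and sorted by ``frame``.  Missing optional
    columns yield trajectories without shape fields.  ``n_frames`` defaults to
    one past the largest frame index seen (or 4000 if larger).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if df.duplicated(subset=["rbc_id", "frame"]).any():
        bad = df[df.duplicated(subset=["rbc_id", "frame"])].iloc[0]
        raise TrackValidationError(
            f"cell {bad['rbc_id']!r}: duplicate frame {int(bad['frame'])}"
        )
    has_circ = "circularity" in df.columns
    has_orient = "orientation_deg" in df.columns
    trajectories = []
    for rbc_id, grp in df.groupby("rbc_id", sort=True):
        grp = grp.sort_values("frame")
        trajectories.append(
            Trajectory(
                rbc_id=str(rbc_id),
                frame=grp["frame"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                u=grp["u_mm_s"].to_numpy(),
                circularity=grp["circularity"].to_numpy() if has_circ else None,
                orientation=grp["orientation_deg"].to_numpy() if has_orient else None,
            )
        )
    if n_frames is None:
        max_frame = max((int(t.frame[-1]) for t in trajectories), default=-1)
        n_frames = max(DEFAULT_N_FRAMES, max_frame + 1)
    return ExperimentTable(trajectories=trajectories, fps=fps, n_frames=n_frames)


def write_tracks(table: ExperimentTable, path) -> None:
    """Write a track table; inverse of :func:`read_tracks` at >= 9 significant digits."""
    frames = []
    any_circ = any(t.circularity is not None for t in table)
    any_orient = any(t.orientation is not None for t in table)
    for t in table:
        rec = {
            "rbc_id": t.rbc_id,
            "frame": t.frame,
            "x_um": t.x,
            "y_um": t.y,
            "u_mm_s": t.u,
        }
        if any_circ:
            rec["circularity"] = t.circularity if t.circularity is not None else np.nan
        if any_orient:
            rec["orientation_deg"] = t.orientation if t.orientation is not None else np.nan
        frames.append(pd.DataFrame(rec))
    cols = list(MANDATORY_COLUMNS) + [
        c for c, keep in zip(OPTIONAL_COLUMNS, (any_circ, any_orient)) if keep
    ]
    if frames:
        df = pd.concat(frames, ignore_index=True)[cols]
    else:
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def compute_speeds(x: np.ndarray, y: np.ndarray, fps: float) -> np.ndarray:
    """Speeds (mm/s) from centroid displacements when the tracker supplies none.

    Central differences in the interior, one-sided at the ends; positions in
    um and fps in frames/s, so the um/s result is scaled by 1e-3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.gradient(x)
    dy = np.gradient(y)
    return np.hypot(dx, dy) * fps * 1e-3


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, tuple)):
            return list(o)
        if hasattr(o, "value") and isinstance(o, object) and o.__class__.__module__.startswith("lingerlab"):
            return getattr(o, "value")
        return super().default(o)


def write_report(results: dict, path) -> None:
    """Serialize pipeline outputs to strict JSON with a schema version field."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION}
    doc.update(results)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, allow_nan=False, cls=_ReportEncoder)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
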