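"""End-to-end orchestration: simulate/load -> classify -> fluxes -> LDFs -> report.

A single :class:`RunConfig` drives the whole analysis.  In ``simulate`` mode
tracks come from the synthetic generator (with ground truth recorded in the
report); in ``analyze`` mode they are read from a track table on disk.  The
report is a JSON document containing classification records and lingering
frequencies per criterion, the tau-threshold sensitivity table, the per-ROI
flux summary with partitioning fractions, lateral distributions and skewness
indices split by lingering label, optional composite-LDF fits against a
target profile, separation-axis crossing percentages per cell group, and the
two-sample test results.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from . import __version__
from .classification import (
    CRITERIA,
    DEFAULT_R_RBC,
    DEFAULT_TAU_THRESHOLD,
    LRBC,
    NLRBC,
    SENSITIVITY_TAU_THRESHOLDS,
    ClassificationRecord,
    NoThresholdError,
    classify,
    compute_records,
    intersection_speed_samples,
    lingering_frequency,
    reference_time,
    threshold_sensitivity,
    velocity_pdf_threshold,
)
from .distribution import build_ldf, fit_gamma, ks_two_sample, mann_whitney
from .geometry import (
    BifurcationGeometry,
    NotApplicableError,
    RoiLabel,
    assign_roi_array,
    crossed_separation_axis,
    make_default_geometry,
)
from .hemodynamics import PhysicalConstants, flux_summary
from .synthetic import SyntheticConfig, generate_experiment
from .tracks import ExperimentTable, read_tracks, write_report

logger = logging.getLogger("lingerlab")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"  # "simulate" | "analyze"
    tracks_path: str | None = None  # analyze mode input
    output_path: str | None = None  # report JSON; None = do not write
    geometry_overrides: dict = field(default_factory=dict)
    synthetic: SyntheticConfig | None = None  # simulate mode; None = defaults
    criterion: str = "tau"
    tau_threshold: float = DEFAULT_TAU_THRESHOLD
    r_rbc: float = DEFAULT_R_RBC
    u_threshold: float | None = None  # None = estimate from the velocity PDF
    sensitivity_thresholds: tuple = SENSITIVITY_TAU_THRESHOLDS
    n_bins: int = 24
    fit_target: list | None = None  # per-bin mass of a target LDF, same grid
    fps: float = 395.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if self.mode == "analyze" and not self.tracks_path:
            raise ConfigError("analyze mode requires tracks_path")
        if self.criterion not in CRITERIA:
            raise ConfigError(f"unknown criterion {self.criterion!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("synthetic"), dict):
            syn = dict(data["synthetic"])
            geo = syn.pop("geometry", None)
            kwargs = {}
            if geo is not None:
                kwargs["geometry"] = make_default_geometry(geo)
            data["synthetic"] = SyntheticConfig(**syn, **kwargs)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def ldf_samples(
    table: ExperimentTable,
    geom: BifurcationGeometry,
    roi: RoiLabel,
    station: str,
) -> dict[str, float]:
    """Per-cell lateral coordinate at a ROI cross-section.

    ``station`` is ``"inlet"`` (first frame of the cell inside the ROI) or
    ``"outlet"`` (last frame); cells that never visit the ROI are omitted.
    Returns {rbc_id: y*}.
    """
    if station not in ("inlet", "outlet"):
        raise ValueError("station must be 'inlet' or 'outlet'")
    out = {}
    for traj in table:
        xy = traj.positions()
        labels = assign_roi_array(xy, geom)
        idx = np.flatnonzero(labels == roi)
        if len(idx) == 0:
            continue
        i = idx[0] if station == "inlet" else idx[-1]
        from .geometry import lateral_coordinate

        try:
            out[traj.rbc_id] = lateral_coordinate(xy[i], geom, roi, tolerance=0.1)
        except Exception:  # noqa: BLE001 - jittered point just outside the wall
            continue
    return out


def concurrent_lingering_split(
    records: list[ClassificationRecord], criterion: str = "tau"
) -> dict[str, str]:
    """Split non-lingerers by whether they entered I during a lingering event.

    An NLRBC counts as "during" iff its first intersection frame falls within
    the closed intersection-occupancy interval [entry, exit] of any LRBC.
    Returns {rbc_id: "during" | "without"} for the NLRBC subset.
    """
    lrbc_windows = [
        (rec.entry_frame, rec.exit_frame)
        for rec in records
        if rec.labels.get(criterion) == LRBC
    ]
    out = {}
    for rec in records:
        if rec.labels.get(criterion) != NLRBC:
            continue
        f = rec.entry_frame
        during = any(lo <= f <= hi for lo, hi in lrbc_windows)
        out[rec.rbc_id] = "during" if during else "without"
    return out


def _sa_crossing_percentages(
    table: ExperimentTable,
    geom: BifurcationGeometry,
    records: list[ClassificationRecord],
    criterion: str,
) -> dict[str, float]:
    """Percentage of cells crossing the parent symmetry axis, per cell group."""
    crossed: dict[str, bool] = {}
    for traj in table:
        try:
            crossed[traj.rbc_id] = crossed_separation_axis(traj, geom)
        except NotApplicableError:
            continue
    label_of = {rec.rbc_id: rec.labels.get(criterion) for rec in records}
    split = concurrent_lingering_split(records, criterion)

    def pct(ids) -> float | None:
        ids = [i for i in ids if i in crossed]
        if not ids:
            return None
        return 100.0 * sum(crossed[i] for i in ids) / len(ids)

    all_ids = list(crossed)
    return {
        "all": pct(all_ids),
        "lrbc": pct([i for i in all_ids if label_of.get(i) == LRBC]),
        "nlrbc": pct([i for i in all_ids if label_of.get(i) == NLRBC]),
        "nlrbc_without_lingering": pct([i for i in all_ids if split.get(i) == "without"]),
        "nlrbc_during_lingering": pct([i for i in all_ids if split.get(i) == "during"]),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return the report document (a dict).

    Deterministic given the config (and seed, in simulate mode).  Stage errors
    propagate annotated with the stage name; already-computed sections are
    kept in the partial report with a failure marker.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    report: dict = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        if cfg.mode == "simulate":
            syn = cfg.synthetic or SyntheticConfig(
                geometry=make_default_geometry(cfg.geometry_overrides), seed=cfg.seed
            )
            geom = syn.geometry
            table, truth = generate_experiment(syn)
            report["ground_truth"] = {
                "gamma_true": syn.gamma_true,
                "lingering_fraction": truth.lingering_fraction(),
                "labels": {r.rbc_id: r.is_lingerer for r in truth},
            }
        else:
            geom = make_default_geometry(cfg.geometry_overrides)
            table = read_tracks(cfg.tracks_path, fps=cfg.fps)
        logger.info("stage %s: %d cells (%.2f s)", stage, len(table), time.perf_counter() - t0)

        stage = "classification"
        t0 = time.perf_counter()
        scale = reference_time(table, geom)
        records = compute_records(table, geom, scale)
        u_thr = cfg.u_threshold
        u_thr_source = "config"
        if u_thr is None:
            try:
                u_thr = velocity_pdf_threshold(intersection_speed_samples(table, geom))
                u_thr_source = "velocity_pdf"
            except (NoThresholdError, ValueError) as exc:
                logger.info("velocity-PDF threshold unavailable (%s)", exc)
                u_thr = None
        frequencies = {}
        for crit in CRITERIA:
            if crit in ("min_velocity", "rashidi") and u_thr is None:
                continue
            classify(
                records,
                crit,
                tau_threshold=cfg.tau_threshold,
                r_rbc=cfg.r_rbc,
                u_threshold=u_thr,
            )
            frequencies[crit] = lingering_frequency(records, crit)
        report["reference_scale"] = {"L_um": scale.L, "u_out0_mm_s": scale.u_out0, "t_ref_s": scale.t_ref}
        report["classification"] = {
            "criterion": cfg.criterion,
            "tau_threshold": cfg.tau_threshold,
            "u_threshold": u_thr,
            "u_threshold_source": u_thr_source if u_thr is not None else None,
            "r_rbc": cfg.r_rbc,
            "n_analyzed": len(records),
            "n_excluded": len(table) - len(records),
            "lingering_frequency": frequencies,
            "threshold_sensitivity": {
                str(k): v
                for k, v in threshold_sensitivity(records, cfg.sensitivity_thresholds).items()
            },
            "records": [
                {
                    "rbc_id": r.rbc_id,
                    "ds_min_um": r.ds_min,
                    "u_min_mm_s": r.u_min,
                    "t_r_s": r.t_r,
                    "tau": r.tau,
                    "labels": dict(r.labels),
                }
                for r in records
            ],
        }
        logger.info("stage %s done (%.2f s)", stage, time.perf_counter() - t0)

        stage = "fluxes"
        t0 = time.perf_counter()
        fx = flux_summary(table, geom, PhysicalConstants(r_rbc=cfg.r_rbc))
        report["fluxes"] = {
            "u_mean_mm_s": fx.u_mean,
            "tube_hematocrit": fx.ht,
            "q_blood_mm3_s": fx.q_blood,
            "q_rbc_mm3_s": fx.q_rbc,
            "q_blood_hat_mm3_s": fx.q_blood_hat,
            "q_rbc_hat_mm3_s": fx.q_rbc_hat,
            "phi": fx.phi,
            "psi": fx.psi,
            "capillary_number": fx.capillary_number,
        }
        logger.info("stage %s done (%.2f s)", stage, time.perf_counter() - t0)

        stage = "distributions"
        t0 = time.perf_counter()
        label_of = {r.rbc_id: r.labels.get(cfg.criterion) for r in records}
        ldf_section: dict = {}
        daughter_out_by_label = {LRBC: [], NLRBC: []}
        for roi, name in (
            (RoiLabel.PARENT, "parent"),
            (RoiLabel.DAUGHTER1, "daughter1"),
            (RoiLabel.DAUGHTER2, "daughter2"),
        ):
            for station in ("inlet", "outlet"):
                samples = ldf_samples(table, geom, roi, station)
                groups = {"all": list(samples.values())}
                groups[LRBC] = [v for k, v in samples.items() if label_of.get(k) == LRBC]
                groups[NLRBC] = [v for k, v in samples.items() if label_of.get(k) == NLRBC]
                if roi is not RoiLabel.PARENT and station == "outlet":
                    daughter_out_by_label[LRBC].extend(groups[LRBC])
                    daughter_out_by_label[NLRBC].extend(groups[NLRBC])
                for gname, vals in groups.items():
                    if len(vals) < 2:
                        continue
                    ldf = build_ldf(vals, cfg.n_bins)
                    ldf_section[f"{name}_{station}_{gname}"] = {
                        "bin_edges": ldf.bin_edges.tolist(),
                        "mass": ldf.mass.tolist(),
                        "n_samples": ldf.n_samples,
                        "sk": ldf.sk,
                    }
        report["ldf"] = ldf_section

        tests = {}
        par_in = ldf_samples(table, geom, RoiLabel.PARENT, "inlet")
        a = [v for k, v in par_in.items() if label_of.get(k) == LRBC]
        b = [v for k, v in par_in.items() if label_of.get(k) == NLRBC]
        if a and b:
            d, p = ks_two_sample(a, b)
            tests["ks_parent_inlet_lrbc_vs_nlrbc"] = {"D": d, "p": p}
        if daughter_out_by_label[LRBC] and daughter_out_by_label[NLRBC]:
            d, p = ks_two_sample(daughter_out_by_label[LRBC], daughter_out_by_label[NLRBC])
            tests["ks_daughter_outlet_lrbc_vs_nlrbc"] = {"D": d, "p": p}
        report["statistical_tests"] = tests

        if (
            cfg.fit_target is not None
            and daughter_out_by_label[LRBC]
            and daughter_out_by_label[NLRBC]
        ):
            ldf_l = build_ldf(daughter_out_by_label[LRBC], cfg.n_bins)
            ldf_n = build_ldf(daughter_out_by_label[NLRBC], cfg.n_bins)
            from .distribution import LateralDistribution

            target = LateralDistribution(
                bin_edges=ldf_l.bin_edges,
                mass=np.asarray(cfg.fit_target, dtype=float),
                n_samples=0,
            )
            fit = fit_gamma(target, ldf_l, ldf_n)
            report["gamma_fit"] = {
                "gamma_hat": fit.gamma_hat,
                "error": fit.error,
                "fit_interval": list(fit.fit_interval),
            }
        logger.info("stage %s done (%.2f s)", stage, time.perf_counter() - t0)

        stage = "sa_crossing"
        report["sa_crossing_pct"] = _sa_crossing_percentages(table, geom, records, cfg.criterion)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        if cfg.output_path:
            write_report(report, cfg.output_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if cfg.output_path:
        write_report(report, cfg.output_path)
    return report


def _config_echo(cfg: RunConfig) -> dict:
    echo = asdict(cfg)
    syn = echo.get("synthetic")
    if syn is not None:
        # geometry dataclass carries derived arrays; echo only its inputs
        geo = syn.get("geometry", {})
        syn["geometry"] = {
            k: geo[k]
            for k in ("width", "height", "channel_length", "branch_angle", "roi_length", "roi_offset")
            if k in geo
        }
    return _jsonable(echo)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
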