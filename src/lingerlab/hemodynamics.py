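"""Tube hematocrit, blood flow rates, RBC fluxes and partitioning fractions.

Units are fixed throughout: lengths in um, speeds in mm/s, volumes in um^3
and fluxes in mm^3/s; the um^2 -> mm^2 cross-section conversion is the only
one needed and is applied in one place.

The tube hematocrit in a region of interest (ROI) is the frame-averaged
packed cell volume: mean over frames of (cell count x mean corpuscular
volume) / ROI volume.  The empirical Fåhraeus relation of Pries & Secomb
predicts the tube-to-reservoir hematocrit ratio from the hydraulic diameter.
Blood flow rate per ROI is chi x (mean cell speed) x cross-section, the RBC
flux weights it by tube hematocrit, and measured fluxes are corrected to
satisfy mass conservation at the bifurcation by a constrained least-squares
adjustment in relative units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BifurcationGeometry, RoiLabel, assign_roi_array
from .tracks import ExperimentTable

UM2_TO_MM2 = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Suspension and cell constants for the reference (rabbit RBC) experiment."""

    mcv: float = 68.6  # um^3, mean corpuscular volume
    mu: float = 1.96e-3  # Pa s, suspending-medium viscosity
    rho: float = 1090.0  # kg/m^3
    gs: float = 2.5e-6  # N/m, membrane surface elastic shear modulus
    chi: float = 1.0  # plasma/RBC velocity coefficient
    r_rbc: float = 3.05  # um, cell radius

    def __post_init__(self) -> None:
        for name in ("mcv", "mu", "rho", "gs", "r_rbc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")


@dataclass
class FluxSummary:
    """Per-ROI hemodynamic summary; index 0 = parent, 1/2 = daughters."""

    u_mean: dict[int, float]  # mm/s
    ht: dict[int, float]  # fraction
    q_blood: dict[int, float]  # mm^3/s, uncorrected
    q_rbc: dict[int, float]  # mm^3/s, uncorrected
    q_blood_hat: dict[int, float]  # conservation-corrected
    q_rbc_hat: dict[int, float]
    phi: dict[int, float]  # fractional blood flow, daughters
    psi: dict[int, float]  # fractional RBC flux, daughters
    capillary_number: float


def hydraulic_diameter(width: float, height: float) -> float:
    """Hydraulic diameter 2WH/(W+H) of a rectangular duct (um)."""
    if not (width > 0 and height > 0):
        raise ValueError("width and height must be positive")
    return 2.0 * width * height / (width + height)


def pries_secomb_tube_hematocrit(hr: float, dh: float) -> float:
    """Tube hematocrit predicted by the Pries-Secomb empirical relation.

    Ht/Hr = Hr + (1 - Hr) * (1 + 1.7 exp(-0.415 Dh) - 0.6 exp(-0.011 Dh))
    with Dh in um; returns Ht as a fraction.
    """
    if not 0 < hr <= 1:
        raise ValueError("reservoir hematocrit must be in (0, 1]")
    if not dh > 0:
        raise ValueError("hydraulic diameter must be positive")
    ratio = hr + (1.0 - hr) * (1.0 + 1.7 * np.exp(-0.415 * dh) - 0.6 * np.exp(-0.011 * dh))
    return hr * ratio


def roi_tube_hematocrit(counts, consts: PhysicalConstants, v_roi: float) -> float:
    """Frame-averaged tube hematocrit from per-frame cell counts in one ROI."""
    if not v_roi > 0:
        raise ValueError("ROI volume must be positive")
    counts = np.asarray(counts, dtype=float)
    return float(counts.mean() * consts.mcv / v_roi)


def blood_flow_rate(u_mean: float, width: float, height: float, chi: float = 1.0) -> float:
    """Blood flow rate chi * u * W * H (mm^3/s); u in mm/s, W and H in um."""
    return chi * u_mean * width * height * UM2_TO_MM2


def rbc_flux(u_mean: float, ht: float, width: float, height: float) -> float:
    """RBC flux u * Ht * W * H (mm^3/s)."""
    return u_mean * ht * width * height * UM2_TO_MM2


def conserve_fluxes(q0: float, q1: float, q2: float) -> tuple[float, float, float]:
    """Correct measured fluxes to satisfy Q0 = Q1 + Q2 at the bifurcation.

    Minimises the sum of squared relative adjustments
    sum_i ((Qhat_i - Q_i)/Q_i)^2 subject to the conservation constraint; the
    Lagrange solution is closed-form:

        Qhat_0 = Q0 - d Q0^2 / S,   Qhat_i = Q_i + d Q_i^2 / S  (i = 1, 2)

    with d = Q0 - Q1 - Q2 and S = Q0^2 + Q1^2 + Q2^2.  Conserving inputs are
    returned unchanged; symmetric daughters stay symmetric.
    """
    if not (q0 > 0 and q1 > 0 and q2 > 0):
        raise ValueError("all fluxes must be positive")
    d = q0 - q1 - q2
    s = q0 * q0 + q1 * q1 + q2 * q2
    return (q0 - d * q0 * q0 / s, q1 + d * q1 * q1 / s, q2 + d * q2 * q2 / s)


def fractional_flows(
    q_blood_hat: tuple[float, float, float], q_rbc_hat: tuple[float, float, float]
) -> tuple[float, float, float, float]:
    """Fractional blood flows (Phi_1, Phi_2) and RBC fluxes (Psi_1, Psi_2)."""
    qb0, qb1, qb2 = q_blood_hat
    qr0, qr1, qr2 = q_rbc_hat
    if not (qb0 > 0 and qr0 > 0):
        raise ValueError("parent fluxes must be positive")
    return qb1 / qb0, qb2 / qb0, qr1 / qr0, qr2 / qr0


def capillary_number(consts: PhysicalConstants, u_mean: float) -> float:
    """Capillary number mu * u / Gs, with u converted from mm/s to m/s."""
    if u_mean < 0:
        raise ValueError("speed must be >= 0")
    return consts.mu * (u_mean * 1e-3) / consts.gs


# ---------------------------------------------------------------------------
# track-table driven summary

_ROI_INDEX = {RoiLabel.PARENT: 0, RoiLabel.DAUGHTER1: 1, RoiLabel.DAUGHTER2: 2}


def roi_frame_counts(table: ExperimentTable, geom: BifurcationGeometry) -> dict[int, np.ndarray]:
    """Per-frame cell counts for ROIs 0/1/2 over the whole acquisition."""
    counts = {i: np.zeros(table.n_frames) for i in (0, 1, 2)}
    for traj in table:
        labels = assign_roi_array(traj.positions(), geom)
        for roi, i in _ROI_INDEX.items():
            frames = traj.frame[labels == roi]
            counts[i][frames] += 1
    return counts


def roi_mean_speeds(
    table: ExperimentTable,
    geom: BifurcationGeometry,
    exclude_ids: set[str] | None = None,
) -> dict[int, float]:
    """Sample-weighted mean speed (mm/s) per ROI over all per-frame samples.

    ``exclude_ids`` drops whole cells (e.g. lingerers) before averaging.
    """
    samples: dict[int, list] = {0: [], 1: [], 2: []}
    for traj in table:
        if exclude_ids and traj.rbc_id in exclude_ids:
            continue
        labels = assign_roi_array(traj.positions(), geom)
        for roi, i in _ROI_INDEX.items():
            samples[i].append(traj.u[labels == roi])
    return {
        i: float(np.concatenate(v).mean()) if v and len(np.concatenate(v)) else float("nan")
        for i, v in samples.items()
    }


def flux_summary(
    table: ExperimentTable,
    geom: BifurcationGeometry,
    consts: PhysicalConstants | None = None,
) -> FluxSummary:
    """Full per-ROI hemodynamic summary from a track table."""
    consts = consts or PhysicalConstants()
    u_mean = roi_mean_speeds(table, geom)
    counts = roi_frame_counts(table, geom)
    v_roi = geom.roi_volume()
    ht = {i: roi_tube_hematocrit(counts[i], consts, v_roi) for i in (0, 1, 2)}
    q_blood = {
        i: blood_flow_rate(u_mean[i], geom.width, geom.height, consts.chi) for i in (0, 1, 2)
    }
    q_rbc = {i: rbc_flux(u_mean[i], ht[i], geom.width, geom.height) for i in (0, 1, 2)}
    qb_hat = conserve_fluxes(q_blood[0], q_blood[1], q_blood[2])
    qr_hat = conserve_fluxes(q_rbc[0], q_rbc[1], q_rbc[2])
    phi1, phi2, psi1, psi2 = fractional_flows(qb_hat, qr_hat)
    return FluxSummary(
        u_mean=u_mean,
        ht=ht,
        q_blood=q_blood,
        q_rbc=q_rbc,
        q_blood_hat=dict(enumerate(qb_hat)),
        q_rbc_hat=dict(enumerate(qr_hat)),
        phi={1: phi1, 2: phi2},
        psi={1: psi1, 2: psi2},
        capillary_number=capillary_number(consts, u_mean[0]),
    )
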