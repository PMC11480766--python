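"""Lateral distribution functions, skewness index, and composite-LDF fitting.

The lateral distribution function (LDF) of a channel is the normalised
histogram of cell lateral positions y* = y/W over [-0.5, 0.5] — the
hematocrit profile.  Its skewness index

    Sk = | (mass below the centerline) - 0.5 |

is 0 for a symmetric profile and 0.5 when all cells sit on one side.

A composite LDF mixes the lingerer and non-lingerer profiles,

    LDF_C(y*, gamma) = gamma LDF_L(y*) + (1 - gamma) LDF_N(y*),

and the lingering frequency gamma_hat that best explains a target profile is
found by least squares over the distal half-channel y* in [0, 0.5].  Because
LDF_C is linear in gamma, the squared error is exactly quadratic and the
minimiser is closed-form (clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

DEFAULT_N_BINS = 24


class GridMismatchError(ValueError):
    pass


class UnidentifiableError(ValueError):
    """The lingerer and non-lingerer LDFs coincide on the fit interval."""


@dataclass(frozen=True)
class LateralDistribution:
    """Binned, normalised lateral profile over y* in [-0.5, 0.5]."""

    bin_edges: np.ndarray
    mass: np.ndarray  # per-bin frequency, sums to 1
    n_samples: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "mass", mass)
        if len(edges) != len(mass) + 1:
            raise ValueError("bin_edges must have one more entry than mass")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not (np.isclose(edges[0], -0.5) and np.isclose(edges[-1], 0.5)):
            raise ValueError("edges must span [-0.5, 0.5]")
        if np.any(mass < 0):
            raise ValueError("bin mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1, got {mass.sum()!r}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def density(self) -> np.ndarray:
        """Mass per unit y* (the LDF as a piecewise-constant density)."""
        return self.mass / self.bin_widths

    @property
    def sk(self) -> float:
        return skewness_index(self)

    def same_grid(self, other: "LateralDistribution") -> bool:
        return len(self.bin_edges) == len(other.bin_edges) and np.allclose(
            self.bin_edges, other.bin_edges
        )


@dataclass(frozen=True)
class GammaFit:
    """Optimal lingering frequency explaining a target lateral profile."""

    gamma_hat: float
    error: float
    fit_interval: tuple[float, float] = (0.0, 0.5)


def build_ldf(y_samples, n_bins: int = DEFAULT_N_BINS) -> LateralDistribution:
    """Histogram lateral samples into a normalised LDF.

    Bins are half-open [e_k, e_{k+1}) with the last bin closed, over an even
    number (>= 4) of equal-width bins spanning [-0.5, 0.5] so that a bin edge
    falls exactly on the centerline.
    """
    y = np.asarray(y_samples, dtype=float)
    if len(y) == 0:
        raise ValueError("no lateral samples")
    if np.any((y < -0.5) | (y > 0.5)):
        bad = y[(y < -0.5) | (y > 0.5)][0]
        raise ValueError(f"lateral sample {bad} outside [-0.5, 0.5]")
    if n_bins < 4 or n_bins % 2:
        raise ValueError(f"n_bins must be even and >= 4, got {n_bins}")
    edges = np.linspace(-0.5, 0.5, n_bins + 1)
    counts, _ = np.histogram(y, bins=edges)
    return LateralDistribution(bin_edges=edges, mass=counts / counts.sum(), n_samples=len(y))


def skewness_index(ldf: LateralDistribution) -> float:
    """Sk = |mass below the centerline - 0.5| in [0, 0.5].

    Discrete form of the half-channel integral ratio; requires a bin edge at
    y* = 0 (guaranteed for even equal-width grids).
    """
    upper_edges = ldf.bin_edges[1:]
    if not np.any(np.isclose(upper_edges, 0.0)):
        raise ValueError("skewness index needs a bin edge at y* = 0")
    lower_mass = float(ldf.mass[upper_edges <= 1e-12].sum())
    return abs(lower_mass - 0.5)


def composite_ldf(
    ldf_l: LateralDistribution, ldf_n: LateralDistribution, gamma: float
) -> LateralDistribution:
    """Convex combination gamma * LDF_L + (1 - gamma) * LDF_N on a shared grid."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if not ldf_l.same_grid(ldf_n):
        raise GridMismatchError("lingerer and non-lingerer LDFs use different bin grids")
    mass = gamma * ldf_l.mass + (1.0 - gamma) * ldf_n.mass
    n = int(round(gamma * ldf_l.n_samples + (1.0 - gamma) * ldf_n.n_samples))
    return LateralDistribution(bin_edges=ldf_l.bin_edges, mass=mass, n_samples=n)


def _fit_weights(ldf: LateralDistribution, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    lower_edges = ldf.bin_edges[:-1]
    upper_edges = ldf.bin_edges[1:]
    sel = (lower_edges >= lo - 1e-12) & (upper_edges <= hi + 1e-12)
    return sel


def squared_error(
    target: LateralDistribution,
    ldf_l: LateralDistribution,
    ldf_n: LateralDistribution,
    gamma: float,
    fit_interval: tuple[float, float] = (0.0, 0.5),
) -> float:
    """E(gamma): bin-width-weighted squared density mismatch on the fit interval."""
    comp = gamma * ldf_l.density + (1.0 - gamma) * ldf_n.density
    sel = _fit_weights(target, fit_interval)
    diff = target.density[sel] - comp[sel]
    return float(np.sum(target.bin_widths[sel] * diff * diff))


def fit_gamma(
    target: LateralDistribution,
    ldf_l: LateralDistribution,
    ldf_n: LateralDistribution,
    fit_interval: tuple[float, float] = (0.0, 0.5),
) -> GammaFit:
    """Least-squares lingering frequency explaining a target profile.

    E(gamma) is quadratic in gamma, so the minimiser is closed-form:
    with per-bin residuals a = target - LDF_N and direction b = LDF_L - LDF_N
    (as densities, restricted to the fit interval),
    gamma_hat = sum(w a b) / sum(w b^2), clipped to [0, 1].
    """
    for other in (ldf_l, ldf_n):
        if not target.same_grid(other):
            raise GridMismatchError("all LDFs must share one bin grid")
    sel = _fit_weights(target, fit_interval)
    if not sel.any():
        raise ValueError(f"no bins inside fit interval {fit_interval}")
    w = target.bin_widths[sel]
    a = target.density[sel] - ldf_n.density[sel]
    b = ldf_l.density[sel] - ldf_n.density[sel]
    denom = float(np.sum(w * b * b))
    if denom <= 0.0:
        raise UnidentifiableError(
            "lingerer and non-lingerer LDFs coincide on the fit interval"
        )
    gamma_hat = float(np.clip(np.sum(w * a * b) / denom, 0.0, 1.0))
    err = squared_error(target, ldf_l, ldf_n, gamma_hat, fit_interval)
    return GammaFit(gamma_hat=gamma_hat, error=err, fit_interval=tuple(fit_interval))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic, p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = _stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of the first sample, p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = _stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
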