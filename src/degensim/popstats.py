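"""Summary statistics over trait distributions from either engine.

Population homogeneity is measured by the mass-weighted standard deviation of
trait values; regimes (divergent vs. static) are classified by counting modes
of the smoothed trait distribution; resource exploitation is tracked by the
consumed fraction of total carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .trait_space import ResourceProfile, TraitGrid

__all__ = [
    "TraitDistribution",
    "trait_sd",
    "count_modes",
    "find_modes",
    "consumed_fraction",
    "sd_vs_sigma_scan",
    "ScanResult",
]

#: Mass below this fraction of the maximum is treated as numerical dust and
#: zeroed before mode counting.
EXTINCTION_REL = 1e-12

#: Mode-detection defaults: smoothing bandwidth in trait units, and the
#: minimum peak prominence relative to the global maximum.
DEFAULT_SMOOTH_BW = 5.0
DEFAULT_MIN_REL_PROMINENCE = 0.05


@dataclass(frozen=True)
class TraitDistribution:
    """Non-negative population mass per grid location."""

    grid: TraitGrid
    mass: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (self.grid.n_points,):
            raise ValueError("mass length does not match grid")
        if np.any(m < 0):
            raise ValueError("mass must be non-negative")
        object.__setattr__(self, "mass", m)

    @property
    def total(self) -> float:
        return float(self.mass.sum())


def trait_sd(d: TraitDistribution) -> float:
    """Mass-weighted population standard deviation of trait values.

    Uses the population formula (divisor = total mass); with unit masses per
    individual this coincides with the SD over individual trait values.
    """
    total = d.mass.sum()
    if total <= 0:
        raise ValueError("trait_sd undefined for zero total mass (extinct population)")
    locs = d.grid.locations
    mean = float(np.dot(d.mass, locs) / total)
    var = float(np.dot(d.mass, (locs - mean) ** 2) / total)
    return float(np.sqrt(max(var, 0.0)))


def _smoothed_mass(
    d: TraitDistribution, smooth_bw: float, extinction_rel: float
) -> np.ndarray:
    mass = d.mass.copy()
    mass[mass < extinction_rel * mass.max()] = 0.0
    if smooth_bw > 0:
        mass = gaussian_filter1d(mass, sigma=smooth_bw / d.grid.spacing, mode="constant")
    return mass


def count_modes(
    d: TraitDistribution,
    smooth_bw: float = DEFAULT_SMOOTH_BW,
    min_rel_prominence: float = DEFAULT_MIN_REL_PROMINENCE,
) -> int:
    """Number of modes of the Gaussian-smoothed trait distribution.

    A mode is a local maximum of the smoothed mass whose peak prominence
    exceeds ``min_rel_prominence`` times the global maximum.  The
    distribution is zero-padded at both ends so boundary maxima count.
    """
    return len(find_modes(d, smooth_bw, min_rel_prominence)[0])


def find_modes(
    d: TraitDistribution,
    smooth_bw: float = DEFAULT_SMOOTH_BW,
    min_rel_prominence: float = DEFAULT_MIN_REL_PROMINENCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Mode and inter-mode-valley trait values of the smoothed distribution.

    Returns ``(peak_locations, valley_locations)``; valleys are the minima of
    the smoothed mass between consecutive detected modes.
    """
    if d.total <= 0:
        raise ValueError("mode detection undefined for zero total mass")
    smooth = _smoothed_mass(d, smooth_bw, EXTINCTION_REL)
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = find_peaks(padded, prominence=min_rel_prominence * padded.max())
    idx = peaks - 1  # undo padding offset
    locs = d.grid.locations
    valleys = []
    for a, b in zip(idx, idx[1:]):
        valleys.append(locs[a + int(np.argmin(smooth[a : b + 1]))])
    return locs[idx], np.array(valleys)


def consumed_fraction(obj, K: ResourceProfile) -> float:
    """Fraction of total carrying capacity exploited by the population.

    Mean-field: total population mass over total capacity (both × spacing).
    Cellular automata: resource consumed in the last completed cycle over the
    per-cycle resource budget.  Accepts a density-like object (``.density``),
    a CA state (``.consumed_last_cycle``), or a :class:`TraitDistribution`.
    """
    total_K = K.total
    if total_K <= 0:
        raise ValueError("consumed_fraction undefined: total carrying capacity is zero")
    if hasattr(obj, "consumed_last_cycle"):
        return float(obj.consumed_last_cycle / total_K)
    if hasattr(obj, "density"):
        mass = float(np.sum(obj.density) * K.grid.spacing)
        return mass / total_K
    if isinstance(obj, TraitDistribution):
        # mass is already density × spacing (or a head count)
        return float(obj.total / total_K)
    raise TypeError(f"cannot compute consumed fraction for {type(obj)!r}")


@dataclass
class ScanResult:
    """Outcome of an SD-versus-sigma scan."""

    table: pd.DataFrame  # columns: sigma, iteration, sd, mode_count
    argmin_sigma: float | None  # sigma minimizing latest-iteration SD, stabilizing regime only
    boundary_sigma: float | None  # smallest sigma classified as stabilizing (unimodal)


def sd_vs_sigma_scan(
    sigmas: Sequence[float],
    runner: Callable[[float], "object"],
    at_iterations: Sequence[int],
) -> ScanResult:
    """Scan degeneracy values, recording trait SD and mode count at chosen iterations.

    ``runner(sigma)`` must return a :class:`~degensim.timeseries.TimeSeries`
    whose snapshots carry ``iteration``, ``sd`` and ``mode_count`` stats and
    cover all requested iterations.  The reported ``argmin_sigma`` minimizes
    the latest-iteration SD restricted to the stabilizing (unimodal) regime;
    multimodal (dichotomous) sigma values are excluded, mirroring the split
    between divergent and stabilizing dynamics.
    """
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigmas must be strictly increasing")
    rows = []
    for sigma in sigmas:
        ts = runner(sigma)
        by_iter = {snap.stats["iteration"]: snap for snap in ts.snapshots}
        for it in at_iterations:
            if it not in by_iter:
                raise ValueError(f"run at sigma={sigma} has no snapshot at iteration {it}")
            snap = by_iter[it]
            rows.append(
                {
                    "sigma": sigma,
                    "iteration": it,
                    "sd": snap.stats["sd"],
                    "mode_count": snap.stats["mode_count"],
                }
            )
    table = pd.DataFrame(rows)
    latest = table[table["iteration"] == max(at_iterations)]
    stabilizing = latest[latest["mode_count"] == 1]
    if len(stabilizing):
        argmin_sigma = float(stabilizing.loc[stabilizing["sd"].idxmin(), "sigma"])
        boundary_sigma = float(stabilizing["sigma"].min())
    else:
        argmin_sigma = None
        boundary_sigma = None
    return ScanResult(table=table, argmin_sigma=argmin_sigma, boundary_sigma=boundary_sigma)
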