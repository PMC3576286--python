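"""Trait-axis discretization, degeneracy kernels, and resource environments.

The model universe is a one-dimensional trait axis discretized into evenly
spaced locations.  Individuals are characterized by a single trait value
(their location), and a resource -- expressed as a carrying capacity K(s) --
is distributed along the same axis.  Degenerate (imperfectly specific)
resource consumption is described by a unimodal kernel f(s - s'): an
individual whose median trait value is s' consumes resource at nearby
locations s with weight f(s - s').  The kernel's standard deviation sigma is
the *degeneracy range*; sigma = 0 recovers strictly location-specific
consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitGrid",
    "DegeneracyKernel",
    "ResourceProfile",
    "ResourceSchedule",
    "make_grid",
    "gaussian_kernel",
    "kernel_mass_in_window",
    "rectangular_resource",
    "widening_schedule",
]

#: Kernels are tabulated out to this many standard deviations from the center
#: (or to the grid extent, whichever is smaller).
KERNEL_TRUNCATION_SDS = 6.0


class ConfigurationError(ValueError):
    """Raised for inconsistent grid / resource / schedule configuration."""


@dataclass(frozen=True)
class TraitGrid:
    """Evenly spaced discretization of the one-dimensional trait axis.

    Parameters
    ----------
    lower, upper:
        Trait values of the first and last grid location (inclusive).
    spacing:
        Distance between adjacent locations, in trait units.
    """

    lower: float
    upper: float
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")
        if self.lower > self.upper:
            raise ConfigurationError(
                f"lower ({self.lower}) must not exceed upper ({self.upper})"
            )
        span = self.upper - self.lower
        k = round(span / self.spacing)
        if abs(k * self.spacing - span) > 1e-9 * max(1.0, abs(span)):
            raise ConfigurationError(
                f"spacing {self.spacing} does not divide the range "
                f"[{self.lower}, {self.upper}] into a whole number of intervals"
            )

    @property
    def n_points(self) -> int:
        return round((self.upper - self.lower) / self.spacing) + 1

    @property
    def extent(self) -> float:
        """Total width of the axis, upper - lower."""
        return self.upper - self.lower

    @property
    def locations(self) -> np.ndarray:
        return self.lower + self.spacing * np.arange(self.n_points)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def index_of(self, value: float) -> int:
        """Index of the grid location nearest to ``value`` (must lie on the grid)."""
        i = round((value - self.lower) / self.spacing)
        if not 0 <= i < self.n_points:
            raise ConfigurationError(f"location {value} outside grid [{self.lower}, {self.upper}]")
        return i


@dataclass(frozen=True)
class DegeneracyKernel:
    """Tabulated degeneracy function f evaluated on symmetric grid offsets.

    ``weights[i]`` is f(offsets[i]); offsets are multiples of the grid
    spacing, symmetric about 0, and the kernel is even and unimodal with its
    maximum at offset 0.  For sigma > 0 the weights are Gaussian densities and
    are *not* renormalized after truncation: kernel mass falling outside the
    trait axis is deliberately lost, representing fruitless consumption
    attempts outside the resource range.
    """

    sigma: float
    offsets: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    spacing: float = 1.0

    @property
    def half_width(self) -> int:
        """Number of tabulated offsets on each side of zero."""
        return (len(self.weights) - 1) // 2

    @property
    def total_mass(self) -> float:
        """Sum of weights times spacing (≈ 1 for sigma > 0, exactly 1 for sigma = 0)."""
        if self.sigma == 0:
            return 1.0
        return float(np.sum(self.weights) * self.spacing)


def make_grid(lower: float, upper: float, spacing: float = 1.0) -> TraitGrid:
    """Build a :class:`TraitGrid`; ``spacing`` must divide ``upper - lower`` exactly."""
    return TraitGrid(lower=lower, upper=upper, spacing=spacing)


def gaussian_kernel(sigma: float, grid: TraitGrid) -> DegeneracyKernel:
    """Gaussian degeneracy kernel f(x) = exp(-x²/2σ²)/(σ√(2π)) tabulated on grid offsets.

    The kernel is evaluated at offsets k·spacing with |k·spacing| ≤
    min(6σ, grid extent).  sigma = 0 returns the discrete identity (delta)
    kernel: weight 1 at offset 0.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return DegeneracyKernel(
            sigma=0.0,
            offsets=np.array([0.0]),
            weights=np.array([1.0]),
            spacing=grid.spacing,
        )
    reach = min(KERNEL_TRUNCATION_SDS * sigma, grid.extent)
    k_max = int(np.floor(reach / grid.spacing + 1e-9))
    offsets = grid.spacing * np.arange(-k_max, k_max + 1)
    weights = np.exp(-(offsets**2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))
    return DegeneracyKernel(sigma=float(sigma), offsets=offsets, weights=weights, spacing=grid.spacing)


def kernel_mass_in_window(kernel: DegeneracyKernel, center: float, grid: TraitGrid) -> float:
    """Fraction of the kernel's mass landing inside the trait axis when centered at ``center``.

    Quantifies the edge penalty: individuals near the boundary lose part of
    their consumption range outside the resource distribution.
    """
    if not grid.contains(center):
        raise ValueError(f"center {center} outside grid [{grid.lower}, {grid.upper}]")
    if kernel.sigma == 0:
        return 1.0
    positions = center + kernel.offsets
    inside = (positions >= grid.lower - 1e-9) & (positions <= grid.upper + 1e-9)
    return float(np.sum(kernel.weights[inside]) * kernel.spacing)


@dataclass(frozen=True)
class ResourceProfile:
    """Carrying capacity K(s) per grid location."""

    grid: TraitGrid
    capacity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cap = np.asarray(self.capacity, dtype=float)
        if cap.shape != (self.grid.n_points,):
            raise ConfigurationError(
                f"capacity length {cap.shape} does not match grid with {self.grid.n_points} points"
            )
        if np.any(cap < 0):
            raise ConfigurationError("carrying capacity must be non-negative everywhere")
        object.__setattr__(self, "capacity", cap)

    @property
    def total(self) -> float:
        """Total carrying capacity, Σ K·spacing."""
        return float(np.sum(self.capacity) * self.grid.spacing)

    def support_bounds(self) -> tuple[float, float]:
        """Trait values of the first and last location with positive capacity."""
        nz = np.nonzero(self.capacity > 0)[0]
        if len(nz) == 0:
            raise ConfigurationError("resource profile is identically zero")
        locs = self.grid.locations
        return float(locs[nz[0]]), float(locs[nz[-1]])


def rectangular_resource(grid: TraitGrid, lo: float, hi: float, height: float) -> ResourceProfile:
    """Rectangular carrying-capacity profile: ``height`` on [lo, hi], zero elsewhere."""
    if height <= 0:
        raise ConfigurationError(f"height must be positive, got {height}")
    if not (grid.lower <= lo <= hi <= grid.upper):
        raise ConfigurationError(
            f"need lower <= lo <= hi <= upper, got lo={lo}, hi={hi} on [{grid.lower}, {grid.upper}]"
        )
    locs = grid.locations
    capacity = np.where((locs >= lo - 1e-9) & (locs <= hi + 1e-9), float(height), 0.0)
    return ResourceProfile(grid=grid, capacity=capacity)


@dataclass(frozen=True)
class ResourceSchedule:
    """Piecewise-constant-in-time resource environment.

    ``segments`` is an ordered sequence of (start_time, profile) pairs; the
    profile starting at time t applies on [t, next_start) -- lookups are
    right-continuous, so at the switch time the *new* profile applies.
    """

    segments: tuple[tuple[float, ResourceProfile], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("schedule needs at least one segment")
        starts = [s for s, _ in self.segments]
        if starts[0] != 0:
            raise ConfigurationError("first segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError("segment start times must be strictly increasing")
        grids = {p.grid for _, p in self.segments}
        if len(grids) != 1:
            raise ConfigurationError("all profiles in a schedule must share one grid")

    @property
    def grid(self) -> TraitGrid:
        return self.segments[0][1].grid

    @classmethod
    def constant(cls, profile: ResourceProfile) -> "ResourceSchedule":
        return cls(segments=((0.0, profile),))

    def lookup(self, t: float) -> ResourceProfile:
        """Profile in force at time t (piecewise constant, right-continuous)."""
        current = self.segments[0][1]
        for start, profile in self.segments:
            if t >= start:
                current = profile
            else:
                break
        return current


def widening_schedule(
    outer: ResourceProfile, fraction_per_side: float, t_switch: float
) -> ResourceSchedule:
    """Two-segment schedule: a narrowed rectangle until ``t_switch``, then ``outer``.

    The inner rectangle removes ``fraction_per_side`` of the outer support
    width from each side (e.g. outer support [0, 299] with fraction 1/6 gives
    inner support [50, 249]).  Models a small, edge-only broadening of the
    resource distribution mid-run.
    """
    if not 0 < fraction_per_side < 0.5:
        raise ConfigurationError(
            f"fraction_per_side must lie in (0, 0.5), got {fraction_per_side}"
        )
    if t_switch <= 0:
        raise ConfigurationError(f"t_switch must be positive, got {t_switch}")
    lo, hi = outer.support_bounds()
    grid = outer.grid
    n_support = round((hi - lo) / grid.spacing) + 1
    height = float(outer.capacity.max())
    inner_region = (outer.capacity > 0)
    if not np.all(outer.capacity[inner_region] == height):
        raise ConfigurationError("widening_schedule requires a rectangular outer profile")
    shift = round(fraction_per_side * n_support) * grid.spacing
    inner = rectangular_resource(grid, lo + shift, hi - shift, height)
    return ResourceSchedule(segments=((0.0, inner), (float(t_switch), outer)))
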