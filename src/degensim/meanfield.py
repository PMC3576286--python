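"""Mean-field engine: non-local logistic growth with demand-partitioned resource.

The population is a density N(s, t) on the trait grid.  Each subpopulation at
s' consumes resource degenerately across the axis with kernel weight
f(s - s'); the total *demand* on resource at s is

    D(s) = ∫ f(s - s'') N(s'') ds'' ,

and the carrying capacity K(s) is partitioned among consumers in proportion
to their share of that demand.  The resulting dynamics are

    dN(s')/dt = r N(s') (1 - 1/g(s')),   g(s') = ∫ K(s) f(s - s') / D(s) ds ,

where the factor N(s') inside the share integral has been cancelled
algebraically against the outer division (an identity, not an approximation,
which also avoids 0/0 at empty sites).  g(s') is the per-capita carrying
capacity reachable from s'; g ≡ 1 on the occupied set characterizes
equilibrium, which forces ∫N = ∫K over the demanded region.

Integration is classical fixed-step 4th-order Runge-Kutta; negative densities
from overshoot are clipped to zero after each committed step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from . import popstats
from .timeseries import Snapshot, TimeSeries
from .trait_space import (
    ConfigurationError,
    DegeneracyKernel,
    ResourceProfile,
    ResourceSchedule,
    TraitGrid,
)

__all__ = [
    "PopulationDensity",
    "MeanfieldConfig",
    "demand_field",
    "share_integral",
    "growth_rhs",
    "rk4_step",
    "integrate",
    "default_initial_density",
]


@dataclass(frozen=True)
class PopulationDensity:
    """Non-negative population density per grid location (individuals per trait unit)."""

    grid: TraitGrid
    density: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.shape != (self.grid.n_points,):
            raise ConfigurationError("density length does not match grid")
        if np.any(d < 0):
            raise ConfigurationError("density must be non-negative")
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class MeanfieldConfig:
    """Numerical parameters of the mean-field engine.

    r is the Malthusian growth rate (location-independent; time is measured
    in units of 1/r).  dt is the fixed RK4 step.  demand_floor is relative to
    max(N)·spacing: demand below the floor is treated as absent and the
    corresponding resource exerts no force.  decay_cap sets the death rate
    (in units of r) at occupied sites with no reachable resource, where the
    raw equation would diverge.
    """

    r: float = 1.0
    dt: float = 0.025
    n_steps: int = 8000
    snapshot_every: int = 100
    demand_floor: float = 1e-12
    decay_cap: float = 1.0
    extinction_rel: float = 1e-12

    def __post_init__(self) -> None:
        if self.r <= 0 or self.dt <= 0:
            raise ConfigurationError("r and dt must be positive")
        if self.n_steps < 1 or self.snapshot_every < 1:
            raise ConfigurationError("n_steps and snapshot_every must be >= 1")
        if self.demand_floor <= 0:
            raise ConfigurationError("demand_floor must be positive")


def _check_shared_grid(kernel: DegeneracyKernel, grid: TraitGrid) -> None:
    if abs(kernel.spacing - grid.spacing) > 1e-12:
        raise ConfigurationError(
            f"kernel spacing {kernel.spacing} does not match grid spacing {grid.spacing}"
        )


def _convolve(values: np.ndarray, kernel: DegeneracyKernel, periodic: bool) -> np.ndarray:
    """Discrete kernel sum Σ_j f(s_i - s_j)·values_j·spacing.

    Bounded grids contribute nothing from outside the axis; periodic grids
    wrap offsets around (test/oracle use).
    """
    w = kernel.weights
    half = kernel.half_width
    n = len(values)
    if not periodic:
        full = np.convolve(values, w)
        return full[half : half + n] * kernel.spacing
    out = np.zeros(n)
    for a, wa in enumerate(w):
        out += wa * np.roll(values, a - half)
    return out * kernel.spacing


class KernelOperator:
    """Dense matrix form of the bounded-grid kernel sum.

    W[i, j] = f(s_i - s_j)·spacing, so W @ v equals the discrete convolution
    used by :func:`demand_field` (identical up to floating-point summation
    order).  The even kernel makes W symmetric.  Built once per run and
    applied via BLAS; for a 300-point grid this is several times faster than
    per-step convolution.
    """

    def __init__(self, kernel: DegeneracyKernel, grid: TraitGrid) -> None:
        _check_shared_grid(kernel, grid)
        n = grid.n_points
        col = np.zeros(n)
        m = min(kernel.half_width + 1, n)
        col[:m] = kernel.weights[kernel.half_width : kernel.half_width + m]
        self.matrix = toeplitz(col) * grid.spacing
        self.spacing = grid.spacing

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.matrix @ values


def _rhs_from_operator(
    dens: np.ndarray, K_cap: np.ndarray, op: KernelOperator, cfg: MeanfieldConfig
) -> np.ndarray:
    """growth_rhs on raw arrays through a precomputed KernelOperator."""
    clipped = np.maximum(dens, 0.0)
    D = op.apply(clipped)
    floor_abs = cfg.demand_floor * float(clipped.max(initial=0.0)) * op.spacing
    demanded = D > floor_abs
    ratio = np.where(demanded, K_cap / np.where(demanded, D, 1.0), 0.0)
    g = op.apply(ratio)
    rhs = np.zeros_like(clipped)
    occupied = clipped > 0
    fed = occupied & (g > 0)
    rhs[fed] = cfg.r * clipped[fed] * (1.0 - 1.0 / g[fed])
    starved = occupied & ~fed
    rhs[starved] = -cfg.r * cfg.decay_cap * clipped[starved]
    return rhs


def demand_field(
    N: PopulationDensity, kernel: DegeneracyKernel, periodic: bool = False
) -> np.ndarray:
    """Total demand D(s) = Σ f(s - s'')·N(s'')·spacing over the grid."""
    _check_shared_grid(kernel, N.grid)
    return _convolve(N.density, kernel, periodic)


def share_integral(
    N: PopulationDensity,
    K: ResourceProfile,
    kernel: DegeneracyKernel,
    demand_floor: float = 1e-12,
    periodic: bool = False,
) -> np.ndarray:
    """Per-capita reachable capacity g(s') = Σ K(s)·f(s - s')/D(s)·spacing.

    Locations with no demand (D below the floor, relative to max(N)·spacing)
    contribute nothing: unconsumed resource exerts no force.  K(s) = 0
    locations contribute nothing regardless of demand.
    """
    _check_shared_grid(kernel, N.grid)
    if K.grid.n_points != N.grid.n_points:
        raise ConfigurationError("resource and density grids differ")
    D = demand_field(N, kernel, periodic)
    floor_abs = demand_floor * float(N.density.max(initial=0.0)) * N.grid.spacing
    ratio = np.where(D > floor_abs, K.capacity / np.where(D > floor_abs, D, 1.0), 0.0)
    return _convolve(ratio, kernel, periodic)


def growth_rhs(
    N: PopulationDensity,
    K: ResourceProfile,
    kernel: DegeneracyKernel,
    cfg: MeanfieldConfig,
    periodic: bool = False,
) -> np.ndarray:
    """dN/dt: r·N·(1 - 1/g) where occupied and g > 0; -r·N·decay_cap where no
    reachable resource; 0 where empty."""
    g = share_integral(N, K, kernel, cfg.demand_floor, periodic)
    dens = N.density
    rhs = np.zeros_like(dens)
    occupied = dens > 0
    fed = occupied & (g > 0)
    rhs[fed] = cfg.r * dens[fed] * (1.0 - 1.0 / g[fed])
    starved = occupied & ~fed
    rhs[starved] = -cfg.r * cfg.decay_cap * dens[starved]
    return rhs


def _rhs_raw(
    dens: np.ndarray,
    grid: TraitGrid,
    K: ResourceProfile,
    kernel: DegeneracyKernel,
    cfg: MeanfieldConfig,
) -> np.ndarray:
    # RK4 stages may carry (small) negative entries; treat them as empty.
    clipped = np.maximum(dens, 0.0)
    return growth_rhs(PopulationDensity(grid, clipped), K, kernel, cfg)


def rk4_step(
    N: PopulationDensity,
    K_at_t: ResourceProfile,
    kernel: DegeneracyKernel,
    cfg: MeanfieldConfig,
) -> PopulationDensity:
    """One classical 4-stage RK4 update of the full density field.

    Negatives in the committed state are clipped to zero; non-finite values
    abort with a diagnostic.
    """
    dens = N.density
    grid = N.grid
    dt = cfg.dt
    k1 = _rhs_raw(dens, grid, K_at_t, kernel, cfg)
    k2 = _rhs_raw(dens + 0.5 * dt * k1, grid, K_at_t, kernel, cfg)
    k3 = _rhs_raw(dens + 0.5 * dt * k2, grid, K_at_t, kernel, cfg)
    k4 = _rhs_raw(dens + dt * k3, grid, K_at_t, kernel, cfg)
    new = dens + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(new)):
        bad = int(np.flatnonzero(~np.isfinite(new))[0])
        raise FloatingPointError(
            f"non-finite density after RK4 step at grid index {bad} "
            f"(dt={dt}, sigma={kernel.sigma}); reduce dt or check the configuration"
        )
    return PopulationDensity(grid, np.maximum(new, 0.0))


def _snapshot_stats(
    dens: np.ndarray, grid: TraitGrid, K: ResourceProfile, iteration: int, extinction_rel: float
) -> dict:
    mass = dens * grid.spacing
    dist = popstats.TraitDistribution(grid, mass)
    stats: dict = {"iteration": iteration, "total": dist.total}
    if dist.total > 0:
        thresh = extinction_rel * float(mass.max())
        trimmed = popstats.TraitDistribution(grid, np.where(mass > thresh, mass, 0.0))
        stats["sd"] = popstats.trait_sd(trimmed)
        stats["mode_count"] = popstats.count_modes(trimmed)
        stats["consumed_fraction"] = popstats.consumed_fraction(dist, K)
    else:
        stats.update({"sd": np.nan, "mode_count": 0, "consumed_fraction": 0.0})
    return stats


def integrate(
    N0: PopulationDensity,
    schedule: ResourceSchedule,
    kernel: DegeneracyKernel,
    cfg: MeanfieldConfig,
) -> TimeSeries:
    """Fixed-step RK4 integration with snapshots every ``snapshot_every`` steps.

    The resource profile applied during step i is ``schedule.lookup(i·dt)``.
    The initial state and the final state are always recorded.
    """
    grid = N0.grid
    op = KernelOperator(kernel, grid)
    dens = N0.density
    dt = cfg.dt
    K = schedule.lookup(0.0)
    snaps = [Snapshot(0.0, dens * grid.spacing, _snapshot_stats(dens, grid, K, 0, cfg.extinction_rel))]
    for i in range(cfg.n_steps):
        K = schedule.lookup(i * dt)
        K_cap = K.capacity
        k1 = _rhs_from_operator(dens, K_cap, op, cfg)
        k2 = _rhs_from_operator(dens + 0.5 * dt * k1, K_cap, op, cfg)
        k3 = _rhs_from_operator(dens + 0.5 * dt * k2, K_cap, op, cfg)
        k4 = _rhs_from_operator(dens + dt * k3, K_cap, op, cfg)
        dens = dens + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(dens)):
            bad = int(np.flatnonzero(~np.isfinite(dens))[0])
            raise FloatingPointError(
                f"non-finite density at step {i + 1}, grid index {bad} "
                f"(dt={dt}, sigma={kernel.sigma}); reduce dt or check the configuration"
            )
        dens = np.maximum(dens, 0.0)
        step = i + 1
        if step % cfg.snapshot_every == 0 or step == cfg.n_steps:
            t = step * dt
            snaps.append(
                Snapshot(t, dens * grid.spacing,
                         _snapshot_stats(dens, grid, K, step, cfg.extinction_rel))
            )
    status = "extinct" if snaps[-1].stats["total"] <= 0 else "ok"
    return TimeSeries(grid=grid, snapshots=snaps, engine="meanfield", status=status,
                      meta={"sigma": kernel.sigma, "r": cfg.r, "dt": cfg.dt, "n_steps": cfg.n_steps})


def default_initial_density(
    K: ResourceProfile, amplitude_fraction: float = 0.01
) -> PopulationDensity:
    """Rectangular initial density: a small fraction of K on the resource support.

    Joint rescaling of K and N0 rescales the whole trajectory, so the
    amplitude is immaterial to the dynamics' shape.
    """
    return PopulationDensity(K.grid, amplitude_fraction * K.capacity)
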