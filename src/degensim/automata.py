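"""Stochastic engine: energy-budget cellular automata with degenerate feeding.

Each automaton is an individual with an integer trait location and an energy
store.  Time is cyclical; the resource array is restored to its base value at
the start of every cycle, and automata are processed once per cycle in a
freshly randomized order.  Per cycle each automaton

1. expends a constant maintenance cost ("cost of living"): a fixed fraction
   of the consumption unit, the same for every automaton and cycle;
2. (optionally) dies at random with a fixed probability;
3. attempts to feed at a location drawn as round(loc + sigma·z), z a
   standard normal variate from the Box-Muller transform -- draws landing
   outside the grid are fruitless, and a feed succeeds only if at least one
   full consumption unit remains at the drawn location;
4. dies if its energy balance is ≤ 0;
5. self-propagates if its energy exceeds the reproduction threshold; the
   child starts with the founder energy (deducted from the parent by
   default) at the parent's location, displaced by round(mutability·z) and
   clipped to the grid when heritable trait variability is enabled.

Children join the processing pool the following cycle.  With a fixed seed the
whole history is deterministic.

``run_cycle`` advances the whole population through one cycle using a
vectorized allocation that is exactly equivalent to processing the automata
sequentially in the shuffled order (a sequential path is kept for
verification): per-automaton variates are pre-drawn in processing order, and
because every successful feed removes one fixed unit, resource at each cell
goes to the earliest-processed automata that drew it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import popstats
from .timeseries import Snapshot, TimeSeries
from .trait_space import ConfigurationError, ResourceProfile, TraitGrid

__all__ = [
    "Automaton",
    "CAParams",
    "CAState",
    "init_state",
    "box_muller",
    "draw_feed_location",
    "step_automaton",
    "spawn_offspring",
    "run_cycle",
    "run",
    "OUT_OF_RANGE",
]

#: Sentinel returned by draw_feed_location for draws outside the grid.
OUT_OF_RANGE: int = -(10**9)


@dataclass
class Automaton:
    """One individual: trait location (grid index) and accumulated energy."""

    location: int
    energy: float


@dataclass(frozen=True)
class CAParams:
    """Constants of the cellular-automata engine.

    ``maintenance_fraction`` is the constant per-cycle cost of living as a
    fraction of the consumption unit (cost = maintenance_fraction ×
    consume_unit); an automaton whose long-run feeding success rate falls
    below this fraction starves.  The defaults are chosen so that one
    resource cell sustains on the order of ten individuals and the
    generation time is on the order of ten cycles; all are
    configuration-exposed.
    """

    sigma: float
    maintenance_fraction: float = 0.5
    consume_unit: float = 1.0
    repro_threshold: float = 5.0
    initial_energy: float = 1.0
    death_prob: float = 0.0
    mutability: float = 0.0
    max_population: int = 10**6
    #: "deduct": child energy comes out of the parent's store (default);
    #: "copy": the parent keeps its full store (sensitivity switch).
    offspring_energy: str = "deduct"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")
        if not 0 <= self.maintenance_fraction < 1:
            raise ConfigurationError("maintenance_fraction must lie in [0, 1)")
        if self.consume_unit <= 0 or self.initial_energy <= 0:
            raise ConfigurationError("consume_unit and initial_energy must be positive")
        if self.repro_threshold <= self.initial_energy:
            raise ConfigurationError("repro_threshold must exceed initial_energy")
        if not 0 <= self.death_prob < 1:
            raise ConfigurationError("death_prob must lie in [0, 1)")
        if self.mutability < 0:
            raise ConfigurationError("mutability must be non-negative")
        if self.offspring_energy not in ("deduct", "copy"):
            raise ConfigurationError("offspring_energy must be 'deduct' or 'copy'")


@dataclass
class CAState:
    """Full engine state: per-cycle resource, the population, and the RNG."""

    grid: TraitGrid
    base_resource: ResourceProfile
    remaining: np.ndarray
    locations: np.ndarray  # int array, one entry per live automaton
    energies: np.ndarray  # float array, parallel to locations
    cycle: int
    rng: np.random.Generator
    consumed_last_cycle: float = 0.0

    @property
    def population_size(self) -> int:
        return len(self.locations)

    def automata(self) -> list[Automaton]:
        return [Automaton(int(l), float(e)) for l, e in zip(self.locations, self.energies)]

    def histogram(self) -> np.ndarray:
        return np.bincount(self.locations, minlength=self.grid.n_points).astype(float)


def init_state(
    grid: TraitGrid,
    resource: ResourceProfile,
    founders: list[tuple[int, int]],
    params: CAParams,
    seed: int,
) -> CAState:
    """Create a state with ``count`` founders of energy ``initial_energy`` at each location."""
    locs: list[int] = []
    for loc, count in founders:
        if not grid.contains(loc):
            raise ConfigurationError(f"founder location {loc} outside grid")
        locs.extend([grid.index_of(loc)] * count)
    return CAState(
        grid=grid,
        base_resource=resource,
        remaining=resource.capacity.copy(),
        locations=np.array(locs, dtype=np.int64),
        energies=np.full(len(locs), params.initial_energy, dtype=float),
        cycle=0,
        rng=np.random.default_rng(seed),
    )


def box_muller(rng: np.random.Generator, n: int) -> np.ndarray:
    """n standard normal variates via the Box-Muller transform."""
    if n == 0:
        return np.empty(0)
    pairs = (n + 1) // 2
    u1 = 1.0 - rng.random(pairs)  # in (0, 1], keeps the log finite
    u2 = rng.random(pairs)
    radius = np.sqrt(-2.0 * np.log(u1))
    z = np.empty(2 * pairs)
    z[0::2] = radius * np.cos(2.0 * np.pi * u2)
    z[1::2] = radius * np.sin(2.0 * np.pi * u2)
    return z[:n]


def draw_feed_location(
    loc: int, sigma: float, rng: np.random.Generator, n_points: int | None = None
) -> int:
    """Feeding target round(loc + sigma·z); OUT_OF_RANGE if it misses the grid.

    ``n_points`` bounds the valid index range [0, n_points); pass None to get
    the raw (unchecked) candidate.
    """
    if sigma == 0:
        cand = loc
    else:
        z = box_muller(rng, 1)[0]
        cand = int(np.rint(loc + sigma * z))
    if n_points is not None and not 0 <= cand < n_points:
        return OUT_OF_RANGE
    return cand


def spawn_offspring(parent_loc: int, params: CAParams, rng: np.random.Generator, n_points: int) -> int:
    """Offspring location: the parent's, displaced by round(mutability·z), clipped to the grid."""
    if params.mutability == 0:
        return parent_loc
    z = box_muller(rng, 1)[0]
    child = int(np.rint(parent_loc + params.mutability * z))
    return min(max(child, 0), n_points - 1)


#: step_automaton event labels
SURVIVED, DIED, REPRODUCED = "SURVIVED", "DIED", "REPRODUCED"


def step_automaton(a: Automaton, state: CAState, params: CAParams) -> tuple[str, Automaton | None]:
    """Process one automaton mid-cycle; returns (event, child-or-None).

    Mutates the automaton, the state's remaining-resource array, and the RNG.
    Scalar reference used by the sequential cycle path and in tests; the
    vectorized ``run_cycle`` is exactly equivalent.
    """
    n_points = state.grid.n_points
    a.energy -= params.maintenance_fraction * params.consume_unit
    if params.death_prob > 0 and state.rng.random() < params.death_prob:
        return DIED, None
    cand = draw_feed_location(a.location, params.sigma, state.rng, n_points)
    if cand != OUT_OF_RANGE and state.remaining[cand] >= params.consume_unit:
        state.remaining[cand] -= params.consume_unit
        a.energy += params.consume_unit
    if a.energy <= 0:
        return DIED, None
    if a.energy > params.repro_threshold:
        child_loc = spawn_offspring(a.location, params, state.rng, n_points)
        if params.offspring_energy == "deduct":
            a.energy -= params.initial_energy
        return REPRODUCED, Automaton(child_loc, params.initial_energy)
    return SURVIVED, None


def _allocate_feeds(
    candidates: np.ndarray, remaining: np.ndarray, consume_unit: float
) -> np.ndarray:
    """First-come-first-served feeding in processing order (vectorized).

    ``candidates`` holds per-automaton target cells in processing order (-1
    for out-of-range draws).  Each cell c can serve floor(remaining[c]/unit)
    feeds; the earliest-processed automata targeting c succeed.  Returns a
    boolean success mask and depletes ``remaining`` in place.
    """
    n = len(candidates)
    success = np.zeros(n, dtype=bool)
    valid = np.flatnonzero(candidates >= 0)
    if len(valid) == 0:
        return success
    cand = candidates[valid]
    capacity = np.floor(remaining / consume_unit).astype(np.int64)
    order = np.argsort(cand, kind="stable")  # groups by cell, keeps processing order
    sorted_cand = cand[order]
    # rank of each request within its cell's queue
    group_start = np.flatnonzero(np.r_[True, sorted_cand[1:] != sorted_cand[:-1]])
    ranks = np.arange(len(sorted_cand)) - np.repeat(group_start, np.diff(np.r_[group_start, len(sorted_cand)]))
    ok = ranks < capacity[sorted_cand]
    success[valid[order[ok]]] = True
    served = np.bincount(sorted_cand[ok], minlength=len(remaining))
    remaining -= served * consume_unit
    return success


def run_cycle(state: CAState, params: CAParams, sequential: bool = False) -> CAState:
    """Advance the whole population through one cycle.

    Resets the resource, shuffles the processing order, processes every
    automaton once, appends children (who first act next cycle), removes the
    dead, and increments the cycle counter.  The vectorized default and the
    ``sequential`` verification path consume the identical random-variate
    stream and produce bit-identical states.
    """
    if state.population_size > params.max_population:
        raise RuntimeError(
            f"population {state.population_size} exceeds max_population "
            f"{params.max_population} at cycle {state.cycle}; runaway configuration"
        )
    rng = state.rng
    n = state.population_size
    remaining = state.base_resource.capacity.copy()
    if n == 0:
        state.remaining = remaining
        state.cycle += 1
        state.consumed_last_cycle = 0.0
        return state

    perm = rng.permutation(n)
    locs = state.locations[perm]
    energies = state.energies[perm] - params.maintenance_fraction * params.consume_unit

    # Pre-draw all per-automaton variates in processing order; both execution
    # paths below consume these same arrays.
    if params.death_prob > 0:
        random_death = rng.random(n) < params.death_prob
    else:
        random_death = np.zeros(n, dtype=bool)
    alive = ~random_death
    n_alive = int(alive.sum())
    if params.sigma > 0:
        z = box_muller(rng, n_alive)
        cand_f = np.rint(locs[alive] + params.sigma * z)
    else:
        cand_f = locs[alive].astype(float)
    candidates = np.where(
        (cand_f >= 0) & (cand_f < state.grid.n_points), cand_f, -1
    ).astype(np.int64)

    if sequential:
        success = np.zeros(n_alive, dtype=bool)
        for i, c in enumerate(candidates):
            if c >= 0 and remaining[c] >= params.consume_unit:
                remaining[c] -= params.consume_unit
                success[i] = True
    else:
        success = _allocate_feeds(candidates, remaining, params.consume_unit)

    e_alive = energies[alive]
    e_alive[success] += params.consume_unit
    survived = e_alive > 0
    locs_s = locs[alive][survived]
    e_s = e_alive[survived]

    reproducing = e_s > params.repro_threshold
    n_repro = int(reproducing.sum())
    if params.mutability > 0 and n_repro:
        zc = box_muller(rng, n_repro)
        child_locs = np.rint(locs_s[reproducing] + params.mutability * zc)
        child_locs = np.clip(child_locs, 0, state.grid.n_points - 1).astype(np.int64)
    else:
        child_locs = locs_s[reproducing].copy()
    if params.offspring_energy == "deduct":
        e_s[reproducing] -= params.initial_energy

    state.locations = np.concatenate([locs_s, child_locs])
    state.energies = np.concatenate([e_s, np.full(n_repro, params.initial_energy)])
    state.remaining = remaining
    state.consumed_last_cycle = float(
        np.sum(state.base_resource.capacity - remaining) * state.grid.spacing
    )
    state.cycle += 1
    return state


def run(
    state: CAState,
    params: CAParams,
    n_cycles: int,
    snapshot_every: int = 50,
) -> TimeSeries:
    """Run the automata for ``n_cycles``, recording location histograms.

    Terminates early (status "extinct") if the population dies out.
    """
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    grid = state.grid
    snaps = [Snapshot(float(state.cycle), state.histogram(), _ca_stats(state))]
    status = "ok"
    for _ in range(n_cycles):
        run_cycle(state, params)
        if state.cycle % snapshot_every == 0 or state.population_size == 0:
            snaps.append(Snapshot(float(state.cycle), state.histogram(), _ca_stats(state)))
        if state.population_size == 0:
            status = "extinct"
            break
    if snaps[-1].time != state.cycle:
        snaps.append(Snapshot(float(state.cycle), state.histogram(), _ca_stats(state)))
    return TimeSeries(grid=grid, snapshots=snaps, engine="ca", status=status,
                      meta={"sigma": params.sigma, "mutability": params.mutability,
                            "n_cycles": n_cycles})


def _ca_stats(state: CAState) -> dict:
    hist = state.histogram()
    stats: dict = {"iteration": state.cycle, "total": float(hist.sum())}
    if hist.sum() > 0:
        dist = popstats.TraitDistribution(state.grid, hist)
        stats["sd"] = popstats.trait_sd(dist)
        stats["mode_count"] = popstats.count_modes(dist)
        stats["consumed_fraction"] = popstats.consumed_fraction(state, state.base_resource)
    else:
        stats.update({"sd": np.nan, "mode_count": 0, "consumed_fraction": 0.0})
    return stats
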