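"""Snapshot time series shared by both simulation engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_space import TraitGrid

__all__ = ["Snapshot", "TimeSeries"]


@dataclass(frozen=True)
class Snapshot:
    """Population state at one recorded time.

    ``mass`` is the population mass per grid location: density × spacing for
    the mean-field engine, automaton counts for the cellular automata.
    ``stats`` carries per-snapshot summaries (sd, mode_count, total,
    consumed_fraction).
    """

    time: float
    mass: np.ndarray = field(repr=False)
    stats: dict = field(default_factory=dict)


@dataclass
class TimeSeries:
    grid: TraitGrid
    snapshots: list[Snapshot]
    engine: str = ""
    status: str = "ok"  # "ok" or "extinct"
    meta: dict = field(default_factory=dict)

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def stat_trajectory(self, key: str) -> np.ndarray:
        return np.array([s.stats.get(key, np.nan) for s in self.snapshots])

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy table: one row per (time, location)."""
        locs = self.grid.locations
        frames = [
            pd.DataFrame({"time": snap.time, "location": locs, "mass": snap.mass})
            for snap in self.snapshots
        ]
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for snap in self.snapshots:
            row = {"time": snap.time}
            row.update(snap.stats)
            rows.append(row)
        return pd.DataFrame(rows)
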