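"""Serialization of runs (tidy CSV snapshots + JSON summaries) and test fixtures."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .popstats import TraitDistribution
from .timeseries import Snapshot, TimeSeries
from .trait_space import DegeneracyKernel, ResourceProfile, TraitGrid

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_profile_csv",
    "write_kernel_csv",
    "make_fixture",
]


def write_profile_csv(profile: ResourceProfile, path: str | Path) -> None:
    """Resource profile as a two-column CSV (location, value)."""
    pd.DataFrame({"location": profile.grid.locations, "value": profile.capacity}).to_csv(
        path, index=False
    )


def write_kernel_csv(kernel: DegeneracyKernel, path: str | Path) -> None:
    """Kernel weights as a two-column CSV (location = offset, value = weight)."""
    pd.DataFrame({"location": kernel.offsets, "value": kernel.weights}).to_csv(path, index=False)


def write_timeseries(ts: TimeSeries, outdir: str | Path, config: dict | None = None) -> dict:
    """Write a run directory: snapshots.csv, summary.json, optional config.yaml.

    snapshots.csv is long/tidy (time, location, mass) with stable column
    order; summary.json carries per-snapshot statistics plus run status
    ("extinct" if the population died out).  Returns the paths written.
    """
    if not ts.snapshots:
        raise ValueError("cannot write an empty time series")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    snap_path = outdir / "snapshots.csv"
    ts.to_frame().to_csv(snap_path, index=False)
    paths["snapshots"] = snap_path

    summary = {
        "engine": ts.engine,
        "status": ts.status,
        "meta": ts.meta,
        "grid": {"lower": ts.grid.lower, "upper": ts.grid.upper, "spacing": ts.grid.spacing},
        "snapshots": [
            {"time": snap.time, **{k: _jsonable(v) for k, v in snap.stats.items()}}
            for snap in ts.snapshots
        ],
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    paths["summary"] = summary_path

    if config is not None:
        config_path = outdir / "config.yaml"
        config_path.write_text(yaml.safe_dump(config, sort_keys=False))
        paths["config"] = config_path
    return paths


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v


def read_timeseries(outdir: str | Path) -> TimeSeries:
    """Reconstruct a TimeSeries from a run directory written by write_timeseries."""
    outdir = Path(outdir)
    summary = json.loads((outdir / "summary.json").read_text())
    g = summary["grid"]
    grid = TraitGrid(lower=g["lower"], upper=g["upper"], spacing=g["spacing"])
    table = pd.read_csv(outdir / "snapshots.csv", float_precision="round_trip")
    stats_by_time = {s["time"]: {k: v for k, v in s.items() if k != "time"} for s in summary["snapshots"]}
    snaps = []
    for t, group in table.groupby("time", sort=True):
        mass = group.sort_values("location")["mass"].to_numpy()
        snaps.append(Snapshot(float(t), mass, stats_by_time.get(float(t), {})))
    return TimeSeries(
        grid=grid,
        snapshots=snaps,
        engine=summary.get("engine", ""),
        status=summary.get("status", "ok"),
        meta=summary.get("meta", {}),
    )


def make_fixture(kind: str, grid: TraitGrid, seed: int = 0) -> TraitDistribution:
    """Deterministic toy trait distributions for tests.

    kinds: "bumps" (two separated Gaussians), "uniform", "point" (all mass at
    the midpoint), "random" (seeded positive noise).
    """
    locs = grid.locations
    n = grid.n_points
    if kind == "bumps":
        c1 = grid.lower + 0.25 * grid.extent
        c2 = grid.lower + 0.75 * grid.extent
        w = max(grid.extent / 20.0, grid.spacing)
        mass = np.exp(-((locs - c1) ** 2) / (2 * w**2)) + np.exp(-((locs - c2) ** 2) / (2 * w**2))
    elif kind == "uniform":
        mass = np.ones(n)
    elif kind == "point":
        mass = np.zeros(n)
        mass[n // 2] = 1.0
    elif kind == "random":
        mass = np.random.default_rng(seed).random(n) + 1e-3
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return TraitDistribution(grid, mass)
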