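"""Run configuration: validated YAML/JSON configs with defaults for either engine."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .automata import CAParams
from .meanfield import MeanfieldConfig
from .trait_space import (
    ConfigurationError,
    ResourceSchedule,
    TraitGrid,
    make_grid,
    rectangular_resource,
    widening_schedule,
)

__all__ = ["RunConfig", "load_config"]

_GRID_KEYS = {"lower", "upper", "spacing"}
_RESOURCE_KEYS = {"lo", "hi", "height", "widen_fraction_per_side", "widen_t_switch"}
_TOP_KEYS = {
    "engine",
    "sigma",
    "grid",
    "resource",
    "meanfield",
    "ca",
    "n_steps",
    "n_cycles",
    "snapshot_every",
    "seed",
    "outdir",
}


@dataclass
class RunConfig:
    """Validated configuration for a single simulation run.

    ``engine`` selects the mean-field or cellular-automata engine; the grid,
    the (optionally widening) rectangular resource, the degeneracy sigma and
    the engine parameters are filled with the package defaults where the
    config file is silent.  A seed is required for the stochastic engine.
    """

    engine: str
    sigma: float
    grid: TraitGrid
    schedule: ResourceSchedule
    meanfield: MeanfieldConfig = field(default_factory=MeanfieldConfig)
    ca: CAParams | None = None
    n_cycles: int = 2000
    snapshot_every: int = 100
    seed: int | None = None
    outdir: str | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in ("meanfield", "ca"):
            raise ConfigurationError(f"engine must be 'meanfield' or 'ca', got {self.engine!r}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be non-negative, got {self.sigma}")
        if self.engine == "ca" and self.seed is None:
            raise ConfigurationError("engine 'ca' requires a seed")


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {where}")


def _build_schedule(grid: TraitGrid, spec: dict, engine: str) -> ResourceSchedule:
    _reject_unknown(spec, _RESOURCE_KEYS, "resource")
    height = float(spec.get("height", 100.0 if engine == "meanfield" else 10.0))
    lo = float(spec.get("lo", grid.lower))
    hi = float(spec.get("hi", grid.upper))
    outer = rectangular_resource(grid, lo, hi, height)
    if "widen_fraction_per_side" in spec:
        if "widen_t_switch" not in spec:
            raise ConfigurationError("widen_fraction_per_side requires widen_t_switch")
        return widening_schedule(
            outer, float(spec["widen_fraction_per_side"]), float(spec["widen_t_switch"])
        )
    return ResourceSchedule.constant(outer)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration (JSON is valid YAML).

    Unknown keys are rejected with a message naming the offending key;
    omitted keys get the package defaults (grid [0, 299], r = 1, dt = 0.025,
    rectangular resource over the full grid).
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping, got {type(data).__name__}")
    _reject_unknown(data, _TOP_KEYS, str(path))
    if "engine" not in data:
        raise ConfigurationError("config is missing required key 'engine'")
    engine = data["engine"]
    if engine not in ("meanfield", "ca"):
        raise ConfigurationError(f"engine must be 'meanfield' or 'ca', got {engine!r}")

    grid_spec = dict(data.get("grid", {}))
    _reject_unknown(grid_spec, _GRID_KEYS, "grid")
    grid = make_grid(
        grid_spec.get("lower", 0), grid_spec.get("upper", 299), grid_spec.get("spacing", 1.0)
    )
    schedule = _build_schedule(grid, dict(data.get("resource", {})), engine)
    sigma = float(data.get("sigma", 0.0))
    if sigma < 0:
        raise ConfigurationError(f"sigma must be non-negative, got {sigma}")

    snapshot_every = int(data.get("snapshot_every", 100))
    mf_spec = dict(data.get("meanfield", {}))
    if "n_steps" in data:
        mf_spec.setdefault("n_steps", int(data["n_steps"]))
    mf_spec.setdefault("snapshot_every", snapshot_every)
    try:
        mf_cfg = MeanfieldConfig(**mf_spec)
    except TypeError as exc:
        raise ConfigurationError(f"bad meanfield config: {exc}") from exc

    ca_params = None
    if engine == "ca":
        ca_spec = dict(data.get("ca", {}))
        ca_spec.setdefault("sigma", sigma)
        try:
            ca_params = CAParams(**ca_spec)
        except TypeError as exc:
            raise ConfigurationError(f"bad ca config: {exc}") from exc

    return RunConfig(
        engine=engine,
        sigma=sigma,
        grid=grid,
        schedule=schedule,
        meanfield=mf_cfg,
        ca=ca_params,
        n_cycles=int(data.get("n_cycles", 2000)),
        snapshot_every=snapshot_every,
        seed=data.get("seed"),
        outdir=data.get("outdir"),
        raw=data,
    )
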