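"""Scripted reproductions of the model's headline result sets.

Each experiment runs the engines under the study conditions (rectangular
resource on the 300-point trait axis), classifies the resulting dynamics as
divergent (≥ 2 modes) or static (1 mode, shrinking SD), and returns a report
dict with the measured quantities and named PASS/FAIL checks.  Reports are
plain data; ``degensim.io.write_timeseries`` persists the underlying
snapshot tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import automata as ca
from . import meanfield as mf
from . import popstats
from .io import write_timeseries
from .timeseries import TimeSeries
from .trait_space import (
    ResourceSchedule,
    gaussian_kernel,
    make_grid,
    rectangular_resource,
    widening_schedule,
)

__all__ = [
    "exp_zero_degeneracy",
    "exp_divergence_vs_stasis",
    "exp_sigma_scan",
    "exp_nonlocal_widening",
    "exp_founder_mutability",
    "exp_initial_condition_robustness",
    "EXPERIMENTS",
]

#: Study conditions shared by all experiments.
GRID = make_grid(0, 299, 1.0)
MF_HEIGHT = 100.0  # mean-field carrying capacity per cell (free scale)
CA_HEIGHT = 10.0  # CA resource units per cell per cycle
MF_STEPS = 8000  # "late iterations" for mean-field runs (dt = 0.025)
CA_CYCLES = 2000  # "late cycles" for CA runs
NARROW_SIGMA = 60.0
BROAD_SIGMA = 120.0


def classify(ts: TimeSeries) -> str:
    """Regime of a finished run: "divergent" (≥ 2 modes) or "static"."""
    return "divergent" if ts.final.stats["mode_count"] >= 2 else "static"


def run_meanfield(
    sigma: float,
    schedule: ResourceSchedule | None = None,
    N0: mf.PopulationDensity | None = None,
    n_steps: int = MF_STEPS,
    snapshot_every: int = 200,
    **cfg_kwargs,
) -> TimeSeries:
    """One mean-field run under the study conditions (rectangular K unless given)."""
    if schedule is None:
        schedule = ResourceSchedule.constant(rectangular_resource(GRID, 0, 299, MF_HEIGHT))
    if N0 is None:
        N0 = mf.default_initial_density(schedule.lookup(0.0))
    cfg = mf.MeanfieldConfig(n_steps=n_steps, snapshot_every=snapshot_every, **cfg_kwargs)
    kernel = gaussian_kernel(sigma, schedule.grid)
    return mf.integrate(N0, schedule, kernel, cfg)


def run_ca(
    sigma: float,
    seed: int,
    founders: list[tuple[int, int]] | None = None,
    n_cycles: int = CA_CYCLES,
    snapshot_every: int = 100,
    **param_kwargs,
) -> TimeSeries:
    """One CA run under the study conditions (rectangular resource, full-range founders)."""
    resource = rectangular_resource(GRID, 0, 299, CA_HEIGHT)
    if founders is None:
        founders = [(i, 1) for i in range(GRID.n_points)]
    params = ca.CAParams(sigma=sigma, **param_kwargs)
    state = ca.init_state(GRID, resource, founders, params, seed=seed)
    return ca.run(state, params, n_cycles=n_cycles, snapshot_every=snapshot_every)


def _finish(report: dict, outdir: str | Path | None, runs: dict[str, TimeSeries]) -> dict:
    report["passed"] = all(report["checks"].values())
    if outdir is not None:
        outdir = Path(outdir)
        for name, ts in runs.items():
            write_timeseries(ts, outdir / name)
        import json

        (Path(outdir) / "report.json").write_text(json.dumps(_plain(report), indent=1))
    return report


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def exp_zero_degeneracy(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Validation at sigma = 0: every site follows an independent logistic curve.

    Mean-field trajectories are compared to the closed-form logistic
    solution; CA per-site totals stabilize with no cross-site coupling
    (per-site outcomes are uncorrelated across seeds).
    """
    K = rectangular_resource(GRID, 0, 299, MF_HEIGHT)
    N0 = mf.PopulationDensity(GRID, np.ones(GRID.n_points))
    cfg = mf.MeanfieldConfig(n_steps=400, snapshot_every=400)  # t = 10
    ts = mf.integrate(N0, ResourceSchedule.constant(K), gaussian_kernel(0.0, GRID), cfg)
    t = ts.final.time
    closed = MF_HEIGHT / (1.0 + (MF_HEIGHT / 1.0 - 1.0) * np.exp(-cfg.r * t))
    max_rel = float(np.max(np.abs(ts.final.mass - closed)) / closed)

    # CA: site totals across independent seeds are uncorrelated (sigma = 0
    # decouples sites; each holds an independent birth-death process).
    totals = []
    for s in range(3):
        ts_ca = run_ca(0.0, seed=seed + s, n_cycles=400, snapshot_every=400)
        totals.append(ts_ca.final.mass)
    cors = [
        float(np.corrcoef(totals[i], totals[j])[0, 1])
        for i in range(3)
        for j in range(i + 1, 3)
    ]
    report = {
        "meanfield_max_rel_dev": max_rel,
        "ca_site_mean": float(np.mean(totals[-1])),
        "ca_cross_seed_correlations": cors,
        "checks": {
            "meanfield_matches_logistic": max_rel < 1e-4,
            "ca_sites_uncorrelated": all(abs(c) < 0.25 for c in cors),
        },
    }
    return _finish(report, outdir, {"meanfield_sigma0": ts})


def exp_divergence_vs_stasis(
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4), outdir: str | Path | None = None
) -> dict:
    """Narrow degeneracy diverges, broad degeneracy freezes — both engines.

    4 mean-field + 2 × len(seeds) CA runs with rectangular resource and
    population over the full axis; reports per-run regime, final SD, and
    engine agreement.
    """
    runs: dict[str, TimeSeries] = {}
    report: dict = {"meanfield": {}, "ca": {}, "checks": {}}
    for sigma in (NARROW_SIGMA, BROAD_SIGMA):
        ts = run_meanfield(sigma)
        runs[f"meanfield_sigma{sigma:g}"] = ts
        sds = ts.stat_trajectory("sd")
        last_q = sds[3 * len(sds) // 4 :]
        report["meanfield"][f"sigma{sigma:g}"] = {
            "regime": classify(ts),
            "final_sd": float(sds[-1]),
            "final_modes": int(ts.final.stats["mode_count"]),
            "sd_decreasing_final_quarter": bool(np.all(np.diff(last_q) < 0)),
        }
        ca_regimes = []
        for s in seeds:
            ts_ca = run_ca(sigma, seed=s)
            runs[f"ca_sigma{sigma:g}_seed{s}"] = ts_ca
            ca_regimes.append(classify(ts_ca))
        report["ca"][f"sigma{sigma:g}"] = {
            "regimes": ca_regimes,
            "final_sd": float(ts_ca.final.stats["sd"]),
        }
    mfr = report["meanfield"]
    car = report["ca"]
    report["checks"] = {
        "meanfield_narrow_divergent": mfr[f"sigma{NARROW_SIGMA:g}"]["regime"] == "divergent",
        "meanfield_broad_static": mfr[f"sigma{BROAD_SIGMA:g}"]["regime"] == "static",
        "ca_narrow_divergent_all_seeds": all(
            r == "divergent" for r in car[f"sigma{NARROW_SIGMA:g}"]["regimes"]
        ),
        "ca_broad_static_all_seeds": all(
            r == "static" for r in car[f"sigma{BROAD_SIGMA:g}"]["regimes"]
        ),
    }
    return _finish(report, outdir, runs)


def exp_sigma_scan(
    sigmas=None,
    at_iterations: tuple[int, ...] = (2000, 4000, 6000, 8000),
    outdir: str | Path | None = None,
) -> dict:
    """SD-versus-sigma scan over the stabilizing regime (default sigma 100..150).

    Reports the stabilizing-regime argmin of late-time SD, a U-shape check,
    and the decoupling of homogenization from resource exploitation: the
    consumed fraction plateaus while SD keeps falling.
    """
    if sigmas is None:
        sigmas = list(range(100, 151))
    n_steps = max(at_iterations)
    snap = int(np.gcd.reduce(np.array(at_iterations, dtype=np.int64)))
    scan = popstats.sd_vs_sigma_scan(
        [float(s) for s in sigmas],
        lambda sigma: run_meanfield(sigma, n_steps=n_steps, snapshot_every=snap),
        at_iterations,
    )
    latest = scan.table[scan.table["iteration"] == max(at_iterations)].reset_index(drop=True)
    earliest = scan.table[scan.table["iteration"] == min(at_iterations)].reset_index(drop=True)
    stab = latest[latest["mode_count"] == 1]
    sd_vals = stab["sd"].to_numpy()
    i_min = int(np.argmin(sd_vals))
    u_shaped = 0 < i_min < len(sd_vals) - 1
    sd_still_falling = bool(np.all(latest["sd"].to_numpy() < earliest["sd"].to_numpy()))

    # decoupling at the argmin sigma: consumption saturates in the first half
    # of the run while SD keeps decreasing afterwards
    ts = run_meanfield(scan.argmin_sigma, n_steps=n_steps, snapshot_every=snap // 4)
    cons = ts.stat_trajectory("consumed_fraction")
    sds = ts.stat_trajectory("sd")
    half = len(cons) // 2
    plateau_early = bool(np.all(cons[half:] > 0.99 * cons[-1]))
    sd_falls_late = bool(np.all(np.diff(sds[half:]) < 0))

    report = {
        "argmin_sigma": scan.argmin_sigma,
        "boundary_sigma": scan.boundary_sigma,
        "table": scan.table.to_dict(orient="list"),
        "checks": {
            "u_shaped_sd_curve": u_shaped,
            "sd_latest_below_earliest_everywhere": sd_still_falling,
            "consumption_saturated_before_final_half": plateau_early,
            "sd_still_falling_after_plateau": sd_falls_late,
        },
    }
    return _finish(report, outdir, {})


def exp_nonlocal_widening(
    sigma: float = 55.0,
    n_steps: int = 3000,
    fraction_per_side: float = 1.0 / 6.0,
    outdir: str | Path | None = None,
) -> dict:
    """A small edge-only widening of the resource flips stasis to divergence.

    Mean-field, dt = 0.025; the resource is the inner rectangle for the
    first half of the run, then widens to the full axis.  The population's
    response is central: the new inter-mode minimum appears inside the old
    (inner) support, not at the edges where the environment changed.
    """
    outer = rectangular_resource(GRID, 0, 299, MF_HEIGHT)
    dt = 0.025
    schedule = widening_schedule(outer, fraction_per_side, t_switch=(n_steps // 2) * dt)
    inner = schedule.segments[0][1]
    N0 = mf.default_initial_density(inner)
    ts = run_meanfield(sigma, schedule=schedule, N0=N0, n_steps=n_steps, snapshot_every=100, dt=dt)

    switch_iter = n_steps // 2
    pre = [s for s in ts.snapshots if 0 < s.stats["iteration"] <= switch_iter]
    pre_sds = np.array([s.stats["sd"] for s in pre])
    pre_modes = [s.stats["mode_count"] for s in pre]
    final_dist = popstats.TraitDistribution(GRID, ts.final.mass)
    peaks, valleys = popstats.find_modes(final_dist)
    inner_lo, inner_hi = inner.support_bounds()
    valley_central = len(valleys) > 0 and all(inner_lo <= v <= inner_hi for v in valleys)

    # control: the inner resource alone, never widened -> no transition
    control = run_meanfield(
        sigma,
        schedule=ResourceSchedule.constant(inner),
        N0=N0,
        n_steps=n_steps,
        snapshot_every=n_steps // 2,
        dt=dt,
    )

    report = {
        "pre_switch_final_sd": float(pre_sds[-1]),
        "post_switch_final_modes": int(ts.final.stats["mode_count"]),
        "final_peaks": peaks.tolist(),
        "final_valleys": valleys.tolist(),
        "inner_support": [inner_lo, inner_hi],
        "control_final_modes": int(control.final.stats["mode_count"]),
        "checks": {
            "pre_switch_static_and_homogenizing": all(m == 1 for m in pre_modes)
            and bool(np.all(np.diff(pre_sds) < 0)),
            "post_switch_divergent": ts.final.stats["mode_count"] >= 2,
            "new_minimum_inside_inner_support": valley_central,
            "no_transition_without_widening": control.final.stats["mode_count"] == 1,
        },
    }
    return _finish(report, outdir, {"widening": ts, "control": control})


def exp_founder_mutability(
    mutabilities: tuple[float, ...] = (2.0, 5.0, 15.0, 30.0),
    sigmas: tuple[float, ...] = (NARROW_SIGMA, BROAD_SIGMA),
    washout_factor: float = 2.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Heritable trait variability: single mid-range founder, mutability sweep.

    Regimes survive mutability well below sigma; mutability ≫ sigma (the
    washout runs at ``washout_factor × sigma``) overwhelms degeneracy and
    spreads the population toward the uniform distribution
    (SD → √((n²−1)/12) ≈ 86.6 on 300 locations).
    """
    uniform_sd = float(np.sqrt((GRID.n_points**2 - 1) / 12.0))
    founders = [(150, 1)]
    runs: dict[str, TimeSeries] = {}
    cells: dict = {}
    for sigma in sigmas:
        for mut in mutabilities:
            ts = run_ca(sigma, seed=seed, founders=founders, mutability=mut)
            runs[f"sigma{sigma:g}_mut{mut:g}"] = ts
            cells[(sigma, mut)] = {
                "regime": classify(ts),
                "final_sd": float(ts.final.stats["sd"]),
                "population": float(ts.final.stats["total"]),
            }
        mut_big = washout_factor * sigma
        ts = run_ca(sigma, seed=seed, founders=founders, mutability=mut_big)
        runs[f"sigma{sigma:g}_washout"] = ts
        cells[(sigma, "washout")] = {
            "mutability": mut_big,
            "final_sd": float(ts.final.stats["sd"]),
            "rel_dev_from_uniform_sd": abs(ts.final.stats["sd"] - uniform_sd) / uniform_sd,
        }
    low_muts = [m for m in mutabilities if m <= 15]
    report = {
        "uniform_sd": uniform_sd,
        "cells": {f"sigma{s:g}_mut{m}": v for (s, m), v in cells.items()},
        "checks": {
            "narrow_divergent_up_to_mut15": all(
                cells[(NARROW_SIGMA, m)]["regime"] == "divergent" for m in low_muts
            ),
            "broad_static_up_to_mut15": all(
                cells[(BROAD_SIGMA, m)]["regime"] == "static" for m in low_muts
            ),
            "washout_sd_near_uniform": all(
                cells[(s, "washout")]["rel_dev_from_uniform_sd"] < 0.2 for s in sigmas
            ),
        },
    }
    return _finish(report, outdir, runs)


def exp_initial_condition_robustness(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Regimes are insensitive to the initial distribution and to random death.

    Mean-field at broad sigma from rectangular vs. seeded-random N0 (same
    regime; SD trajectories agree to within a fraction of a trait unit, the
    kernel-smoothed envelopes coincide while grid-scale roughness of the
    random start persists as neutral modes); narrow sigma from asymmetric
    random N0 still branches; CA regimes are unchanged by a 1% per-cycle
    random death.
    """
    rng = np.random.default_rng(seed)
    runs: dict[str, TimeSeries] = {}
    K = rectangular_resource(GRID, 0, 299, MF_HEIGHT)
    ts_rect = run_meanfield(BROAD_SIGMA)
    N_rand = mf.PopulationDensity(GRID, rng.random(GRID.n_points) * 2.0)
    ts_rand = run_meanfield(BROAD_SIGMA, N0=N_rand)
    runs["broad_rect"], runs["broad_random"] = ts_rect, ts_rand
    sd_a, sd_b = ts_rect.final.stats["sd"], ts_rand.final.stats["sd"]

    N_asym = mf.PopulationDensity(
        GRID, rng.random(GRID.n_points) * (0.5 + np.linspace(0, 1, GRID.n_points))
    )
    ts_asym = run_meanfield(NARROW_SIGMA, N0=N_asym)
    runs["narrow_asymmetric_random"] = ts_asym

    ca_same = {}
    for sigma in (NARROW_SIGMA, BROAD_SIGMA):
        base = classify(run_ca(sigma, seed=seed, n_cycles=1500))
        perturbed = classify(run_ca(sigma, seed=seed, n_cycles=1500, death_prob=0.01))
        ca_same[f"sigma{sigma:g}"] = {"no_death": base, "death_prob_0.01": perturbed}

    report = {
        "broad_sd_rect": float(sd_a),
        "broad_sd_random": float(sd_b),
        "broad_sd_abs_diff": float(abs(sd_a - sd_b)),
        "broad_sd_rel_diff": float(abs(sd_a - sd_b) / sd_a),
        "narrow_random_final_modes": int(ts_asym.final.stats["mode_count"]),
        "ca_random_death": ca_same,
        "checks": {
            "broad_same_regime": classify(ts_rect) == classify(ts_rand) == "static",
            "broad_sd_within_one_trait_unit": abs(sd_a - sd_b) < 1.0,
            "narrow_random_still_divergent": ts_asym.final.stats["mode_count"] >= 2,
            "ca_regimes_unchanged_by_random_death": all(
                v["no_death"] == v["death_prob_0.01"] for v in ca_same.values()
            ),
        },
    }
    return _finish(report, outdir, runs)


#: CLI experiment registry: name -> callable(outdir=...) -> report
EXPERIMENTS = {
    "zero-degeneracy": exp_zero_degeneracy,
    "fig5": exp_divergence_vs_stasis,
    "fig6": exp_sigma_scan,
    "fig7": exp_nonlocal_widening,
    "fig8": exp_founder_mutability,
    "init-robustness": exp_initial_condition_robustness,
}
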