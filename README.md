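# degensim

Simulation toolkit for **degeneracy-driven, non-local resource competition**
on a one-dimensional trait axis — a model in which the *same* competitive
mechanism produces either rapid evolutionary divergence (branching into
separated phenotypic modes with suppression of intermediates) or prolonged
stasis (a unimodal population whose trait homogeneity keeps increasing),
depending only on how specific resource consumption is.

It is written for theoretical ecologists and evolutionary modellers who want
a reproducible, scriptable implementation of both formulations of the model:
a deterministic mean-field equation and a stochastic individual-based engine.

## The model

Individuals are characterized by a single heritable trait value `s'` on a
discretized axis (default: integer locations 0..299). A resource with
carrying capacity `K(s)` lives on the same axis (default: rectangular,
uniform over the full range). Consumption is *degenerate*: an individual at
`s'` consumes resource at `s` with Gaussian weight

    f(s − s') = exp(−(s − s')² / 2σ²) / (σ√(2π)),

where σ is the **degeneracy range**. Kernel mass extending past the axis is
lost — consumption attempts outside the resource range are fruitless, which
penalizes peripheral phenotypes.

**Mean-field engine** (`degensim.meanfield`). The population density
`N(s', t)` obeys a non-local logistic equation: the demand on resource at
`s` is `D(s) = ∫ f(s − s'') N(s'') ds''`, each location's capacity is
partitioned among consumers in proportion to their share of demand, and

    dN(s')/dt = r N(s') (1 − 1/g(s')),   g(s') = ∫ K(s) f(s − s') / D(s) ds.

`g` is the per-capita capacity reachable from `s'`; `g ≡ 1` on the occupied
set at equilibrium, which forces `∫N = ∫K`. Integration is fixed-step
classical RK4 (default dt = 0.025). At σ = 0 every site decouples into an
independent logistic curve — the engine's validation limit.

**Cellular-automata engine** (`degensim.automata`). Individuals carry an
energy store. Each cycle the resource renews, the processing order is
reshuffled, and every automaton pays a constant cost of living, attempts to
feed at `round(s' + σz)` with `z` a Box-Muller standard normal draw (one
fixed unit per success), dies if its balance drops to ≤ 0, and
self-propagates when its balance exceeds a threshold. Offspring inherit the
parent's location, optionally displaced by a Gaussian *mutability* draw.

Narrow σ (well below the resource range) → branching; broad σ (comparable to
the range) → stasis with shrinking trait SD. Both engines agree on the
regime, and the homogenization continues long after the population has
saturated total carrying capacity — the dynamics are not driven by improved
resource exploitation.

## Worked example

```python
from degensim import gaussian_kernel, make_grid, rectangular_resource, ResourceSchedule
from degensim import meanfield as mf
from degensim.experiments import run_ca

grid = make_grid(0, 299, 1.0)
K = rectangular_resource(grid, 0, 299, 100.0)

for sigma in (60.0, 120.0):
    ts = mf.integrate(
        mf.default_initial_density(K),
        ResourceSchedule.constant(K),
        gaussian_kernel(sigma, grid),
        mf.MeanfieldConfig(n_steps=8000, snapshot_every=500),
    )
    s = ts.final.stats
    print(f"meanfield sigma={sigma:g}: modes={s['mode_count']} "
          f"sd={s['sd']:.2f} consumed={s['consumed_fraction']:.3f}")

ts = run_ca(120.0, seed=1)
s = ts.final.stats
print(f"ca        sigma=120: modes={s['mode_count']} sd={s['sd']:.2f} "
      f"population={s['total']:.0f}")
```

prints

```
meanfield sigma=60: modes=2 sd=68.13 consumed=1.000
meanfield sigma=120: modes=1 sd=12.35 consumed=1.000
ca        sigma=120: modes=1 sd=9.00 population=5790
```

At σ = 60 the mean-field population has split into two modes (trait SD stays
high because the modes sit far apart); at σ = 120 it is a single narrowing
peak (SD 12.35 and still falling), yet in both cases the population mass has
fully saturated the carrying capacity (`consumed = 1.000`). The stochastic
engine at σ = 120 independently reaches the same unimodal, homogenizing
state.

The scripted experiment suite (`degensim.experiments`, also available as
`degensim exp <name>` from the shell: `zero-degeneracy`, `fig5`, `fig6`,
`fig7`, `fig8`, `init-robustness`) reproduces the full result set: the
σ-scan of late-time SD, the widening-induced stasis→divergence transition,
single-founder colonies with heritable variability, and the stochastic
robustness checks.

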