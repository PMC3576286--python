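# Methods

## Model

A population lives on a one-dimensional trait axis `S`, discretized into
evenly spaced locations (default: 300 integer locations 0..299, spacing 1,
shared by both engines so their outputs are directly comparable). A resource
with carrying capacity `K(s)` occupies the same axis; all experiments use a
rectangular (uniform) `K` on a contiguous support. Consumption is
*degenerate*: an individual whose median trait value is `s'` consumes
resource at `s` with weight given by a normalized Gaussian kernel
`f(x) = exp(−x²/2σ²)/(σ√2π)` of standard deviation σ (the degeneracy range).
σ = 0 is the strictly specific limit (a discrete delta kernel).

Kernels are tabulated at grid offsets out to min(6σ, grid extent) and are
**not renormalized after truncation**: mass falling outside the axis is
lost. This is deliberate and load-bearing — peripheral individuals waste
part of their consumption range on locations holding no resource, which is
the mechanism that disadvantages the edges. Renormalizing per location would
erase it. The statement that `f` integrates to 1 over `S` is therefore an
approximation valid for σ much smaller than the axis; at σ comparable to the
axis width the deficit *is* the model's edge effect. (On a periodic test
ring, where nothing is lost, the truncated mass cancels identically between
demand and share, and a uniform state obeys the exact local logistic rate —
this is used as an oracle in the tests.)

## Mean-field engine

With density `N(s', t)`, demand on resource at `s` is the kernel sum
`D(s) = Σ f(s − s'') N(s'') Δs`. Capacity at `s` is split among consumers in
proportion to demand share, giving the per-capita reachable capacity

    g(s') = Σ_s K(s) f(s − s') / D(s) Δs

and the growth law `dN/dt = r N (1 − 1/g)`. The factor `N(s')` appearing in
the raw demand-partition form cancels algebraically against the outer
division; implementing the cancelled form is an identity, not an
approximation, and removes the 0/0 at empty sites.

Numerical choices:

- **Demand floor.** Resource at locations nobody demands must exert no
  force. Where `D(s) ≤ 10⁻¹² · max(N) · Δs` the contribution to `g` is
  zeroed (rather than floored-and-divided, which would fabricate enormous
  shares from numerically empty demand).
- **Starved sites.** Where `N > 0` but `g = 0` (occupied location with no
  reachable resource) the raw equation diverges to −∞; the implementation
  decays such sites at the finite rate `−r·N` (`decay_cap = 1`), the mildest
  choice that still guarantees local extinction.
- **Integration.** Classical fixed-step RK4, default dt = 0.025. Negative
  densities from overshoot are clipped to 0 after each committed step (not
  mid-stage), preserving non-negativity without touching smooth
  trajectories. Non-finite values abort with a diagnostic.
- **Operator form.** The production integrator applies the kernel as a dense
  symmetric Toeplitz matrix (one BLAS matrix–vector product per integral per
  stage); the documented `demand_field`/`share_integral` functions use
  direct convolution. Both paths agree to machine precision and both are
  checked against O(n²) double-loop references.
- **Defaults.** r = 1 (time is measured in units of 1/r), rectangular K
  height 100 per cell, initial density 0.01·K on the resource support. The
  dynamics are invariant to joint rescaling of K and N₀ (asserted as a
  property test), so these two amplitudes are free scales. Production runs
  default to 8000 steps (t = 200), by which the regime classification and
  the SD ordering across σ are stable; the widening experiment uses the
  3000-step protocol its result set specifies.

Two structural facts worth knowing. First, multiplying `g ≡ 1` on the
occupied set by `N`, summing, and swapping the order of summation forces
`Σ N Δs = Σ_{demanded} K Δs` at equilibrium: the consumed fraction saturates
at 1. Second, the equation constrains only kernel-smoothed functionals of
`N`; grid-scale (high-frequency) structure lies in the kernel's numerical
null space for broad σ and is neutrally stable. A cell-level random initial
density therefore keeps its roughness forever while its *envelope*,
summary statistics, and regime match the smooth-start solution. This is a
property of the equation, not an artifact: comparisons across initial
conditions are made on regimes and summary statistics (trait SD agrees to
within half a trait unit on a 300-unit axis), not pointwise.

## Cellular-automata engine

Individuals (automata) carry an integer location and a real-valued energy
store. Time is cyclical; the resource array resets to its base value every
cycle, and automata are processed once per cycle in a freshly shuffled
order. Per automaton and cycle:

1. a constant maintenance cost is deducted: `maintenance_fraction ×
   consume_unit` (default 0.5 × 1);
2. optional random death with probability `death_prob`;
3. one feeding attempt at `round(loc + σz)`, `z` a Box-Muller standard
   normal variate; the draw fails outside the grid or if less than one full
   unit remains at the target; a success transfers one unit to the store;
4. death if the balance is ≤ 0;
5. self-propagation if the balance exceeds `repro_threshold` (default 5):
   the child starts with `initial_energy` (default 1), deducted from the
   parent so no energy is created; a "copy" switch (parent keeps its store)
   exists for sensitivity runs. Children first act the following cycle, so
   lineage growth cannot depend on shuffle position. With mutability m > 0
   the child's location is displaced by `round(m·z)` and clipped to the
   grid (out-of-range phenotypes would starve deterministically anyway;
   clipping keeps the population finite without biasing the interior).

**Why a constant cost of living, not a multiplicative one.** A maintenance
rule of the form `energy ← energy·(1 − m)` keeps the balance strictly
positive forever, so the death-by-starvation rule can never fire, no
competitive exclusion occurs, and neither branching nor stasis develops
cleanly. The constant-cost reading — every automaton expends the same fixed
fraction of the standard consumption unit each cycle — makes starvation
reachable: an individual whose long-run feeding success rate falls below
`maintenance_fraction` dies. This threshold interpretation is also what
gives the engine its crisp selection gradient.

**Defaults and scales.** Base resource 10 units per cell per cycle on 300
cells and cost 0.5/cycle support a steady population of ≈ 6000 (total
resource / cost), i.e. O(10) individuals per cell, with a generation time of
O(10) cycles (a well-fed founder first reproduces on cycle 9: the balance
recursion e ← e + 0.5 from e = 1 crosses the threshold 5 at e = 5.5).
Production runs default to 2000 cycles, comfortably past the point where the
regime classification and SD trends have stabilized. A `max_population`
guard (10⁶) aborts runaway configurations.

The per-cycle update is implemented in vectorized form: all per-automaton
variates are pre-drawn in processing order, and since each success removes
one fixed unit, feeding resolves as first-come-first-served per cell. This
is *exactly* equivalent to the sequential pass (a sequential path is kept
and bit-identity between the two is asserted in the tests). Identical seeds
give bit-identical histories.

## Statistics and regime classification

- **Trait SD**: mass-weighted population standard deviation of location
  values (divisor = total mass); with unit masses this is the SD over
  individual trait values, so both engines use one formula.
- **Mode counting**: the mass profile (numerical dust below 10⁻¹² of the
  maximum zeroed) is smoothed with a Gaussian of bandwidth 5 trait units,
  zero-padded so boundary maxima count, and peaks with prominence above 5%
  of the global maximum are counted (`scipy.signal.find_peaks`). The
  regimes of interest are far from these thresholds — divergent runs show
  deep inter-mode gaps and static runs a single dominant peak — but the
  thresholds make the visual classification reproducible. "Divergent" means
  ≥ 2 modes; "static" means 1.
- **Consumed fraction**: population mass over total capacity (mean-field),
  or last-cycle consumption over the per-cycle budget (CA).
- **SD-vs-σ scan**: one mean-field run per σ, with SD and mode count
  recorded on an iteration ladder (default 2000/4000/6000/8000). The
  reported argmin is restricted to unimodal runs, mirroring the split
  between dichotomous and stabilizing dynamics. The minimum's location
  drifts slowly with the evaluation iteration (118 at 2000 steps, 122 at
  8000), which is why the experiment reports the whole ladder.

## What the experiments show (and their limits)

The experiment layer reruns the result set at desk scale: branching at
σ = 60 and stasis at σ = 120 in both engines; the U-shaped SD(σ) curve over
σ = 100..150 with its minimum at σ = 122 at the default ladder; saturation
of total consumption *before* homogenization stops (the decoupling that
shows the dynamics are not adaptively maximizing exploitation); the
stasis→divergence flip triggered by widening the resource by 1/6 of its
range per side at half-run, with the population's response appearing in the
middle of the axis rather than at the edges where the environment changed;
and single-founder colonies whose regimes survive mutability up to 15 but
wash out toward the uniform distribution (SD ≈ 86.6) at mutability ≫ σ
(the washout runs use mutability = 2σ).

Synthetic inputs are exactly the study conditions: rectangular resource and
rectangular (or seeded-random) initial populations on [0, 299]. What passing
these checks shows is internal: the two independent formulations agree on
regime behavior and obey the analytic limits (σ = 0 logistic, equilibrium
conservation, brute-force integral oracles). What they cannot show is
anything about real populations — the model is one-trait, asexual, with a
static rectangular resource, location-independent r and σ, and no cost of
degeneracy.

## Known limitations

- The CA constants (maintenance, unit, threshold, founder energy, per-cell
  resource) are this package's own calibration; only σ, mutability, the
  range [0, 299], and founder placement are fixed by the protocol. CA and
  mean-field amplitudes are therefore not comparable — engine agreement is
  asserted at the level of regime classification and SD trends.
- The mean-field SD argmin depends mildly on the evaluation iteration
  (±a few σ-units across the default ladder) because SD decays without
  settling; there is no true interior equilibrium to converge to.
- Fixed-step RK4 with post-step clipping is adequate for the default dt on
  these smooth fields but is not a stiff solver; pathological configs
  (huge r·dt) abort on non-finite values rather than adapting.
- For broad kernels the mean-field equation is blind to grid-scale
  structure (neutral modes); pointwise comparisons between runs started
  from rough initial conditions are not meaningful, and all cross-run
  claims are made on smoothed or summary quantities.
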