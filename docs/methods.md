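# Methods

## Model

Two FitzHugh–Nagumo neurons under a shared, phase-aligned sinusoidal
stimulus, coupled bidirectionally through a medium with resistive,
inductive and capacitive character:

```
dx1/dt = f1(x1) - y1 + (a/ω) cos(ωt) - u_pid
dy1/dt = b1 x1 + v1 y1
dx2/dt = f2(x2) - y2 + (a/ω) cos(ωt) + u_pid + u_s
dy2/dt = b2 x2 + v2 y2
```

with `f_i(x) = x (x - 1)(1 - r_i x)`, synchronization error `e = x1 - x2`,
natural coupling current `u_pid = kp e + ki z + kd ė` and supervisory signal
`u_s = k̃p e + k̃i z + k̃d ė`. The state `z` with `ż = e`, `z(0) = 0`
realizes both running integrals: they start at the same instant with the
same integrand, so they are one and the same quantity and sharing the state
is exact, not an approximation. The supervisory signal acts on neuron 2
only; the natural current enters the two neurons with opposite signs, which
is why `dx1/dt + dx2/dt` is independent of all three natural gains — a
structural invariant the tests assert.

The recovery leak `v` defaults to 0, under which the coupled model has
purely integrating recovery variables; a nonzero leak is accepted for the
standalone single-neuron form.

Assumptions inherited from the model: the medium is linear (so the three
current components superpose), both neurons receive the identical stimulus,
and coupling is purely electrical (gap junction); chemical synapses,
stochastic inputs, delays and networks of more than two neurons are out of
scope.

## Resolving the implicit coupling

`ė = ẋ1 - ẋ2` appears inside `u_pid` and `u_s`, making the activation
equations implicit. Collecting the derivative terms yields the linear
system `M (ẋ1, ẋ2)ᵀ = (F1, F2)ᵀ` with

```
M = [[1 + kd, -kd], [-(kd + k̃d), 1 + kd + k̃d]],   det M = 1 + 2 kd + k̃d,
```

where `F1`, `F2` are the explicit parts of the right-hand sides. Rather
than a generic linear solve, the implementation subtracts the rows first:

```
ė  = (F1 - F2) / det M
ẋ1 = F1 - kd ė
ẋ2 = ẋ1 - ė
```

This back-substituted form is algebraically exact and has a useful
floating-point property: when `F1 == F2` (identical neurons in identical
states) the computed `ė` is exactly zero, so a perfectly symmetric pair can
never desynchronize through rounding. Configurations with
`|1 + 2 kd + k̃d| ≤ 1e-12` are rejected as singular, naming the offending
gains. Residuals of the raw implicit equations at the resolved point are at
machine-epsilon level (checked against an independent fixed-point iteration
for a thousand random states and gain sets).

## Integration

`scipy.integrate.solve_ivp` on the resolved explicit system. Defaults:
RK45, `rtol = 1e-8`, `atol = 1e-10`, horizon 200 time units, output grid
step 0.05 (4001 samples). The horizon is long enough for both the
synchronization transient and the steady oscillatory regime to be visible
at the reference parameters; all settings are configurable. Derived
signals (`e`, `ė`, `u_pid`, `u_s`) are recomputed from the exact right-hand
side at every output sample, never by finite-differencing the stored
states, so `ė` satisfies the error dynamics
`ė = f1(x1) - f2(x2) - y1 + y2 - (2 u_pid + u_s)` to solver accuracy.

Default initial condition: `(x1, y1) = (0.1, 0.1)`, `(x2, y2) = (0, 0)`,
`z = 0` — distinct starting states so synchronization is a nontrivial
event. Integration is deterministic; identical inputs give bit-identical
trajectories.

For the cross-check against an independently coded conventional resistive
simulator the package uses DOP853 at `rtol = 1e-11`, `atol = 1e-13` on both
sides, so each trajectory is converged well below the 1e-6 comparison
level.

## Metrics

All metrics are functions of the sampled error `e(t)`:

* `objective_j` — trapezoidal `∫₀^τ e² dt`; τ defaults to the full horizon.
  If τ falls between samples the integrand is linearly interpolated at τ.
* `steady_state_error` — mean `|e|` over the terminal window, default the
  last 20% of the horizon. The window fraction is a reporting choice: the
  reference dynamics settle well before 80% of the 200-unit horizon.
* `peak_error` — max `|e|` over the whole horizon; used as the overshoot
  proxy since transient overshoot is otherwise not uniquely defined for an
  oscillatory error.
* `terminal_oscillation` — standard deviation of `e` over the terminal
  window.

All four are invariant under swapping the two neurons (`e → -e`).

## Particle swarm optimizer

Global-best PSO, written in-package:

```
V ← W V + C1 Rand (Pbest - X) + C2 Rand (Gbest - X),   X ← X + V
```

`Rand` is a fresh uniform(0,1) scalar per term, per dimension, per step.
Defaults `W = 0.7`, `C1 = C2 = 1.5`, 30 particles, 100 iterations —
standard practice values; the model supplies no preferred setting.
Positions are clipped to the search box and clipped velocity components
zeroed. Updates are synchronous: all particles move against the global
best entering the iteration, then personal and global bests refresh, so
results are independent of evaluation order and fully reproducible from
the seed. The stop rule is the iteration budget, optionally shortened when
the per-iteration global-best improvement falls below a tolerance
(a fitness-based stop is not well defined without a known target value).

The default search box is symmetric, `[-2, 2]` per gain, so gains of
either sign are reachable — negative derivative compensation in particular
is a legitimate optimum. For the supervisory study the derivative gain is
bounded below at -0.9 instead, keeping `det M = 1 + 2 kd + k̃d` positive
and the closed loop well posed; candidate gain sets whose closed loop still
diverges receive a large finite penalty (1e6, far above any J attainable by
a bounded trajectory at these horizons) so the swarm keeps moving rather
than aborting.

## Study conditions

The reference pair is mismatched — `r1 = 10, r2 = 10.5, b1 = 1, b2 = 1.2` —
under the shared stimulus `a = 0.1, ω = 0.8796`, so perfect synchrony is
impossible without coupling. Three sweeps probe the natural gains one at a
time:

| swept | grid | held fixed |
|---|---|---|
| kp | 0.1, 0.3, 0.6, 1 | ki = 1e-4, kd = 1e-5 |
| ki | 1e-4, 0.3, 0.6, 1 | kp = 1, kd = 1e-5 |
| kd | 0.001, 0.04, 0.1, 0.3 | kp = ki = 0.01 |

Expected (and asserted) trends: increasing kp strictly decreases the
steady-state error; at ki = 1 the steady-state error drops below 1e-2;
increasing kd suppresses the terminal oscillation. All rows of a sweep
share initial conditions and solver settings.

The supervisory study starts from deliberately deficient natural coupling,
all three gains at 1e-4 (the mismatched pair then holds a steady-state
error of ≈ 0.22, far above the 0.05 deficiency threshold), and tunes
`(k̃p, k̃i, k̃d)` by PSO against `J` of the full closed-loop simulation. At
study scale the swarm uses 10 particles and 15 iterations (161 closed-loop
simulations); this is ample for the 3-dimensional box — the tuned loop cuts
the steady-state error by ≈ 96%, and results are stable across seeds. With
these deficient gains and box the optimum sits at the box corner
(2, 2, 2): once the natural coupling is negligible, J decreases
monotonically in all three supervisory gains over the feasible box, so the
strongest admissible compensator wins. Smaller interior optima, including
ones with negative derivative gain, arise for other deficiency patterns
and boxes.

## What the tests do and do not show

The studies run on the deterministic reference configuration, not on data:
passing tests demonstrate the structural properties of the model (exact
implicit resolution, sign cancellation, reduction to the resistive model)
and the qualitative effect of each coupling term under the documented
initial conditions, horizon and solver settings. They do not certify the
behavior of biological neurons, nor pixel-level agreement with any
particular published trajectory plot, since those depend on unstated
initial conditions. Known limitations: two neurons only; no noise, delay
or parameter drift; the PID decomposition assumes a linear coupling
medium; `steady_state_error` is a windowed average, not a control-theoretic
settling-time certificate.
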