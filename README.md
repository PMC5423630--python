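# fhnsync

Synchronization of two gap-junction-coupled FitzHugh–Nagumo (FHN) neurons
whose coupling medium is modeled as a parallel RLC circuit, with a
PSO-tuned supervisory PID compensator for deficient coupling.

## The problem

Electrically coupled neurons communicate through the extracellular medium.
The conventional gap-junction model treats that medium as purely resistive:
the current flowing from neuron 1 to neuron 2 is `I = g (x1 - x2)`, a force
proportional to the difference of the membrane (activation) potentials.
Physically, though, the medium also has capacitive and inductive character,
so the conduction current carries three terms:

```
I(t) = g e(t) + g_c de/dt + g_l ∫₀ᵗ e ds ,      e = x1 - x2 .
```

These are exactly the proportional, integral and derivative actions of a PID
controller acting on the synchronization error `e` — the medium is a
*natural PID controller* with gains `kp = g`, `ki = g_l`, `kd = g_c`. Each
neuron follows the stimulated FHN dynamics

```
dx/dt = x (x - 1) (1 - r x) - y + (a/ω) cos(ωt) ∓ I ,    dy/dt = b x ,
```

with the coupling current entering the two neurons with opposite signs.
When the natural gains are too weak to synchronize the pair, a supervisory
PID signal `u_s = k̃p e + k̃i ∫ e + k̃d ė` is added to the second neuron and
its three gains are tuned by particle swarm optimization (PSO) to minimize
the integrated squared error `J = ∫₀^τ e² dt`.

Because `de/dt` appears inside the coupling current, the coupled equations
define the derivatives implicitly. The system is linear in
`(dx1/dt, dx2/dt)`, so the package resolves it exactly through the 2×2 mass
matrix with determinant `1 + 2 kd + k̃d` — no DAE solver involved.

## Worked example

```python
import fhnsync as fs

cfg = fs.reference_config(fs.CouplingGains(kp=0.6, ki=1e-4, kd=1e-5))
traj = fs.simulate(cfg)                 # 200 time units, 4001 samples
print(fs.compute_metrics(traj))
```

prints

```
SyncMetrics(steady_state_error=0.01771889839722575, peak_error=0.30525346225713573,
            terminal_oscillation=0.03350165987894934, objective_j=0.24109438178302667)
```

i.e. with moderate resistive coupling (`kp = 0.6`) the two mismatched
neurons (`r1 = 10, r2 = 10.5, b1 = 1, b2 = 1.2`, shared stimulus
`a = 0.1, ω = 0.8796`) lock to within a mean terminal error of ≈ 0.018
after a transient peaking at ≈ 0.31. Sweeping the proportional gain shows
the trend directly:

```python
print(fs.run_sweep(fs.default_sweep_spec("kp")).table)
```

```
    kp  steady_state_error  peak_error  terminal_oscillation  objective_j
0  0.1            0.113239    0.904592              0.190425    10.650389
1  0.3            0.022360    0.457039              0.035085     0.354579
2  0.6            0.017719    0.305253              0.033502     0.241094
3  1.0            0.013601    0.205560              0.026647     0.146373
```

— stronger resistive coupling monotonically shrinks the steady-state
synchronization error. The same study is available from the shell:

```
fhnsync sweep --gain kp --out out/kp_sweep
fhnsync tune  --out out/tune --seed 1     # PSO-tuned supervisory PID
```

Each command writes CSV tables plus a `manifest.json` echoing the full
resolved configuration, so any run is reproducible from its output
directory alone.

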