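# lamina

A scriptable, GUI-free simulator for layered circuits of the retina and
the early visual system.

Retinal processing is naturally described as stacked two-dimensional
sheets of cells — photoreceptor/horizontal-cell filtering, then bipolar,
amacrine and ganglion cell layers, optionally continuing into cortical
populations — connected by specific synapses.  `lamina` represents each
sheet as a **layer**: a 2-D grid of "Cells" of one model type, where a
Cell may be a neuron, a neural population (e.g. a cortical column in a
mean-field description), or a prosthesis electrode.  Each cell type is an
ODE model

```
dX/dt = F(X, mu, I(t))
```

with state vector `X`, parameters `mu` and inputs `I` assembled from an
external drive (a movie passed through a receptive-field front end, or a
prosthesis electrode current) plus typed synaptic sums: currents (pA),
post-synaptic-potential rates (mV/s) and firing rates (Hz).  Voltage-based
cells follow the generic conductance form

```
C dV/dt = -g_L (V - E_L) - sum_X g_X (V - E_X) + I_syn + I_ext
```

or its per-capacitance variant, with piecewise-linear rectification
`N(V) = max(V - theta, 0)` for rectified conductances.  Synapses are typed
rules over pre/post cell outputs (nicotinic ACh kinetics, rectified and
linear PSPs, gap junctions, GABA_A/AMPA ligand gating, rate couplings,
density-scaled retino-cortical relays), optionally delayed by a
conduction velocity via `delay = d / v_C` on the 2-D inter-cell distance.

What makes the package more than a fixed model zoo:

* **Declarative models.**  Cell and synapse types are JSON documents whose
  vector fields and rules are plain equation text (a small LaTeX subset is
  accepted).  An expression compiler turns them into vectorised numpy
  callables at load time — no code generation, no recompilation.  Users
  add, edit and delete types at runtime; a pair of shipped cortical
  definitions is protected against modification.
* **Graph generators.**  Six connectivity kinds between or within layers
  (one-to-one, nearest neighbours, 4+1, radius, Gaussian-weighted, fully
  connected), with normalised Gaussian weights
  `W = exp(-d^2 / 2 sigma_p^2) / (2 pi sigma_p^2)`.
* **Visual front end.**  Grayscale movies (levels 1–255) filtered by a
  circularly-symmetric difference-of-Gaussians receptive field computed
  with a fourth-order recursive (Deriche-style) Gaussian — O(pixels) at
  any width — followed by a causal exponential temporal cascade.  A
  prosthesis mode instead tiles each frame over an electrode grid and
  feeds per-tile mean gray levels as currents.
* **Engine.**  Explicit fixed-grid solvers (Euler, RK2, RK4 by default,
  adaptive RK45 reporting on the fixed grid), discrete-step delay buffers,
  per-(cell, variable) recordings, deterministic batch sessions from JSON.

## Worked example: a gap-junction pair

Two leaky cells (`tau = 0.1 s`, `E_L = -60 mV`) coupled by reciprocal gap
junctions (`w_gap = 10 Hz`) diffuse toward a common voltage while both
relax to the leak reversal:

```python
from lamina import Graph, LayerSpec, Edge, SessionConfig, run

layer = LayerSpec(name="pair", cell_type="linear_cell", nx=2, ny=1)
graph = Graph(
    layers=[layer],
    edges=[Edge(("pair", 0), ("pair", 1), "gap_junction"),
           Edge(("pair", 1), ("pair", 0), "gap_junction")],
    initial_values={"pair": {"V": [-80.0, -40.0]}},
)
cfg = SessionConfig(graph=graph, dt=1e-4, t_end=0.5,
                    record=[{"layer": "pair", "cells": "all", "var": "V"}])
rec, manifest = run(cfg)
V = rec.series[("pair", "V")]
print(f"t = 0.0 s: V = {V[0].round(3)} mV")
print(f"t = 0.1 s: V = {V[1000].round(3)} mV")
print(f"t = 0.5 s: V = {V[-1].round(3)} mV")
```

prints

```
t = 0.0 s: V = [-80. -40.] mV
t = 0.1 s: V = [-60.996 -59.004] mV
t = 0.5 s: V = [-60. -60.] mV
```

The voltages stay symmetric about −60 mV (the two coupling terms cancel
exactly at every step) and merge onto the common equilibrium.

Three larger scenarios ship as builders (`lamina.scenarios`) and as CLI
subcommands: `retinal_waves` (a lattice of Morris–Lecar starburst
amacrine cells releasing acetylcholine, with a slow-AHP current, that
produces bursting activity without any visual input), `retino_cortical`
(gain-control bipolar → amacrine → ganglion layers driven by a moving
bar, feeding excitatory/inhibitory cortical columns with delayed Gaussian
lateral coupling) and `awc` (an Amari–Wilson–Cowan rate network with
Gaussian pooling and an erf sigmoid).  From a shell:

```sh
lamina scenario --name retinal_waves --out waves/
lamina run -f waves/retinal_waves_session.json --out waves/output
lamina list-models
```

Recordings are written as one CSV per (layer, variable) plus a manifest
JSON.

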