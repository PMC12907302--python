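# Methods

This note documents the models, numerical choices and design decisions
behind `lamina`, in the order a simulation is assembled: units, the
declarative model layer, the cell and synapse libraries, graphs, the
visual front end, the integration engine, and the shipped scenarios.  It
also states what the synthetic stimuli and tests do and do not establish
about real data.

## Units

All internal computation uses one default unit per physical quantity:
seconds, millivolts, picoamps, nanosiemens, millimetres, nanofarads,
hertz and nanomolar.  Alternative units (ms, V, nA, pS, µm, pF, kHz,
µM/mM) convert by exact factors at model load and again at output.
Per-membrane-area units (µA/cm², mS/cm², µF/cm²) form their own
convertible families; they bridge to absolute units only through an
explicit membrane area, since no default cell area is assumed.  Units are
deliberately metadata only: the engine does not check that a user model
is dimensionally coherent.  Spatial positions carry one of three
modalities — millimetres, degrees of visual angle, or pixels — related by
a single per-stimulus calibration factor rather than fixed constants.

## Declarative models and the expression compiler

A cell type is a JSON document: state variables, parameters (name,
default, unit, optional bounds), input slots, auxiliary functions, one
right-hand-side expression per state variable, and named outputs readable
by synapses.  A synapse type is a parameter list, an output kind
(`current`, `voltage_rate` or `firing_rate`) and one rule expression.
Equations are plain ASCII infix over `+ - * / ^`, comparisons, a fixed
function whitelist (`exp log erf tanh sqrt cosh sinh min max pow
heaviside abs where`) and the declared symbols; a small LaTeX subset
(`\frac`, `\sqrt`, function macros, Greek letters, `\cdot`) is normalised
to ASCII before parsing.  The dialect is this package's own definition.

Compilation is a recursive-descent parse to a small AST followed by code
generation to a numpy-vectorised Python callable.  Design points:

* **Auxiliary functions are macros.**  They are inlined at compile time
  with their arguments substituted, so evaluation never recurses and the
  compiled callable is a single flat expression.  Recursive auxiliaries
  are rejected.
* **Strict domains.**  Division by zero and `log`/`sqrt` outside their
  domains raise immediately rather than yielding NaN/Inf sentinels; a
  silent NaN can corrupt hours of simulated time before it is noticed.
* **Strict rectification.**  `heaviside(0) = 0`, matching the strict
  inequality of the piecewise-linear rectifier `N(V) = V − θ for V > θ,
  else 0`.
* **Determinism.**  Compiling the same source twice yields structurally
  identical ASTs (expressions compare and hash structurally).

Every shipped definition has a hand-coded Python twin
(`lamina.cells`, `lamina.synapses`); the test suite requires compiled and
hand-coded forms to agree to 1e−12 relative at random state/parameter
points, which guards both the compiler and the JSON files.

Input slots map to fixed equation symbols: `ext` (external drive),
`I_syn` (pA), `V_syn` (mV/s), `FR_syn` (Hz).  Synapse rules additionally
see the geometric edge weight `w` and pre/post cell outputs as
`pre_<name>` / `post_<name>`; which outputs exist is checked when a graph
is wired, not at compile time, so a rule can be written before the cell
types it will connect.

Two shipped definitions (`cortical_excitatory`, `cortical_inhibitory`)
are protected: they can be neither overwritten nor deleted.  User types
live as one JSON file each in a registry directory; deleting an
unprotected type removes both the entry and its file.

## Cell library

* **Linear cells** (`linear_cell`): `dV/dt = −(V − E_L)/τ + V_syn`.  The
  pharmacology variant adds a tunable conductance `g_P` with Nernst
  potential `E_P` in the per-capacitance form, e.g. for an injected drug.
* **Neurotransmitter amacrine** (`neurotransmitter_amacrine`):
  quasi-static transmitter production through a voltage sigmoid, a leaky
  voltage driven by synaptic current, and a channel activation variable
  `n` that synaptic (GABA_A/AMPA) rules read.
* **Gain-control bipolar / ganglion**: an activity variable integrates
  the rectified voltage and divides the cell's output.  The bipolar
  output `bipolarResponse = N(V − θ_B)/(1 + A_B)` feeds pooling synapses;
  the ganglion output `firingRate = N(V − θ_G)/(1 + A_G)` is the retinal
  output rate.  The divisive form is this package's choice for how the
  activity variable controls the response; the transfer is an ordinary
  output expression, so users can substitute any other form without
  touching code.  The ganglion's tunable ionic term is implemented as
  `(g_T/C)·N(V − V_T)`, i.e. a rectified conductance divided by
  capacitance, consistent with the per-capacitance voltage form used
  throughout.
* **Morris–Lecar** (`morris_lecar`, plus ACh and ACh+sAHP variants): the
  classical two-variable form with the standard Hopf parameter set,
  expressed in absolute nS/nF units with the canonical
  conductance-to-capacitance ratios on a time base of seconds (C = 0.02
  nF, g_Ca = 4.4 nS, φ = 40/s, ...).  With these values a constant drive
  of ~60 pA relaxes to rest and ~100 pA produces sustained spiking, as in
  the per-area original.  The ACh variant adds
  `dA/dt = −A/τ_Ach + μ_A·σ(V)`; A stays non-negative from non-negative
  initial conditions because the production term is non-negative.  The
  sAHP variant adds a two-stage relaxation cascade (R tracks a voltage
  sigmoid, S tracks R) gating a potassium current `−g_sAHP·S⁴·(V − E_K)`.
  This sAHP kinetics is a documented stand-in with the stated state
  variables, not a reproduction of any published starburst-cell model;
  its parameters are fully exposed.
* **Hodgkin–Huxley** (`hodgkin_huxley`): the classical 1952 squid-axon
  rate functions in the modern voltage convention (rest ≈ −65 mV),
  scaled from 1/ms to 1/s, at the original temperature; no temperature
  scaling (Q10) is applied.
* **Cortical columns** (`cortical_excitatory`/`_inhibitory`): a leaky
  population voltage integrating a firing-rate input, with output rate
  `ν = ν_max·Φ(gain·(V − V_thr))`, Φ the erf sigmoid.  This is a
  deliberately simple rate stand-in for a mean-field cortical column —
  monotone, non-negative, saturating — not a particular published
  mean-field derivation; the two populations differ only in their time
  constants by default.
* **Electrode** (`electrode`): a passive low-pass,
  `dV/dt = −V/τ + I_ext/C`.
* **AWC unit** (`awc_cell`): `dV/dt = −V/τ + V_syn + ext` with output
  `f(V) = (1 + erf(gV/√2))/2`, the building block of the
  Amari–Wilson–Cowan scenario.

## Synapse library

Rules produce one of three kinds, summed per post-synaptic cell into the
matching input slot; an edge whose kind has no slot on the post cell type
is a wiring error raised before integration.  The effective coupling of
an edge is the product of the geometric weight produced by the graph
generator (a constant, or the normalised Gaussian profile) and the
synapse type's own gain parameters; every shipped rule therefore carries
the factor `w`.  Inhibition is encoded by negative weights or gains.

The ligand-gated (GABA_A/AMPA) rule drives `−g·n·(V_drive − E)` with the
post-synaptic voltage by default, the physiologically standard driving
force; a `literal` parameter (0/1) switches to the pre-synaptic voltage
for users who want the alternative convention.  The rectified rule reads
`w·max(V_pre − θ_pre, 0)`: the threshold is applied once, inside the
rectifier.  The retino-cortical relay scales the pre firing rate by
`weight · density_retina/density_cortex`, defaulting to 400 and 4000
cells/mm².

**Delays.**  Synapses are instantaneous unless their type declares a
parameter named exactly `conduction_velocity` (mm/s).  The continuous
delay `d/v_C` — `d` the 2-D Euclidean distance between the endpoints,
vertical layer separation ignored — is discretised to the nearest whole
number of integration steps (minimum 0) and served from a per-layer ring
buffer of output samples, pre-filled with the t = 0 value.  Because the
discretisation floors at zero steps, the infinite-velocity limit is
*exactly* the instantaneous code path, which the tests exploit.  Delayed
inputs are held constant across the stages of one integration step;
undelayed inputs are re-evaluated at every solver stage.

## Graphs

Layers are rectangular grids with row-major, 0-based indexing; cell `k`
sits at `origin + spacing·(k mod nx, k div nx)`, all layers sharing one
(x, y) frame.  Six connectivity generators produce the edge sets; all are
verified against an independent brute-force pair enumeration:

* `one_to_one` and `neighbor_4_plus_1` require equal grid counts.
* `nearest_neighbors` connects each cell to *every* cell at the minimal
  strictly-positive distance: 4 in the interior of a square lattice, 3 on
  edges, 2 at corners.  Ties are resolved by connecting to all tied cells
  (deterministic and order-independent); there is no periodic wrap.
* `radius` uses a closed boundary `0 < d ≤ r` with constant weights.
* `gaussian` includes the zero-distance cell and truncates at
  `d > 4σ_p` (weights below e⁻⁸ of the peak) for performance; the cutoff
  is configurable.  Intra-layer Gaussian connectivity is symmetric with
  equal reciprocal weights, and the summed weights from one cell times
  the spacing² Riemann measure converge to 1 as the cutoff grows.
* `fully_connected` excludes self-pairs within a layer.

Graphs serialise to a documented JSON file (layers, edges with synapse
type / weight / delay steps, initial values per layer and state
variable); model parameters live in a separate JSON keyed by layer name
and synapse type, mirroring the structure/parameters split of scenario
files.  Stored delay steps are recomputed from the conduction velocity
whenever a session's `dt` differs.

## Visual front end

Stimuli are grayscale frame stacks with levels in [1, 255] (colour input
is reduced by the channel mean; levels are used as-is, with no luminance
normalisation — a linear gain maps drive into the receiving slot's
units).  Movie containers are decoded through imageio when an
ffmpeg-capable plugin is present; numbered PNG/TIFF stacks are always
supported, and the fixture generators (moving bar, full-field, drifting
grating) emit such stacks plus a manifest.

The receptive field is a circularly-symmetric spatial difference of
Gaussians, `w_c·G(σ_c) − w_s·G(σ_s)` with σ_s > σ_c (centre-surround
lateral inhibition), followed by a causal exponential cascade of order
`n_rf` with per-stage time constant `τ_rf` (defaults 1 and 20 ms).  The
temporal kernel form is this package's choice — the abstraction being
modelled specifies only "spatial DoG plus temporal filtering" — and
deliberately omits the luminance-adaptation and contrast-gain stages of
full outer-retina models.

Gaussian blurs use a fourth-order recursive (Deriche-style)
approximation: the Gaussian is approximated by two exponentially damped
cosines whose sampled Z-transform yields a 4-tap causal + 4-tap
anticausal recursion per axis, O(pixels) at any σ.  Numerator and
denominator coefficients are built by explicit polynomial construction
from the oscillator transfer functions and normalised to exactly unit DC
gain, so constant images are preserved to machine precision.  Boundaries
are replicate-padded by ⌈5σ⌉+5 samples before the recursion.  Measured
accuracy against direct FIR convolution (6σ-truncated kernel) is ~4·10⁻⁴
relative L∞, independent of σ; widths below 0.5 px trigger a warning
because the discrete approximation degrades there.

Cell positions sample the filtered frame at the nearest pixel through the
stimulus calibration (length per pixel).  Frames are zero-order-held
between frame times on the integration grid; each cascade stage is
advanced by the exact first-order exponential update for its (piecewise
constant) input, a choice that keeps the front end causal and exactly
linear.

**Prosthesis mode.**  The frame is partitioned into one tile per
electrode (floor-based bounds, so tiles partition the frame exactly even
when sizes do not divide); each electrode receives the mean gray level of
its tile times a configurable gain (pA per gray level).

## Engine

The global state is the concatenation of per-layer blocks (variables ×
cells); evaluation is vectorised per layer and per edge group (edges
sharing pre layer, post layer, synapse type and delay), with
`np.add.at` scatter-summation into the post layer's input slots.  A
naive per-cell, per-edge reference loop is kept in the synapse module and
the assembled derivative is tested against it.

Solvers are the explicit subset: forward Euler, midpoint RK2, classical
RK4 (default) and an adaptive Dormand–Prince 5(4) that subdivides within
each fixed grid interval — delays and recordings require a fixed output
grid, so adaptivity is internal.  Implicit and multistep methods are out
of scope; all shipped scenarios are non-stiff at their default `dt`.
Measured convergence orders on the leaky cell are 1/2/4 within ±0.05, and
RK4 at `dt = 1e−4 s` tracks the 1 s closed-form exponential to ~1.5e−13
mV.  There are no stochastic terms anywhere in the engine; runs are
bit-reproducible given a session.

Default `dt` is 1e−4 s; the shipped scenarios use 1e−3 s, comfortable for
their fastest rates (≲ 10³/s).  A non-finite state after any step aborts
with the time, layer, cell and variable of the first offending slot.
Recording reads states (or named outputs, e.g. `firingRate`) without
feeding back into the dynamics, at a configurable stride, and writes one
CSV per (layer, variable) plus a manifest containing a hash of the
configuration.

## Scenarios and the synthetic-data generators

The stimulus fixtures and scenario builders are the package's synthetic
data.  They emulate the *structure* of experimental stimuli (a bright bar
sweeping at constant speed, full-field steps, drifting gratings) and of
published circuit layouts; they do not emulate photon noise, optical
blur, eye movements, cell-to-cell parameter heterogeneity within a layer
(layers share parameters by construction) or stochastic synaptic release.
Passing tests therefore establish the correctness of the machinery —
compilation, wiring, integration, delays, filtering — not quantitative
agreement with any particular biological recording.

* **Retinal waves** (default 10×10, 5 s, dt 1e−3): one layer of
  ACh+sAHP Morris–Lecar cells at a constant 100 pA operating point,
  nearest-neighbour nicotinic coupling.  Initial voltages are jittered
  uniformly over [−65, −45] mV under an explicit seed: in stochastic
  treatments wave nucleation is noise-driven, and seeded heterogeneous
  initial conditions stand in for that in a deterministic integrator.
  Expected behaviour, and what the tests assert: bounded voltages
  (−100…60 mV), non-negative ACh, and exact agreement with the
  single-cell reference when the coupling conductance is zeroed.
* **Retino-cortical** (default 8×8 retinal and cortical grids, 1 s):
  gain-control bipolars driven by the moving bar through the DoG front
  end, one-to-one excitation of amacrines and Gaussian pooling onto
  ganglions, amacrine inhibition of both (negative weights), ganglion
  rates relayed to both cortical populations (density ratio 400/4000,
  relay weight 200 so the cortex visibly leaves rest), and delayed
  Gaussian lateral cortical coupling at 100 mm/s.  There is no thalamus
  stage: ganglion rates feed cortex directly.  Zeroing the inhibitory
  weights makes the bipolar traces exactly equal to a feed-forward-only
  reference run.
* **AWC** (default 16×16): `dV_i/dt = −V_i/τ + Σ_j J_ij f(V_j) + H_ext`
  with Gaussian `J_ij` (self-term included) scaled so the diagonal equals
  a nominal `J0`, and the erf sigmoid `f` with gain `g` in 1/mV.  At
  `g = 0`, `f ≡ 1/2` and the network's fixed point solves the linear
  system `V*/τ = J·½ + H_ext`; the simulation reaches it to < 1e−8 mV
  after 2 s (40 time constants).

Lattice sizes and durations are chosen for desk-scale runtimes (each
scenario runs in seconds on one CPU); all three builders are
deterministic given their arguments.

## Known limitations

* Point cells only: no multi-compartment morphology, no spatially
  extended neurons.
* No stochastic integrators; noise can only enter through initial
  conditions or stimuli.
* Receptive fields are circularly symmetric; direction- or
  orientation-selective kernels are not expressible in the recursive
  filtering scheme used.
* No colour processing.
* The cortical-column and sAHP models are documented stand-ins (see
  above); scenario-level checks on them are property-based
  (boundedness, non-negativity, coupling behaviour), not value
  reproduction of any published figure.
* Unit coherence is the user's responsibility.
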