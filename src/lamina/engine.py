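"""Simulation engine: global ODE assembly, explicit solvers, delays,
recordings and batch sessions.

The engine takes a :class:`~lamina.graph.Graph`, a model registry and an
optional stimulus front end, and assembles one global vector field over
the concatenated state of every cell.  Evaluation is vectorised per layer
(cells of a layer share a type and parameters) and per edge group (edges
sharing pre layer, post layer, synapse type and delay), so cost scales
with the number of layers and edge groups, not with individual cells.

Solvers are the explicit subset: forward Euler, midpoint (RK2), classical
RK4 (the default) and an adaptive Dormand–Prince RK45 that reports on the
fixed ``dt`` grid (conduction delays require a fixed output grid).

All computation happens in the default units (s, mV, pA, nS, nF, Hz, nM);
unit conversion belongs to model load and output time.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .graph import Graph, LayerSpec, ValidationError, euclidean_distance, load_graph
from .registry import (KIND_TO_SLOT, SLOT_SYMBOLS, CellTypeDef, ModelRegistry,
                       SynapseTypeDef, load_builtin_registry)
from .stimulus import (ReceptiveFieldSpec, Stimulus, dog_response, load_stimulus,
                       make_full_field, make_grating, make_moving_bar,
                       prosthesis_input)
from .synapses import DelayBuffer, WiringError, synaptic_delay

__all__ = [
    "SOLVERS",
    "IntegrationError",
    "SessionConfig",
    "Recording",
    "Network",
    "assemble",
    "run",
]

SOLVERS = ("euler", "rk2", "rk4", "rk45")
WORKERS = ("visual_flow", "prosthesis", "none")


class IntegrationError(RuntimeError):
    """Non-finite derivative or state during integration."""


# ---------------------------------------------------------------------------
# Session configuration


@dataclass
class SessionConfig:
    """Everything needed for one batch run (mirrors the session JSON)."""

    graph: str | Path | Graph
    params: str | Path | dict | None = None
    worker: str = "none"
    stimulus: str | Path | dict | Stimulus | None = None
    rf: dict | ReceptiveFieldSpec | None = None
    external: dict = field(default_factory=dict)  # layer -> drive spec
    solver: str = "rk4"
    dt: float = 1e-4
    t_end: float = 1.0
    record: list = field(default_factory=list)    # [{layer, cells, var}]
    record_stride: int = 1
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        bad = []
        if self.solver not in SOLVERS:
            bad.append(f"solver {self.solver!r}")
        if self.worker not in WORKERS:
            bad.append(f"worker {self.worker!r}")
        if not self.dt > 0:
            bad.append("dt")
        if not self.t_end >= self.dt:
            bad.append("t_end")
        if self.record_stride < 1:
            bad.append("record_stride")
        for k, r in enumerate(self.record):
            if not isinstance(r, dict) or "layer" not in r or "var" not in r:
                bad.append(f"record[{k}]")
        if bad:
            raise ValidationError("invalid session", bad)

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        path = Path(path)
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"session file {path} is not valid JSON: {exc}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError("unknown session fields", unknown)
        cfg = cls(**data)
        # relative paths resolve against the session file
        base = path.parent
        if isinstance(cfg.graph, str) and not Path(cfg.graph).is_absolute():
            cfg.graph = base / cfg.graph
        if isinstance(cfg.params, str) and not Path(cfg.params).is_absolute():
            cfg.params = base / cfg.params
        if isinstance(cfg.stimulus, str) and not Path(cfg.stimulus).is_absolute():
            cfg.stimulus = base / cfg.stimulus
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = {
            "graph": str(self.graph) if isinstance(self.graph, (str, Path)) else "<inline>",
            "params": str(self.params) if isinstance(self.params, (str, Path)) else self.params,
            "worker": self.worker,
            "stimulus": (str(self.stimulus) if isinstance(self.stimulus, (str, Path))
                         else ("<inline>" if isinstance(self.stimulus, Stimulus)
                               else self.stimulus)),
            "rf": self.rf if not isinstance(self.rf, ReceptiveFieldSpec) else vars(self.rf),
            "external": self.external,
            "solver": self.solver, "dt": self.dt, "t_end": self.t_end,
            "record": self.record, "record_stride": self.record_stride,
            "seed": self.seed,
        }
        return d


@dataclass
class Recording:
    """Per-(layer, variable) time series in default units."""

    times: np.ndarray
    #: (layer, var) -> (n_times, n_selected) array
    series: dict = field(default_factory=dict)
    #: (layer, var) -> list of recorded cell ids
    cells: dict = field(default_factory=dict)

    def frame(self, layer: str, var: str):
        import pandas as pd

        key = (layer, var)
        cols = {"t": self.times}
        for j, cid in enumerate(self.cells[key]):
            cols[f"cell_{cid}"] = self.series[key][:, j]
        return pd.DataFrame(cols)

    def write_csvs(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for layer, var in self.series:
            p = directory / f"{layer}__{var}.csv"
            self.frame(layer, var).to_csv(p, index=False)
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# Assembly


class _LayerBlock:
    """Per-layer runtime data: type, parameters, state slice."""

    def __init__(self, spec: LayerSpec, ctype: CellTypeDef, params: dict,
                 offset: int):
        self.spec = spec
        self.ctype = ctype
        self.params = params
        self.n = spec.n_cells
        self.nvar = len(ctype.state_vars)
        self.var_names = [sv.name for sv in ctype.state_vars]
        self.offset = offset  # start of this layer's block in the flat vector
        self.slots = [SLOT_SYMBOLS[s] for s in ctype.input_slots]
        self.positions = spec.positions()

    def unpack(self, X: np.ndarray) -> dict:
        block = X[self.offset:self.offset + self.n * self.nvar]
        mat = block.reshape(self.nvar, self.n)
        return {name: mat[i] for i, name in enumerate(self.var_names)}

    def env(self, X: np.ndarray) -> dict:
        env = self.unpack(X)
        env.update(self.params)
        return env


class _EdgeGroup:
    """Edges sharing (pre layer, post layer, synapse type, delay)."""

    def __init__(self, pre: str, post: str, sdef: SynapseTypeDef, params: dict,
                 pre_idx, post_idx, weights, delay_steps: int):
        self.pre = pre
        self.post = post
        self.sdef = sdef
        self.params = params
        self.pre_idx = np.asarray(pre_idx, dtype=int)
        self.post_idx = np.asarray(post_idx, dtype=int)
        self.weights = np.asarray(weights, dtype=float)
        self.delay_steps = delay_steps
        self.slot = SLOT_SYMBOLS[KIND_TO_SLOT[sdef.output_kind]]


class Network:
    """Assembled global ODE system over a graph.

    The derivative is a pure function of ``(t, X)`` and the current delay
    buffers; evaluating it never mutates state.
    """

    def __init__(self, graph: Graph, registry: ModelRegistry,
                 cell_params: dict | None = None,
                 synapse_params: dict | None = None, dt: float = 1e-4):
        graph.validate()
        self.graph = graph
        self.registry = registry
        self.dt = dt
        cell_params = cell_params or {}
        synapse_params = synapse_params or {}

        self.layers: dict[str, _LayerBlock] = {}
        offset = 0
        for spec in graph.layers:
            if spec.cell_type not in registry:
                raise WiringError(f"unknown cell type {spec.cell_type!r} "
                                  f"on layer {spec.name!r}")
            ctype = registry[spec.cell_type]
            if ctype.kind != "cell":
                raise WiringError(f"{spec.cell_type!r} is not a cell type")
            params = ctype.default_params()
            params.update(cell_params.get(spec.name, {}))
            self.layers[spec.name] = _LayerBlock(spec, ctype, params, offset)
            offset += spec.n_cells * len(ctype.state_vars)
        self.n_state = offset

        # group edges and wire-check synapse/cell compatibility
        groups: dict[tuple, list] = {}
        for e in graph.edges:
            if e.synapse_type not in registry:
                raise WiringError(f"unknown synapse type {e.synapse_type!r}")
            sdef = registry[e.synapse_type]
            if sdef.kind != "synapse":
                raise WiringError(f"{e.synapse_type!r} is not a synapse type")
            params = sdef.default_params()
            params.update(synapse_params.get(e.synapse_type, {}))
            pre_block = self.layers[e.pre[0]]
            post_block = self.layers[e.post[0]]
            slot_name = KIND_TO_SLOT[sdef.output_kind]
            if slot_name not in post_block.ctype.input_slots:
                raise WiringError(
                    f"synapse {sdef.name!r} produces {sdef.output_kind!r} but "
                    f"cell type {post_block.ctype.name!r} has no "
                    f"{slot_name!r} slot")
            for out in sdef.pre_outputs:
                if out not in pre_block.ctype.outputs:
                    raise WiringError(
                        f"synapse {sdef.name!r} reads pre output {out!r}, "
                        f"absent on cell type {pre_block.ctype.name!r}")
            for out in sdef.post_outputs:
                if out not in post_block.ctype.outputs:
                    raise WiringError(
                        f"synapse {sdef.name!r} reads post output {out!r}, "
                        f"absent on cell type {post_block.ctype.name!r}")
            if sdef.delayed:
                v_C = params.get("conduction_velocity")
                d = euclidean_distance(pre_block.positions[e.pre[1]],
                                       post_block.positions[e.post[1]])
                delay = synaptic_delay(d, v_C, dt)
            else:
                delay = 0
            key = (e.pre[0], e.post[0], e.synapse_type, delay)
            groups.setdefault(key, []).append((e.pre[1], e.post[1], e.weight, params))

        self.edge_groups: list[_EdgeGroup] = []
        for (pre, post, stype, delay), items in sorted(groups.items()):
            pre_idx = [i for i, _, _, _ in items]
            post_idx = [j for _, j, _, _ in items]
            weights = [w for _, _, w, _ in items]
            self.edge_groups.append(_EdgeGroup(
                pre, post, registry[stype], items[0][3], pre_idx, post_idx,
                weights, delay))

        #: outputs each layer must expose every step, for delayed reads
        self._delayed_outputs: dict[str, set[str]] = {}
        for g in self.edge_groups:
            if g.delay_steps > 0:
                self._delayed_outputs.setdefault(g.pre, set()).update(
                    g.sdef.pre_outputs)
        self.max_delay = max((g.delay_steps for g in self.edge_groups), default=0)
        self._buffers: dict[tuple[str, str], DelayBuffer] = {}

        #: per-step external drive arrays, layer -> (n_steps+1, n) or scalar
        self.external_drive: dict[str, np.ndarray | float] = {}

    # -- state packing ------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        X = np.zeros(self.n_state)
        for name, block in self.layers.items():
            init = self.graph.initial_values.get(name, {})
            for i, var in enumerate(block.var_names):
                if var in init:
                    X[block.offset + i * block.n:
                      block.offset + (i + 1) * block.n] = init[var]
        return X

    def locate(self, flat_index: int) -> tuple[str, int, str]:
        """Map a flat state index back to (layer, cell id, variable)."""
        for name, b in self.layers.items():
            if b.offset <= flat_index < b.offset + b.n * b.nvar:
                local = flat_index - b.offset
                return name, local % b.n, b.var_names[local // b.n]
        raise IndexError(flat_index)

    # -- delay buffers ------------------------------------------------------
    def reset_buffers(self, X0: np.ndarray) -> None:
        self._buffers.clear()
        for lname, outs in self._delayed_outputs.items():
            block = self.layers[lname]
            env = block.env(X0)
            for out in outs:
                val = np.broadcast_to(
                    np.asarray(block.ctype.outputs[out](env), dtype=float),
                    (block.n,))
                self._buffers[(lname, out)] = DelayBuffer(val, self.max_delay)

    def push_buffers(self, X: np.ndarray) -> None:
        for (lname, out), buf in self._buffers.items():
            block = self.layers[lname]
            env = block.env(X)
            buf.push(np.broadcast_to(
                np.asarray(block.ctype.outputs[out](env), dtype=float), (block.n,)))

    # -- derivative ---------------------------------------------------------
    def derivative(self, t: float, X: np.ndarray,
                   ext_step: int | None = None) -> np.ndarray:
        """Global dX/dt at (t, X); ``ext_step`` indexes the external drive."""
        envs = {name: b.env(X) for name, b in self.layers.items()}
        # outputs needed by any synapse group, from current state
        outputs: dict[str, dict[str, np.ndarray]] = {}

        def layer_output(lname: str, oname: str) -> np.ndarray:
            cache = outputs.setdefault(lname, {})
            if oname not in cache:
                block = self.layers[lname]
                cache[oname] = np.broadcast_to(np.asarray(
                    block.ctype.outputs[oname](envs[lname]), dtype=float),
                    (block.n,))
            return cache[oname]

        # accumulate synaptic inputs
        acc: dict[tuple[str, str], np.ndarray] = {}
        for g in self.edge_groups:
            env = dict(g.params)
            env["w"] = g.weights
            for out in g.sdef.pre_outputs:
                if g.delay_steps > 0:
                    series = self._buffers[(g.pre, out)].read(g.delay_steps)
                else:
                    series = layer_output(g.pre, out)
                env[f"pre_{out}"] = series[g.pre_idx]
            for out in g.sdef.post_outputs:
                env[f"post_{out}"] = layer_output(g.post, out)[g.post_idx]
            vals = np.broadcast_to(np.asarray(g.sdef.rule(env), dtype=float),
                                   g.pre_idx.shape)
            key = (g.post, g.slot)
            if key not in acc:
                acc[key] = np.zeros(self.layers[g.post].n)
            np.add.at(acc[key], g.post_idx, vals)

        dX = np.empty(self.n_state)
        for name, block in self.layers.items():
            env = envs[name]
            for slot in block.slots:
                env[slot] = acc.get((name, slot), 0.0)
            if "ext" in block.slots:
                drive = self.external_drive.get(name, 0.0)
                if isinstance(drive, np.ndarray):
                    k = 0 if ext_step is None else min(ext_step, len(drive) - 1)
                    env["ext"] = drive[k]
                else:
                    env["ext"] = drive
            derivs = {var: block.ctype.rhs[var](env) for var in block.var_names}
            for i, var in enumerate(block.var_names):
                dX[block.offset + i * block.n:
                   block.offset + (i + 1) * block.n] = derivs[var]
        return dX

    # -- recording helpers --------------------------------------------------
    def read_variable(self, X: np.ndarray, layer: str, var: str) -> np.ndarray:
        """A state variable or named output of one layer, as (n_cells,)."""
        block = self.layers[layer]
        if var in block.var_names:
            return block.unpack(X)[var].copy()
        if var in block.ctype.outputs:
            return np.broadcast_to(np.asarray(
                block.ctype.outputs[var](block.env(X)), dtype=float),
                (block.n,)).copy()
        raise KeyError(f"layer {layer!r} has no variable or output {var!r}")


# ---------------------------------------------------------------------------
# Solvers (one step on the fixed grid)


def _step_euler(f, t, X, dt):
    return X + dt * f(t, X)


def _step_rk2(f, t, X, dt):
    k1 = f(t, X)
    k2 = f(t + dt / 2, X + dt / 2 * k1)
    return X + dt * k2


def _step_rk4(f, t, X, dt):
    k1 = f(t, X)
    k2 = f(t + dt / 2, X + dt / 2 * k1)
    k3 = f(t + dt / 2, X + dt / 2 * k2)
    k4 = f(t + dt, X + dt * k3)
    return X + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


# Dormand–Prince 5(4) tableau
_DP_C = np.array([0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B5 = np.array([35 / 384, 0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0])
_DP_B4 = np.array([5179 / 57600, 0, 7571 / 16695, 393 / 640, -92097 / 339200,
                   187 / 2100, 1 / 40])


def _step_rk45(f, t, X, dt, rtol=1e-8, atol=1e-10):
    """Adaptive Dormand–Prince integration across one fixed grid interval."""
    t_end = t + dt
    h = dt
    while t < t_end - 1e-15 * max(1.0, abs(t_end)):
        h = min(h, t_end - t)
        K = [f(t, X)]
        for i in range(1, 7):
            Xi = X + h * sum(a * k for a, k in zip(_DP_A[i], K))
            K.append(f(t + _DP_C[i] * h, Xi))
        X5 = X + h * sum(b * k for b, k in zip(_DP_B5, K))
        X4 = X + h * sum(b * k for b, k in zip(_DP_B4, K))
        scale = atol + rtol * np.maximum(np.abs(X), np.abs(X5))
        err = np.sqrt(np.mean(((X5 - X4) / scale) ** 2))
        if err <= 1.0 or h <= 1e-12:
            t += h
            X = X5
        factor = 0.9 * (err + 1e-16) ** (-1 / 5)
        h *= min(5.0, max(0.2, factor))
    return X


_STEPPERS = {"euler": _step_euler, "rk2": _step_rk2, "rk4": _step_rk4,
             "rk45": _step_rk45}


def step(f, t: float, X: np.ndarray, dt: float, solver: str = "rk4") -> np.ndarray:
    """Advance one fixed step with the chosen explicit solver."""
    if dt <= 0:
        raise ValidationError("dt must be > 0", ["dt"])
    if solver not in _STEPPERS:
        raise ValidationError(f"unknown solver {solver!r}", ["solver"])
    return _STEPPERS[solver](f, t, X, dt)


# ---------------------------------------------------------------------------
# Worker front ends


def _resolve_stimulus(cfg: SessionConfig) -> Stimulus | None:
    s = cfg.stimulus
    if s is None or isinstance(s, Stimulus):
        return s
    if isinstance(s, (str, Path)):
        return load_stimulus(s)
    if isinstance(s, dict):
        spec = dict(s)
        kind = spec.pop("kind", None)
        if kind == "moving_bar":
            return make_moving_bar(**spec)
        if kind == "full_field":
            return make_full_field(**spec)
        if kind == "grating":
            return make_grating(**spec)
        if "path" in spec:
            return load_stimulus(**spec)
        raise ValidationError("unrecognised stimulus spec", sorted(s))
    raise ValidationError("unrecognised stimulus spec")


def _build_external(net: Network, cfg: SessionConfig, stim: Stimulus | None,
                    n_steps: int) -> None:
    """Fill ``net.external_drive`` per layer according to the worker."""
    for lname, spec in cfg.external.items():
        if lname not in net.layers:
            raise ValidationError(f"external drive for unknown layer {lname!r}")
        block = net.layers[lname]
        if "ext" not in block.slots:
            raise WiringError(
                f"layer {lname!r} ({block.ctype.name}) has no external slot")
        if "constant" in spec:
            net.external_drive[lname] = float(spec["constant"])
            continue
        gain = float(spec.get("gain", 1.0))
        if cfg.worker == "none":
            warnings.warn(f"worker 'none': stimulus drive for layer {lname!r} "
                          "ignored", stacklevel=2)
            continue
        if stim is None:
            raise ValidationError(
                f"worker {cfg.worker!r} needs a stimulus for layer {lname!r}")
        if cfg.worker == "visual_flow":
            rf = cfg.rf
            if rf is None:
                rf = ReceptiveFieldSpec()
            elif isinstance(rf, dict):
                rf = ReceptiveFieldSpec(**rf)
            net.external_drive[lname] = dog_response(
                stim, rf, block.positions, dt=cfg.dt, t_end=cfg.t_end, gain=gain)
        elif cfg.worker == "prosthesis":
            per_frame = prosthesis_input(stim, block.spec.nx, block.spec.ny, gain)
            idx = np.minimum((np.arange(n_steps + 1) * cfg.dt * stim.fps).astype(int),
                             stim.n_frames - 1)
            net.external_drive[lname] = per_frame[idx]
    if cfg.worker == "none" and cfg.stimulus is not None:
        warnings.warn("worker 'none': configured stimulus is ignored", stacklevel=2)


# ---------------------------------------------------------------------------
# Assembly + run


def assemble(graph: Graph, registry: ModelRegistry | None = None,
             cell_params: dict | None = None, synapse_params: dict | None = None,
             dt: float = 1e-4) -> Network:
    """Build the global ODE system for a graph (wiring errors surface here)."""
    if registry is None:
        registry = load_builtin_registry()
    return Network(graph, registry, cell_params, synapse_params, dt=dt)


def _load_params(params) -> tuple[dict, dict]:
    if params is None:
        return {}, {}
    if isinstance(params, (str, Path)):
        params = json.loads(Path(params).read_text())
    return params.get("cells", {}), params.get("synapses", {})


def run(cfg: SessionConfig, registry: ModelRegistry | None = None,
        progress: bool = False) -> tuple[Recording, dict]:
    """Execute a session: assemble, integrate, record.

    Returns the recording and a run manifest.  Deterministic given the
    session (the seed covers any stochastic fixture content); if
    ``output_dir`` is set, one CSV per recorded (layer, variable) plus the
    manifest JSON are written there.
    """
    cfg.validate()
    if registry is None:
        registry = load_builtin_registry()
    graph = cfg.graph if isinstance(cfg.graph, Graph) else load_graph(cfg.graph,
                                                                      registry)
    cell_params, synapse_params = _load_params(cfg.params)
    net = Network(graph, registry, cell_params, synapse_params, dt=cfg.dt)

    n_steps = int(round(cfg.t_end / cfg.dt))
    stim = _resolve_stimulus(cfg) if cfg.worker != "none" else None
    _build_external(net, cfg, stim, n_steps)

    X = net.initial_state()
    net.reset_buffers(X)

    # recording setup
    rec_specs = []
    for r in cfg.record:
        block = net.layers.get(r["layer"])
        if block is None:
            raise ValidationError(f"record spec for unknown layer {r['layer']!r}")
        cells = r.get("cells", "all")
        ids = list(range(block.n)) if cells == "all" else [int(c) for c in cells]
        for cid in ids:
            if not 0 <= cid < block.n:
                raise ValidationError(f"record cell id {cid} out of range "
                                      f"for layer {r['layer']!r}")
        rec_specs.append((r["layer"], r["var"], ids))
        net.read_variable(X, r["layer"], r["var"])  # fail fast on bad vars

    n_rec = n_steps // cfg.record_stride + 1
    times = np.empty(n_rec)
    series = {(l, v): np.empty((n_rec, len(ids))) for l, v, ids in rec_specs}
    cells_map = {(l, v): ids for l, v, ids in rec_specs}

    def record(k_step: int, k_rec: int, Xc: np.ndarray):
        times[k_rec] = k_step * cfg.dt
        for l, v, ids in rec_specs:
            series[(l, v)][k_rec] = net.read_variable(Xc, l, v)[ids]

    record(0, 0, X)
    stepper = _STEPPERS[cfg.solver]
    k_rec = 1
    for k in range(n_steps):
        t = k * cfg.dt

        def f(tt, XX, _k=k):
            return net.derivative(tt, XX, ext_step=_k)

        X = stepper(f, t, X, cfg.dt)
        if not np.all(np.isfinite(X)):
            bad = int(np.flatnonzero(~np.isfinite(X))[0])
            layer, cid, var = net.locate(bad)
            raise IntegrationError(
                f"non-finite state at t={t + cfg.dt:.6g} s: layer {layer!r}, "
                f"cell {cid}, variable {var!r}")
        net.push_buffers(X)
        if (k + 1) % cfg.record_stride == 0:
            record(k + 1, k_rec, X)
            k_rec += 1

    recording = Recording(times=times[:k_rec], series={k: v[:k_rec]
                                                       for k, v in series.items()},
                          cells=cells_map)

    manifest = {
        "lamina_version": __version__,
        "seed": cfg.seed,
        "n_steps": n_steps,
        "n_state": net.n_state,
        "config": cfg.to_dict(),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        recording.write_csvs(out)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return recording, manifest
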