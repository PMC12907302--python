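"""Ready-made scenario builders.

Three worked examples ship with the package, each returning a
``(Graph, SessionConfig)`` pair that validates against the registry and
runs end-to-end at desk scale:

* **retinal waves** — a lattice of developing starburst amacrine cells
  (Morris–Lecar with acetylcholine release and a slow AHP current),
  coupled by nicotinic ACh synapses, no visual input;
* **retino-cortical** — three retinal layers (gain-control bipolar cells,
  amacrine cells, gain-control ganglion cells) driven by a movie through
  the receptive-field front end, feeding two cortical-column populations
  (excitatory and inhibitory) with delayed Gaussian lateral coupling;
* **Amari–Wilson–Cowan** — a single layer of rate units with Gaussian
  pooling weights and an erf sigmoid, under a constant external drive.

Lattice sizes, durations and parameter values are this package's own
defaults, chosen for clarity and desk-scale runtimes.  Builders are
deterministic given their arguments; the only randomness is the seeded
initial-condition jitter of the waves scenario, which breaks lattice
symmetry in an otherwise deterministic integrator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import SessionConfig
from .graph import Graph, LayerSpec, connect, save_graph

__all__ = [
    "AWCParams",
    "build_retinal_waves",
    "build_retino_cortical",
    "build_awc",
    "save_scenario",
    "SCENARIO_BUILDERS",
]


def build_retinal_waves(nx: int = 10, ny: int = 10, *, seed: int = 0,
                        connectivity: str = "nearest_neighbors",
                        sigma_p: float = 1.5, I_drive: float = 100.0,
                        t_end: float = 5.0, dt: float = 1e-3,
                        g_A: float = 3.0) -> tuple[Graph, SessionConfig]:
    """Developing-retina wave scenario: one SAC layer, ACh coupling.

    Each cell is a Morris–Lecar oscillator releasing acetylcholine with a
    slow after-hyperpolarisation current; ``I_drive`` (pA) sets the
    operating point.  Initial voltages are jittered uniformly (seeded) to
    break symmetry, standing in for the noise-driven wave nucleation of
    stochastic treatments — the integrator itself is deterministic.
    """
    if nx < 2 or ny < 2:
        raise ValueError("lattice must be at least 2x2")
    layer = LayerSpec(name="sac", cell_type="morris_lecar_ach_sahp",
                      nx=nx, ny=ny, spacing=0.05, modality="mm", z=0.0)
    if connectivity == "nearest_neighbors":
        edges = connect(layer, layer, "nearest_neighbors", "acetylcholine")
    elif connectivity == "gaussian":
        edges = connect(layer, layer, "gaussian", "acetylcholine",
                        sigma_p=sigma_p * layer.spacing)
    else:
        raise ValueError("connectivity must be nearest_neighbors or gaussian")

    rng = np.random.default_rng(seed)
    n = layer.n_cells
    init = {
        "V": (-60.0 + rng.uniform(-5.0, 15.0, n)).tolist(),
        "N": np.zeros(n).tolist(),
        "A": np.zeros(n).tolist(),
        "R": np.zeros(n).tolist(),
        "S": np.zeros(n).tolist(),
    }
    graph = Graph(layers=[layer], edges=edges, initial_values={"sac": init})

    session = SessionConfig(
        graph=graph,
        worker="none",
        external={"sac": {"constant": I_drive}},
        solver="rk4", dt=dt, t_end=t_end,
        record=[{"layer": "sac", "cells": "all", "var": "V"},
                {"layer": "sac", "cells": "all", "var": "A"}],
        record_stride=10,
        seed=seed,
        params={"synapses": {"acetylcholine": {"g_A": g_A}}},
    )
    return graph, session


def build_retino_cortical(nx: int = 8, ny: int = 8, *, seed: int = 0,
                          t_end: float = 1.0, dt: float = 1e-3,
                          spacing: float = 0.1,
                          w_exc: float = 20.0, w_inh: float = 10.0,
                          pool_sigma: float = 1.2,
                          cortical_sigma: float = 2.0,
                          cortical_gain_exc: float = 0.2,
                          cortical_gain_inh: float = 0.3,
                          conduction_velocity: float = 100.0,
                          stim_gain: float = 0.2,
                          bar_speed: float = 24.0,
                          disable_inhibition: bool = False,
                          ) -> tuple[Graph, SessionConfig]:
    """Retino-cortical scenario: 3 retinal + 2 cortical layers, moving bar.

    Bipolar cells (gain control) receive the receptive-field drive and
    excite amacrine and ganglion cells; amacrine cells inhibit both;
    ganglion firing rates feed the two cortical populations directly (no
    thalamus stage) through density-scaled relays; cortical columns couple
    laterally with Gaussian weights delayed by conduction velocity.
    Inhibitory couplings are encoded as negative edge weights multiplying
    the synapse rules' positive gains.
    """
    mk = lambda name, ctype, z: LayerSpec(name=name, cell_type=ctype, nx=nx,
                                          ny=ny, spacing=spacing, modality="mm",
                                          z=z)
    bipolar = mk("bipolar", "bipolar_gain_control", 0.0)
    amacrine = mk("amacrine", "linear_cell", 0.1)
    ganglion = mk("ganglion", "ganglion_gain_control", 0.2)
    ctx_exc = mk("cortex_exc", "cortical_excitatory", 1.0)
    ctx_inh = mk("cortex_inh", "cortical_inhibitory", 1.1)

    def scaled(edges, factor):
        for e in edges:
            e.weight *= factor
        return edges

    edges = []
    # retinal circuit: BC -> AC (rectified, excitatory), AC -> BC (linear, inhibitory)
    edges += scaled(connect(bipolar, amacrine, "one_to_one", "rectified"), w_exc)
    edges += scaled(connect(amacrine, bipolar, "one_to_one", "linear"),
                    0.0 if disable_inhibition else -w_inh)
    # BC -> RGC pooling over a Gaussian neighbourhood, AC -> RGC inhibition
    edges += scaled(connect(bipolar, ganglion, "gaussian", "bipolar_pooling",
                            sigma_p=pool_sigma * spacing),
                    w_exc * (2 * np.pi * (pool_sigma * spacing) ** 2))
    edges += scaled(connect(amacrine, ganglion, "one_to_one", "linear"),
                    0.0 if disable_inhibition else -w_inh)
    # RGC rates feed both cortical populations (density-scaled relay)
    edges += connect(ganglion, ctx_exc, "one_to_one", "retino_cortical")
    edges += connect(ganglion, ctx_inh, "one_to_one", "retino_cortical")
    # delayed Gaussian lateral cortical coupling
    sig = cortical_sigma * spacing
    norm = 2 * np.pi * sig ** 2  # so the d=0 coupling is gain*exp(0)
    edges += scaled(connect(ctx_exc, ctx_exc, "gaussian", "cortical_rate_delayed",
                            sigma_p=sig), cortical_gain_exc * norm)
    edges += scaled(connect(ctx_exc, ctx_inh, "gaussian", "cortical_rate_delayed",
                            sigma_p=sig), cortical_gain_exc * norm)
    edges += scaled(connect(ctx_inh, ctx_exc, "gaussian", "cortical_rate_delayed",
                            sigma_p=sig), -cortical_gain_inh * norm)
    edges += scaled(connect(ctx_inh, ctx_inh, "gaussian", "cortical_rate_delayed",
                            sigma_p=sig), -cortical_gain_inh * norm)

    layers = [bipolar, amacrine, ganglion, ctx_exc, ctx_inh]
    init = {
        "bipolar": {"A_B": [0.0] * bipolar.n_cells, "V": [0.0] * bipolar.n_cells},
        "amacrine": {"V": [0.0] * amacrine.n_cells},
        "ganglion": {"V": [0.0] * ganglion.n_cells,
                     "A_G": [0.0] * ganglion.n_cells},
        "cortex_exc": {"V": [-65.0] * ctx_exc.n_cells},
        "cortex_inh": {"V": [-65.0] * ctx_inh.n_cells},
    }
    graph = Graph(layers=layers, edges=edges, initial_values=init)

    field_px = 4 * max(nx, ny)
    session = SessionConfig(
        graph=graph,
        worker="visual_flow",
        stimulus={"kind": "moving_bar", "width": 4, "speed": bar_speed,
                  "duration": t_end, "fps": 30.0,
                  "size": [field_px, field_px],
                  "calibration": spacing * nx / field_px, "modality": "mm"},
        rf={"w_c": 1.0, "sigma_c": 1.5 * spacing, "w_s": 0.5,
            "sigma_s": 4.5 * spacing, "tau_rf": 0.02, "n_rf": 1},
        external={"bipolar": {"gain": stim_gain}},
        solver="rk4", dt=dt, t_end=t_end,
        record=[{"layer": "bipolar", "cells": "all", "var": "V"},
                {"layer": "amacrine", "cells": "all", "var": "V"},
                {"layer": "ganglion", "cells": "all", "var": "firingRate"},
                {"layer": "cortex_exc", "cells": "all", "var": "V"},
                {"layer": "cortex_inh", "cells": "all", "var": "V"},
                {"layer": "cortex_exc", "cells": "all", "var": "nu"}],
        record_stride=5,
        seed=seed,
        params={"cells": {"amacrine": {"E_L": 0.0, "tau": 0.05}},
                "synapses": {"linear": {"gain": 1.0},
                             "rectified": {"gain": 1.0},
                             "retino_cortical": {"weight": 200.0},
                             "cortical_rate_delayed":
                                 {"conduction_velocity": conduction_velocity}}},
    )
    return graph, session


@dataclass
class AWCParams:
    """Amari–Wilson–Cowan network parameters.

    tau: integration time (s); g: sigmoid gain (1/mV); sigma_p: Gaussian
    pooling width in lattice-spacing units; J0: pooling strength (mV/s) at
    distance zero before Gaussian normalisation; H_ext: external drive
    (mV/s).
    """
    tau: float = 0.05
    g: float = 0.5
    sigma_p: float = 2.0
    J0: float = 10.0
    H_ext: float = 5.0


def build_awc(nx: int = 16, ny: int = 16, p: AWCParams | None = None, *,
              seed: int = 0, t_end: float = 1.0, dt: float = 1e-3,
              ) -> tuple[Graph, SessionConfig]:
    """Amari–Wilson–Cowan rate network with Gaussian pooling.

    dV_i/dt = −V_i/τ + Σ_j J_ij f(V_j) + H_ext, with f the erf sigmoid of
    gain g (f(0) = 1/2) and J_ij Gaussian in the cell-to-cell distance
    (the zero-distance term included).  The OPL drive is a constant
    H_ext here; a movie-driven session only needs a different worker.
    """
    p = p or AWCParams()
    layer = LayerSpec(name="awc", cell_type="awc_cell", nx=nx, ny=ny,
                      spacing=1.0, modality="mm")
    sig = p.sigma_p * layer.spacing
    edges = connect(layer, layer, "gaussian", "awc_pooling", sigma_p=sig)
    # scale so that J_ii = J0 (Gaussian profile is 1/(2*pi*sig^2) at d=0)
    scale = p.J0 * 2 * np.pi * sig ** 2
    for e in edges:
        e.weight *= scale
    n = layer.n_cells
    graph = Graph(layers=[layer], edges=edges,
                  initial_values={"awc": {"V": [0.0] * n}})
    session = SessionConfig(
        graph=graph,
        worker="none",
        external={"awc": {"constant": p.H_ext}},
        solver="rk4", dt=dt, t_end=t_end,
        record=[{"layer": "awc", "cells": "all", "var": "V"}],
        record_stride=10,
        seed=seed,
        params={"cells": {"awc": {"tau": p.tau, "g": p.g}}},
    )
    return graph, session


SCENARIO_BUILDERS = {
    "retinal_waves": build_retinal_waves,
    "retino_cortical": build_retino_cortical,
    "awc": build_awc,
}


def save_scenario(graph: Graph, session: SessionConfig,
                  directory: str | Path, name: str) -> tuple[Path, Path]:
    """Write a scenario as ``<name>_graph.json`` + ``<name>_session.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gpath = directory / f"{name}_graph.json"
    spath = directory / f"{name}_session.json"
    save_graph(graph, gpath)
    d = session.to_dict()
    d["graph"] = gpath.name
    d["record_stride"] = session.record_stride
    spath.write_text(json.dumps(d, indent=1))
    return gpath, spath
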