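"""Engine: units, solver orders, vectorised assembly vs a per-edge
reference loop, conduction delays and session bookkeeping."""

import json
import warnings

import numpy as np
import pytest

from lamina.engine import (IntegrationError, Network, Recording, SessionConfig,
                           assemble, run, step)
from lamina.graph import Edge, Graph, LayerSpec, ValidationError, connect
from lamina.synapses import WiringError
from lamina.units import UnitError, convert_units


# ---------------------------------------------------------------------------
# units


@pytest.mark.parametrize("value,frm,to,expected", [
    (1000.0, "ms", "s", 1.0),
    (1.0, "V", "mV", 1000.0),
    (1.0, "nA", "pA", 1000.0),
    (1.0, "nS", "pS", 1000.0),
    (1.0, "mm", "um", 1000.0),
    (1.0, "nF", "pF", 1000.0),
    (1.0, "kHz", "Hz", 1000.0),
    (1.0, "mM", "nM", 1e6),
    (1.0, "uM", "nM", 1e3),
])
def test_unit_conversion_factors(value, frm, to, expected):
    assert convert_units(value, frm, to) == expected


@pytest.mark.parametrize("unit,other", [
    ("s", "ms"), ("mV", "V"), ("pA", "nA"), ("nS", "pS"), ("mm", "um"),
    ("nF", "pF"), ("Hz", "kHz"), ("nM", "mM"), ("nM", "uM"),
])
def test_unit_round_trips_are_exact(unit, other):
    for v in (0.0, 1.0, -3.7, 1234.5):
        assert convert_units(convert_units(v, unit, other), other, unit) == v


def test_per_area_units_need_membrane_area():
    assert convert_units(1.0, "uA/cm2", "pA", membrane_area_cm2=1e-5) == \
        pytest.approx(10.0)
    v = convert_units(5.0, "mS/cm2", "nS", membrane_area_cm2=2e-5)
    assert convert_units(v, "nS", "mS/cm2", membrane_area_cm2=2e-5) == \
        pytest.approx(5.0)
    with pytest.raises(UnitError):
        convert_units(1.0, "uA/cm2", "pA")


def test_cross_quantity_conversion_rejected():
    with pytest.raises(UnitError):
        convert_units(1.0, "mV", "pA")
    with pytest.raises(UnitError):
        convert_units(1.0, "bogus", "s")


# ---------------------------------------------------------------------------
# solvers


def _linear_errors(solver, dts):
    tau, V0 = 0.1, 1.0
    errs = []
    for dt in dts:
        n = int(round(0.5 / dt))
        V = np.array([V0])
        for k in range(n):
            V = step(lambda t, x: -x / tau, k * dt, V, dt, solver)
        errs.append(abs(V[0] - V0 * np.exp(-n * dt / tau)))
    return np.array(errs)


@pytest.mark.parametrize("solver,order", [("euler", 1), ("rk2", 2), ("rk4", 4)])
def test_empirical_convergence_order(solver, order):
    dts = np.array([4e-3, 2e-3, 1e-3])
    errs = _linear_errors(solver, dts)
    slopes = np.diff(np.log(errs)) / np.diff(np.log(dts))
    assert np.all(np.abs(slopes - order) < 0.3)


def test_rk4_linear_cell_error_below_tolerance():
    errs = _linear_errors("rk4", [1e-4])
    assert errs[0] < 1e-6


def test_rk45_matches_closed_form_tightly():
    tau = 0.05
    V = np.array([1.0])
    dt = 1e-2
    for k in range(50):
        V = step(lambda t, x: -x / tau, k * dt, V, dt, "rk45")
    assert V[0] == pytest.approx(np.exp(-0.5 / tau), rel=1e-6, abs=1e-10)


def test_zero_derivative_leaves_state_unchanged():
    X = np.array([1.0, -2.0])
    for solver in ("euler", "rk2", "rk4", "rk45"):
        assert np.array_equal(step(lambda t, x: 0.0 * x, 0.0, X, 0.1, solver), X)


def test_bad_solver_and_dt_rejected():
    with pytest.raises(ValidationError):
        step(lambda t, x: x, 0.0, np.zeros(1), -0.1, "rk4")
    with pytest.raises(ValidationError):
        step(lambda t, x: x, 0.0, np.zeros(1), 0.1, "leapfrog")


# ---------------------------------------------------------------------------
# assembly


def test_single_cell_network_equals_bare_rhs(registry):
    layer = LayerSpec(name="a", cell_type="linear_cell", nx=1, ny=1)
    g = Graph(layers=[layer], edges=[], initial_values={"a": {"V": [-40.0]}})
    net = assemble(g, registry)
    X = net.initial_state()
    tau, E_L = 0.1, -60.0
    assert net.derivative(0.0, X)[0] == pytest.approx(-(X[0] - E_L) / tau)


def test_gap_junction_pair_matches_hand_built_two_ode_system(registry):
    layer = LayerSpec(name="a", cell_type="linear_cell", nx=2, ny=1)
    edges = [Edge(("a", 0), ("a", 1), "gap_junction"),
             Edge(("a", 1), ("a", 0), "gap_junction")]
    g = Graph(layers=[layer], edges=edges,
              initial_values={"a": {"V": [-80.0, -40.0]}})
    net = assemble(g, registry)
    X = net.initial_state()
    tau, E_L, wg = 0.1, -60.0, 10.0

    def hand(V):
        return np.array([-(V[0] - E_L) / tau - wg * (V[0] - V[1]),
                         -(V[1] - E_L) / tau - wg * (V[1] - V[0])])

    assert np.allclose(net.derivative(0.0, X), hand(X), rtol=1e-14)


def test_gap_pair_coupling_sums_to_zero_and_voltages_converge(registry):
    layer = LayerSpec(name="a", cell_type="linear_cell", nx=2, ny=1)
    edges = [Edge(("a", 0), ("a", 1), "gap_junction"),
             Edge(("a", 1), ("a", 0), "gap_junction")]
    g = Graph(layers=[layer], edges=edges,
              initial_values={"a": {"V": [-80.0, -40.0]}})
    cfg = SessionConfig(graph=g, dt=1e-4, t_end=1.0,
                        record=[{"layer": "a", "cells": "all", "var": "V"}])
    rec, _ = run(cfg, registry)
    V = rec.series[("a", "V")]
    # the instantaneous gap contributions are exactly opposite at every step
    coupling = -10.0 * (V[:, 1] - V[:, 0]) + -10.0 * (V[:, 0] - V[:, 1])
    assert np.max(np.abs(coupling)) == 0.0
    assert abs(V[-1, 0] - V[-1, 1]) < 1e-6  # common voltage reached


def test_vectorised_assembly_matches_per_edge_reference_loop(registry, rng):
    """Random <=10-cell two-layer graph: engine derivative vs naive loop."""
    pre = LayerSpec(name="p", cell_type="bipolar_gain_control", nx=2, ny=2)
    post = LayerSpec(name="q", cell_type="ganglion_gain_control", nx=2, ny=2)
    edges = []
    for _ in range(12):
        i, j = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        edges.append(Edge(("p", i), ("q", j), "bipolar_pooling",
                          weight=float(rng.uniform(-2, 2))))
    for _ in range(4):
        i, j = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        if i != j:
            edges.append(Edge(("p", i), ("p", j), "linear",
                              weight=float(rng.uniform(-1, 1))))
    init = {"p": {"A_B": rng.uniform(0, 2, 4).tolist(),
                  "V": rng.uniform(-10, 10, 4).tolist()},
            "q": {"V": rng.uniform(-10, 10, 4).tolist(),
                  "A_G": rng.uniform(0, 2, 4).tolist()}}
    g = Graph(layers=[pre, post], edges=edges, initial_values=init)
    net = assemble(g, registry)
    X = net.initial_state()
    got = net.derivative(0.0, X)

    # naive reference: per cell, per edge
    A_B = np.array(init["p"]["A_B"])
    Vp = np.array(init["p"]["V"])
    Vq = np.array(init["q"]["V"])
    A_G = np.array(init["q"]["A_G"])
    vsyn_p = np.zeros(4)
    vsyn_q = np.zeros(4)
    for e in edges:
        if e.synapse_type == "linear":
            vsyn_p[e.post[1]] += e.weight * Vp[e.pre[1]]
        else:
            br = max(Vp[e.pre[1]] - 0.0, 0.0) / (1.0 + A_B[e.pre[1]])
            vsyn_q[e.post[1]] += e.weight * br
    dA_B = -A_B / 0.2 + 1.0 * np.maximum(Vp, 0.0)
    dVp = -(Vp - 0.0) / 0.05 + vsyn_p
    dVq = -(Vq - 0.0) / 0.05 + vsyn_q
    dA_G = -A_G / 0.2 + 1.0 * np.maximum(Vq, 0.0)
    want = np.concatenate([dA_B, dVp, dVq, dA_G])
    assert np.allclose(got, want, rtol=1e-12, atol=1e-12)


def test_output_kind_slot_mismatch_is_a_wiring_error(registry):
    # retino_cortical produces a firing rate; linear_cell has no FR slot
    pre = LayerSpec(name="p", cell_type="ganglion_gain_control", nx=1, ny=1)
    post = LayerSpec(name="q", cell_type="linear_cell", nx=1, ny=1, z=1.0)
    g = Graph(layers=[pre, post],
              edges=[Edge(("p", 0), ("q", 0), "retino_cortical")],
              initial_values={"p": {"V": [0.0], "A_G": [0.0]},
                              "q": {"V": [0.0]}})
    with pytest.raises(WiringError, match="slot"):
        assemble(g, registry)


def test_missing_pre_output_is_a_wiring_error(registry):
    # acetylcholine reads the pre cell's ACh concentration "A"
    pre = LayerSpec(name="p", cell_type="linear_cell", nx=1, ny=1)
    post = LayerSpec(name="q", cell_type="morris_lecar", nx=1, ny=1, z=1.0)
    g = Graph(layers=[pre, post],
              edges=[Edge(("p", 0), ("q", 0), "acetylcholine")],
              initial_values={"p": {"V": [0.0]},
                              "q": {"V": [-60.0], "N": [0.0]}})
    with pytest.raises(WiringError, match="pre output"):
        assemble(g, registry)


# ---------------------------------------------------------------------------
# delays


def _delayed_chain(registry, v_C, dt=1e-3):
    pre = LayerSpec(name="p", cell_type="cortical_excitatory", nx=2, ny=1,
                    spacing=1.0)
    post = LayerSpec(name="q", cell_type="cortical_inhibitory", nx=2, ny=1,
                     spacing=1.0, z=1.0)
    edges = connect(pre, post, "fully_connected", "cortical_rate_delayed",
                    weight_const=0.5)
    g = Graph(layers=[pre, post],
              initial_values={"p": {"V": [-40.0, -60.0]},
                              "q": {"V": [-65.0, -65.0]}}, edges=edges)
    cfg = SessionConfig(graph=g, dt=dt, t_end=0.2,
                        params={"synapses": {"cortical_rate_delayed":
                                             {"conduction_velocity": v_C}}},
                        record=[{"layer": "q", "cells": "all", "var": "V"}])
    return run(cfg, registry)


def test_infinite_conduction_velocity_equals_instantaneous(registry):
    rec_fast, _ = _delayed_chain(registry, v_C=1e12)
    # instantaneous comparison: same graph wired with the undelayed type
    pre = LayerSpec(name="p", cell_type="cortical_excitatory", nx=2, ny=1)
    post = LayerSpec(name="q", cell_type="cortical_inhibitory", nx=2, ny=1,
                     z=1.0)
    edges = connect(pre, post, "fully_connected", "cortical_rate",
                    weight_const=0.5)
    g = Graph(layers=[pre, post],
              initial_values={"p": {"V": [-40.0, -60.0]},
                              "q": {"V": [-65.0, -65.0]}}, edges=edges)
    cfg = SessionConfig(graph=g, dt=1e-3, t_end=0.2,
                        record=[{"layer": "q", "cells": "all", "var": "V"}])
    rec_none, _ = run(cfg, registry)
    diff = np.max(np.abs(rec_fast.series[("q", "V")]
                         - rec_none.series[("q", "V")]))
    assert diff <= 1e-12


def test_finite_delay_shifts_the_response(registry):
    rec_fast, _ = _delayed_chain(registry, v_C=1e12)
    rec_slow, _ = _delayed_chain(registry, v_C=20.0)  # 1 mm / 20 mm/s = 50 ms
    Vf = rec_fast.series[("q", "V")]
    Vs = rec_slow.series[("q", "V")]
    assert not np.allclose(Vf, Vs)
    # pre-layer voltages decay toward rest, so the delayed run sees the
    # older (stronger) rates and is driven harder early on
    assert Vs[10, 0] > Vf[10, 0]


# ---------------------------------------------------------------------------
# run-level behaviour


def _awc_session(registry, **over):
    layer = LayerSpec(name="a", cell_type="awc_cell", nx=2, ny=2)
    g = Graph(layers=[layer], edges=[],
              initial_values={"a": {"V": [0.0, 1.0, -1.0, 2.0]}})
    kw = dict(graph=g, dt=1e-3, t_end=0.1,
              external={"a": {"constant": 5.0}},
              record=[{"layer": "a", "cells": "all", "var": "V"}])
    kw.update(over)
    return SessionConfig(**kw)


def test_same_session_twice_is_bit_identical(registry):
    r1, m1 = run(_awc_session(registry), registry)
    r2, m2 = run(_awc_session(registry), registry)
    assert np.array_equal(r1.series[("a", "V")], r2.series[("a", "V")])
    assert m1["config_hash"] == m2["config_hash"]


def test_recording_shapes_and_stride(registry):
    cfg = _awc_session(registry, t_end=1.0, dt=1e-3, record_stride=10)
    rec, _ = run(cfg, registry)
    assert rec.times.shape == (101,)
    assert rec.series[("a", "V")].shape == (101, 4)
    assert np.all(np.diff(rec.times) > 0)


def test_recording_is_noninvasive(registry):
    full = _awc_session(registry)
    none = _awc_session(registry, record=[{"layer": "a", "cells": [0],
                                           "var": "V"}])
    r1, _ = run(full, registry)
    r2, _ = run(none, registry)
    assert r1.series[("a", "V")][-1, 0] == r2.series[("a", "V")][-1, 0]


def test_worker_none_ignores_configured_stimulus_with_warning(registry):
    cfg = _awc_session(registry,
                       stimulus={"kind": "full_field", "level": 100.0},
                       external={"a": {"gain": 1.0}})
    with pytest.warns(UserWarning, match="ignored"):
        rec, _ = run(cfg, registry)
    # no drive reaches the cells: pure decay toward 0
    assert abs(rec.series[("a", "V")][-1]).max() < 2.0


def test_csv_output_and_manifest(registry, tmp_path):
    cfg = _awc_session(registry, output_dir=tmp_path)
    run(cfg, registry)
    csv = tmp_path / "a__V.csv"
    assert csv.exists()
    header = csv.read_text().splitlines()[0]
    assert header == "t,cell_0,cell_1,cell_2,cell_3"
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["n_state"] == 4 and "config_hash" in manifest


def test_nonfinite_state_raises_with_location(registry):
    layer = LayerSpec(name="a", cell_type="linear_cell", nx=1, ny=1)
    g = Graph(layers=[layer], edges=[],
              initial_values={"a": {"V": [1.0]}})
    cfg = SessionConfig(graph=g, dt=1e3, t_end=1e5, solver="euler",
                        record=[])
    cfg.params = {"cells": {"a": {"tau": 1e-6}}}  # wildly stiff -> blow-up
    with pytest.raises(IntegrationError, match="layer 'a'"):
        run(cfg, registry)


def test_session_file_round_trip_and_validation(registry, tmp_path):
    from lamina.graph import save_graph

    layer = LayerSpec(name="a", cell_type="awc_cell", nx=2, ny=2)
    g = Graph(layers=[layer], edges=[],
              initial_values={"a": {"V": [0.0] * 4}})
    save_graph(g, tmp_path / "g.json")
    session = {"graph": "g.json", "worker": "none", "solver": "rk4",
               "dt": 1e-3, "t_end": 0.05,
               "external": {"a": {"constant": 2.0}},
               "record": [{"layer": "a", "cells": "all", "var": "V"}]}
    spath = tmp_path / "s.json"
    spath.write_text(json.dumps(session))
    cfg = SessionConfig.from_file(spath)
    rec, _ = run(cfg, registry)
    assert rec.series[("a", "V")].shape[1] == 4

    session["solver"] = "bogus"
    spath.write_text(json.dumps(session))
    with pytest.raises(ValidationError):
        SessionConfig.from_file(spath)
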