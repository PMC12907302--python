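"""Model registry: builtin loading, round trips, protection, and the
compiled-vs-hand-coded oracle equivalence for every shipped model."""

import json

import numpy as np
import pytest

import lamina.cells as C
import lamina.synapses as S
from lamina.registry import (NotFoundError, ProtectionError, SchemaError,
                             def_from_dict, def_to_dict, load_builtin_registry,
                             load_type, save_type)

# ---------------------------------------------------------------------------
# hand-coded twins of every builtin definition

def _p(cls, env):
    return cls(**{f: env[f] for f in cls.__dataclass_fields__ if f in env})


CELL_ORACLES = {
    "linear_cell": lambda e: {"V": C.linear_cell_rhs(
        e["V"], _p(C.LinearCellParams, e), e["V_syn"])},
    "linear_pharma_cell": lambda e: {"V": C.pharma_cell_rhs(
        e["V"], _p(C.LinearCellParams, e), e["I_syn"])},
    "neurotransmitter_amacrine": lambda e: dict(zip(
        ("T", "V", "n"), C.neurotransmitter_amacrine_rhs(
            e["T"], e["V"], e["n"], _p(C.NeurotransmitterCellParams, e),
            e["I_syn"]))),
    "bipolar_gain_control": lambda e: dict(zip(
        ("A_B", "V"), C.gain_control_bipolar_rhs(
            e["A_B"], e["V"], _p(C.GainControlParams, e), e["ext"], e["V_syn"]))),
    "ganglion_gain_control": lambda e: dict(zip(
        ("V", "A_G"), C.gain_control_ganglion_rhs(
            e["V"], e["A_G"], _p(C.GainControlParams, e), e["V_syn"]))),
    "electrode": lambda e: {"V": C.electrode_rhs(e["V"], e["tau"], e["C"],
                                                 e["ext"])},
    "morris_lecar": lambda e: dict(zip(
        ("V", "N"), C.morris_lecar_rhs(e["V"], e["N"],
                                       _p(C.MorrisLecarParams, e),
                                       e["ext"], e["I_syn"]))),
    "morris_lecar_ach": lambda e: dict(zip(
        ("V", "N", "A"), C.morris_lecar_ach_rhs(
            e["V"], e["N"], e["A"], _p(C.MorrisLecarParams, e),
            e["ext"], e["I_syn"]))),
    "morris_lecar_ach_sahp": lambda e: dict(zip(
        ("V", "N", "A", "R", "S"), C.morris_lecar_ach_sahp_rhs(
            e["V"], e["N"], e["A"], e["R"], e["S"],
            _p(C.MorrisLecarParams, e), e["ext"], e["I_syn"]))),
    "hodgkin_huxley": lambda e: dict(zip(
        ("V", "m", "h", "n"), C.hodgkin_huxley_rhs(
            e["V"], e["m"], e["h"], e["n"], _p(C.HodgkinHuxleyParams, e),
            e["ext"], e["I_syn"]))),
    "cortical_excitatory": lambda e: {"V": C.cortical_column_rhs(
        e["V"], _p(C.CorticalColumnParams, e), e["FR_syn"])},
    "cortical_inhibitory": lambda e: {"V": C.cortical_column_rhs(
        e["V"], _p(C.CorticalColumnParams, e), e["FR_syn"])},
    "awc_cell": lambda e: {"V": C.awc_rhs(e["V"], _p(C.AWCCellParams, e),
                                          e["V_syn"], e["ext"])},
}

CELL_OUTPUT_ORACLES = {
    "bipolar_gain_control": {
        "bipolarResponse": lambda e: C.bipolar_response(
            e["A_B"], e["V"], _p(C.GainControlParams, e))},
    "ganglion_gain_control": {
        "firingRate": lambda e: C.ganglion_firing_rate(
            e["V"], e["A_G"], _p(C.GainControlParams, e))},
    "cortical_excitatory": {
        "nu": lambda e: C.cortical_transfer(e["V"],
                                            _p(C.CorticalColumnParams, e))},
    "cortical_inhibitory": {
        "nu": lambda e: C.cortical_transfer(e["V"],
                                            _p(C.CorticalColumnParams, e))},
    "awc_cell": {"f": lambda e: C.awc_sigmoid(e["V"], e["g"])},
}

SYNAPSE_ORACLES = {
    "acetylcholine": lambda e, p: S.ach_current(e["pre_A"], e["post_V"], p,
                                                e["w"]),
    "rectified": lambda e, p: S.rectified_psp(e["pre_V"], p, e["w"]),
    "linear": lambda e, p: S.linear_psp(e["pre_V"], p, e["w"]),
    "bipolar_pooling": lambda e, p: S.pooling_psp(e["pre_bipolarResponse"], p,
                                                  e["w"]),
    "gap_junction": lambda e, p: S.gap_junction_psp(e["pre_V"], e["post_V"], p,
                                                    e["w"]),
    "cortical_rate": lambda e, p: S.cortical_rate_coupling(e["pre_nu"], p,
                                                           e["w"]),
    "cortical_rate_delayed": lambda e, p: S.cortical_rate_coupling(
        e["pre_nu"], p, e["w"]),
    "ligand_gated": lambda e, p: S.ligand_gated_psp(e["pre_n"], e["pre_V"],
                                                    e["post_V"], p, e["w"]),
    "retino_cortical": lambda e, p: S.retino_cortical_rate(e["pre_firingRate"],
                                                           p, e["w"]),
    "awc_pooling": lambda e, p: S.cortical_rate_coupling(e["pre_f"], p, e["w"]),
}

STATE_RANGES = {"V": (-80.0, 40.0), "N": (0.0, 1.0), "m": (0.0, 1.0),
                "h": (0.0, 1.0), "n": (0.0, 1.0), "T": (0.0, 50.0),
                "A": (0.0, 100.0), "A_B": (0.0, 10.0), "A_G": (0.0, 10.0),
                "R": (0.0, 1.0), "S": (0.0, 1.0)}


def _random_env(ctype, rng):
    env = {}
    for sv in ctype.state_vars:
        lo, hi = STATE_RANGES[sv.name]
        env[sv.name] = rng.uniform(lo, hi)
    for p in ctype.params:
        scale = rng.uniform(0.5, 1.5)
        val = p.default * scale if p.default != 0 else rng.uniform(-1, 1)
        if p.min is not None:
            val = max(val, p.min)
        if p.max is not None:
            val = min(val, p.max)
        env[p.name] = val
    for slot, sym in (("external", "ext"), ("synaptic_current", "I_syn"),
                      ("synaptic_voltage_rate", "V_syn"),
                      ("synaptic_firing_rate", "FR_syn")):
        if slot in ctype.input_slots:
            env[sym] = rng.uniform(-50.0, 50.0)
    return env


def test_every_builtin_cell_has_an_oracle(registry):
    assert set(registry.names("cell")) == set(CELL_ORACLES)


def test_every_builtin_synapse_has_an_oracle(registry):
    assert set(registry.names("synapse")) == set(SYNAPSE_ORACLES)


@pytest.mark.parametrize("name", sorted(CELL_ORACLES))
def test_compiled_cell_rhs_matches_hand_coded(registry, name, rng):
    ctype = registry[name]
    for _ in range(100):
        env = _random_env(ctype, rng)
        got = ctype.eval_rhs(env)
        want = CELL_ORACLES[name](env)
        for var in want:
            assert got[var] == pytest.approx(want[var], rel=1e-12, abs=1e-12), var


@pytest.mark.parametrize("name", sorted(CELL_OUTPUT_ORACLES))
def test_compiled_cell_outputs_match_hand_coded(registry, name, rng):
    ctype = registry[name]
    for _ in range(100):
        env = _random_env(ctype, rng)
        got = ctype.eval_outputs(env)
        for oname, fn in CELL_OUTPUT_ORACLES[name].items():
            assert got[oname] == pytest.approx(fn(env), rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("name", sorted(SYNAPSE_ORACLES))
def test_compiled_synapse_rule_matches_hand_coded(registry, name, rng):
    sdef = registry[name]
    for _ in range(100):
        params = {p.name: max(p.default * rng.uniform(0.5, 1.5), p.min or -1e9)
                  for p in sdef.params}
        if "literal" in params:
            params["literal"] = float(rng.integers(0, 2))
        env = dict(params)
        env["w"] = rng.uniform(-2.0, 2.0)
        for sym in sdef.rule.symbols:
            if sym.startswith(("pre_", "post_")):
                lo, hi = (0.0, 1.0) if sym.endswith("_n") else (-70.0, 70.0)
                if sym in ("pre_A", "pre_nu", "pre_f", "pre_firingRate",
                           "pre_bipolarResponse"):
                    lo, hi = 0.0, 50.0
                env[sym] = rng.uniform(lo, hi)
        got = sdef.rule(env)
        p = S.SynapseParams(**{k: v for k, v in params.items()
                               if k in S.SynapseParams.__dataclass_fields__})
        want = SYNAPSE_ORACLES[name](env, p)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_delayed_flag_follows_conduction_velocity_parameter(registry):
    assert registry["cortical_rate_delayed"].delayed
    assert not registry["cortical_rate"].delayed


def test_builtin_defaults_match_dataclass_defaults(registry):
    pairs = [("linear_cell", C.LinearCellParams),
             ("morris_lecar", C.MorrisLecarParams),
             ("hodgkin_huxley", C.HodgkinHuxleyParams),
             ("cortical_excitatory", C.CorticalColumnParams),
             ("awc_cell", C.AWCCellParams)]
    for name, cls in pairs:
        defaults = registry[name].default_params()
        for pname, val in defaults.items():
            if pname in cls.__dataclass_fields__:
                assert cls.__dataclass_fields__[pname].default == val, (name,
                                                                        pname)


# ---------------------------------------------------------------------------
# file handling, round trips, protection


def test_linear_cell_builtin_has_single_state_var(registry):
    ctype = registry["linear_cell"]
    assert [sv.name for sv in ctype.state_vars] == ["V"]


def test_save_then_load_round_trips_every_builtin(registry, tmp_path):
    for name in registry.names():
        tdef = registry[name]
        path = tmp_path / f"{name}.json"
        save_type(tdef, path)
        again = load_type(path)
        assert def_to_dict(again) == def_to_dict(tdef)


def test_json_missing_rhs_is_a_validation_error():
    with pytest.raises(SchemaError, match="rhs"):
        def_from_dict({"name": "x", "kind": "cell",
                       "state_vars": [{"name": "V"}], "outputs": {"V": "V"}})


def test_rhs_state_var_mismatch_is_rejected():
    with pytest.raises(SchemaError):
        def_from_dict({"name": "x", "kind": "cell",
                       "state_vars": [{"name": "V"}],
                       "rhs": {"V": "-V", "W": "-W"}, "outputs": {}})


def test_undeclared_symbol_in_rhs_is_rejected():
    with pytest.raises(SchemaError, match="tau"):
        def_from_dict({"name": "x", "kind": "cell",
                       "state_vars": [{"name": "V"}], "params": [],
                       "rhs": {"V": "-V/tau"}, "outputs": {}})


def test_outputs_may_not_reference_input_slots():
    with pytest.raises(SchemaError):
        def_from_dict({"name": "x", "kind": "cell",
                       "state_vars": [{"name": "V"}], "params": [],
                       "input_slots": ["synaptic_voltage_rate"],
                       "rhs": {"V": "-V + V_syn"}, "outputs": {"bad": "V_syn"}})


def test_user_type_lifecycle_create_delete(tmp_path):
    reg = load_builtin_registry(user_dir=tmp_path)
    custom = def_from_dict({
        "name": "my_cell", "kind": "cell",
        "state_vars": [{"name": "V", "unit": "mV"}],
        "params": [{"name": "tau", "default": 0.1, "unit": "s"}],
        "input_slots": [], "rhs": {"V": "-V/tau"}, "outputs": {"V": "V"}})
    path = reg.add_user_type(custom)
    assert path.exists() and "my_cell" in reg

    reg2 = load_builtin_registry(user_dir=tmp_path)  # persisted
    assert "my_cell" in reg2

    reg.delete_type("my_cell")
    assert "my_cell" not in reg and not path.exists()


def test_deleting_protected_type_raises(registry):
    with pytest.raises(ProtectionError):
        registry.delete_type("cortical_excitatory")
    assert "cortical_excitatory" in registry


def test_overwriting_protected_type_raises(registry):
    impostor = def_from_dict({
        "name": "cortical_excitatory", "kind": "cell",
        "state_vars": [{"name": "V"}], "params": [],
        "rhs": {"V": "-V"}, "outputs": {"V": "V"}})
    before = def_to_dict(registry["cortical_excitatory"])
    with pytest.raises(ProtectionError):
        registry.register(impostor)
    assert def_to_dict(registry["cortical_excitatory"]) == before


def test_deleting_unknown_type_raises(registry):
    with pytest.raises(NotFoundError):
        registry.delete_type("no_such_type")


def test_only_the_two_cortical_cells_are_protected(registry):
    protected = [n for n in registry.names() if registry[n].protected]
    assert protected == ["cortical_excitatory", "cortical_inhibitory"]
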