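"""Declarative cell/synapse type definitions and their registry.

A model type is data: a JSON document naming state variables, parameters,
input slots and equation text.  At load time every equation is compiled
(:mod:`lamina.expr`) into a vectorised callable, so a definition behaves
exactly like hand-written code without any code generation step.

Input slots map to fixed symbol names inside the equations:

=========================  ========
slot                       symbol
=========================  ========
external                   ``ext``
synaptic_current           ``I_syn``
synaptic_voltage_rate      ``V_syn``
synaptic_firing_rate       ``FR_syn``
=========================  ========

Synapse rules may reference their own parameters, the geometric edge
weight ``w``, and pre/post cell outputs as ``pre_<output>`` /
``post_<output>``; which outputs actually exist is checked when a graph is
wired, not at compile time.

A handful of shipped definitions are *protected* (the two cortical-column
populations): they cannot be overwritten or deleted.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

from .expr import Expression, ExpressionError, compile_expression

__all__ = [
    "SLOT_SYMBOLS",
    "StateVar",
    "Param",
    "CellTypeDef",
    "SynapseTypeDef",
    "ModelRegistry",
    "RegistryError",
    "ProtectionError",
    "NotFoundError",
    "SchemaError",
    "load_type",
    "save_type",
    "load_builtin_registry",
]

SLOT_SYMBOLS = {
    "external": "ext",
    "synaptic_current": "I_syn",
    "synaptic_voltage_rate": "V_syn",
    "synaptic_firing_rate": "FR_syn",
}

OUTPUT_KINDS = ("current", "voltage_rate", "firing_rate")

#: synapse output kind -> the post-cell input slot it feeds
KIND_TO_SLOT = {
    "current": "synaptic_current",
    "voltage_rate": "synaptic_voltage_rate",
    "firing_rate": "synaptic_firing_rate",
}


class RegistryError(ValueError):
    pass


class ProtectionError(RegistryError):
    pass


class NotFoundError(RegistryError, KeyError):
    pass


class SchemaError(RegistryError):
    """Definition JSON violates the schema; ``fields`` lists failures."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = fields or []
        if self.fields:
            message = f"{message}: {', '.join(self.fields)}"
        super().__init__(message)


@dataclass(frozen=True)
class StateVar:
    name: str
    unit: str = ""


@dataclass(frozen=True)
class Param:
    name: str
    default: float
    unit: str = ""
    min: float | None = None
    max: float | None = None


@dataclass
class CellTypeDef:
    """A named ODE cell model: state, parameters, inputs, vector field."""

    name: str
    state_vars: list[StateVar]
    params: list[Param]
    input_slots: list[str]
    rhs: dict[str, Expression]        # state var -> dX/dt expression
    outputs: dict[str, Expression]    # quantities readable by synapses
    aux_functions: dict[str, tuple[tuple[str, ...], str]] = field(default_factory=dict)
    protected: bool = False
    _raw: dict | None = field(default=None, repr=False, compare=False)

    @property
    def kind(self) -> str:
        return "cell"

    def default_params(self) -> dict[str, float]:
        return {p.name: p.default for p in self.params}

    def symbol_table(self) -> set[str]:
        syms = {sv.name for sv in self.state_vars} | {p.name for p in self.params}
        syms |= {SLOT_SYMBOLS[s] for s in self.input_slots}
        return syms

    def eval_rhs(self, env: dict) -> dict:
        """Evaluate the vector field at a symbol assignment.

        ``env`` maps every state var, param and input-slot symbol to a
        scalar or array; missing input slots default to 0.
        """
        full = dict(env)
        for s in self.input_slots:
            full.setdefault(SLOT_SYMBOLS[s], 0.0)
        return {var: e(full) for var, e in self.rhs.items()}

    def eval_outputs(self, env: dict) -> dict:
        return {name: e(env) for name, e in self.outputs.items()}


@dataclass
class SynapseTypeDef:
    """A named coupling rule producing a current, voltage rate or firing rate."""

    name: str
    params: list[Param]
    output_kind: str
    rule: Expression
    protected: bool = False
    _raw: dict | None = field(default=None, repr=False, compare=False)

    @property
    def kind(self) -> str:
        return "synapse"

    @property
    def delayed(self) -> bool:
        """Delayed iff the type declares a ``conduction_velocity`` parameter."""
        return any(p.name == "conduction_velocity" for p in self.params)

    def default_params(self) -> dict[str, float]:
        return {p.name: p.default for p in self.params}

    @property
    def pre_outputs(self) -> set[str]:
        """Names of pre-synaptic cell outputs the rule reads."""
        return {s[4:] for s in self.rule.symbols if s.startswith("pre_")}

    @property
    def post_outputs(self) -> set[str]:
        return {s[5:] for s in self.rule.symbols if s.startswith("post_")}

    def evaluate(self, pre: dict, post: dict, w, params: dict):
        env = {f"pre_{k}": v for k, v in pre.items()}
        env.update({f"post_{k}": v for k, v in post.items()})
        env["w"] = w
        env.update(params)
        return self.rule(env)


# ---------------------------------------------------------------------------
# (de)serialisation


def _parse_params(raw, where: str) -> list[Param]:
    out = []
    for k, pd in enumerate(raw):
        if "name" not in pd or "default" not in pd:
            raise SchemaError(f"{where}[{k}] needs name and default",
                              sorted({"name", "default"} - set(pd)))
        out.append(Param(pd["name"], float(pd["default"]), pd.get("unit", ""),
                         pd.get("min"), pd.get("max")))
    return out


def def_from_dict(data: dict) -> CellTypeDef | SynapseTypeDef:
    """Build (and compile) a type definition from its JSON dict."""
    kind = data.get("kind")
    if kind not in ("cell", "synapse"):
        raise SchemaError("kind must be 'cell' or 'synapse'", ["kind"])
    if "name" not in data:
        raise SchemaError("missing name", ["name"])
    name = data["name"]
    protected = bool(data.get("protected", False))
    try:
        if kind == "cell":
            missing = sorted({"state_vars", "rhs", "outputs"} - set(data))
            if missing:
                raise SchemaError(f"cell {name!r} missing sections", missing)
            state_vars = [StateVar(sv["name"], sv.get("unit", ""))
                          for sv in data["state_vars"]]
            params = _parse_params(data.get("params", []), "params")
            slots = list(data.get("input_slots", []))
            bad_slots = sorted(set(slots) - set(SLOT_SYMBOLS))
            if bad_slots:
                raise SchemaError(f"cell {name!r} has unknown input slots", bad_slots)
            aux = {k: (tuple(v["args"]), v["expr"])
                   for k, v in data.get("aux_functions", {}).items()}
            table = ({sv.name for sv in state_vars} | {p.name for p in params}
                     | {SLOT_SYMBOLS[s] for s in slots})
            rhs_src = data["rhs"]
            if set(rhs_src) != {sv.name for sv in state_vars}:
                raise SchemaError(
                    f"cell {name!r}: rhs must cover exactly the state vars",
                    sorted(set(rhs_src) ^ {sv.name for sv in state_vars}))
            rhs = {var: compile_expression(src, table, aux)
                   for var, src in rhs_src.items()}
            # outputs may reference only state vars and params
            out_table = {sv.name for sv in state_vars} | {p.name for p in params}
            outputs = {oname: compile_expression(src, out_table, aux)
                       for oname, src in data["outputs"].items()}
            return CellTypeDef(name=name, state_vars=state_vars, params=params,
                               input_slots=slots, rhs=rhs, outputs=outputs,
                               aux_functions=aux, protected=protected, _raw=data)
        else:
            missing = sorted({"rule", "output_kind"} - set(data))
            if missing:
                raise SchemaError(f"synapse {name!r} missing sections", missing)
            if data["output_kind"] not in OUTPUT_KINDS:
                raise SchemaError(f"synapse {name!r}: bad output_kind",
                                  [data["output_kind"]])
            params = _parse_params(data.get("params", []), "params")
            table = {p.name for p in params} | {"w"}
            # pre_*/post_* endpoint symbols resolve at graph wiring time
            deferred = {s for s in _free_symbols(data["rule"])
                        if s.startswith(("pre_", "post_"))}
            rule = compile_expression(data["rule"], table | deferred)
            return SynapseTypeDef(name=name, params=params,
                                  output_kind=data["output_kind"], rule=rule,
                                  protected=protected, _raw=data)
    except ExpressionError as exc:
        raise SchemaError(f"{kind} {name!r}: {exc}") from exc


def _free_symbols(src: str) -> set[str]:
    from .expr import _Parser, _symbols_of, _tokenize, normalize_latex
    return _symbols_of(_Parser(_tokenize(normalize_latex(src))).parse())


def def_to_dict(tdef: CellTypeDef | SynapseTypeDef) -> dict:
    """Canonical JSON dict of a definition (inverse of :func:`def_from_dict`)."""

    def params_out(params):
        out = []
        for p in params:
            d = {"name": p.name, "default": p.default, "unit": p.unit}
            if p.min is not None:
                d["min"] = p.min
            if p.max is not None:
                d["max"] = p.max
            out.append(d)
        return out

    if isinstance(tdef, CellTypeDef):
        return {
            "name": tdef.name,
            "kind": "cell",
            "state_vars": [{"name": sv.name, "unit": sv.unit}
                           for sv in tdef.state_vars],
            "params": params_out(tdef.params),
            "input_slots": list(tdef.input_slots),
            "aux_functions": {k: {"args": list(args), "expr": src}
                              for k, (args, src) in tdef.aux_functions.items()},
            "rhs": {var: e.src for var, e in tdef.rhs.items()},
            "outputs": {k: e.src for k, e in tdef.outputs.items()},
            "protected": tdef.protected,
        }
    return {
        "name": tdef.name,
        "kind": "synapse",
        "params": params_out(tdef.params),
        "output_kind": tdef.output_kind,
        "rule": tdef.rule.src,
        "protected": tdef.protected,
    }


def load_type(path: str | Path) -> CellTypeDef | SynapseTypeDef:
    """Load one definition from its JSON file, compiling all expressions."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return def_from_dict(data)


def save_type(tdef: CellTypeDef | SynapseTypeDef, path: str | Path) -> None:
    """Write a definition back to JSON; save(load(x)) is content-identical."""
    Path(path).write_text(json.dumps(def_to_dict(tdef), indent=1))


# ---------------------------------------------------------------------------
# Registry


class ModelRegistry:
    """Named collection of cell and synapse type definitions.

    Built-in definitions ship with the package; user definitions live in an
    optional directory of JSON files (one per type).  Protected definitions
    can be neither overwritten nor deleted.
    """

    def __init__(self, user_dir: str | Path | None = None):
        self._defs: dict[str, CellTypeDef | SynapseTypeDef] = {}
        self._files: dict[str, Path] = {}
        self.user_dir = Path(user_dir) if user_dir else None
        if self.user_dir is not None:
            self.user_dir.mkdir(parents=True, exist_ok=True)
            for f in sorted(self.user_dir.glob("*.json")):
                tdef = load_type(f)
                self._defs[tdef.name] = tdef
                self._files[tdef.name] = f

    # mapping protocol -----------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __getitem__(self, name: str) -> CellTypeDef | SynapseTypeDef:
        try:
            return self._defs[name]
        except KeyError:
            raise NotFoundError(f"no model type named {name!r}") from None

    def __iter__(self):
        return iter(self._defs)

    def __len__(self):
        return len(self._defs)

    def names(self, kind: str | None = None) -> list[str]:
        return sorted(n for n, d in self._defs.items()
                      if kind is None or d.kind == kind)

    # mutation -------------------------------------------------------------
    def register(self, tdef: CellTypeDef | SynapseTypeDef, *,
                 file: Path | None = None) -> None:
        existing = self._defs.get(tdef.name)
        if existing is not None and existing.protected:
            raise ProtectionError(f"{tdef.name!r} is protected and cannot be replaced")
        self._defs[tdef.name] = tdef
        if file is not None:
            self._files[tdef.name] = Path(file)

    def add_user_type(self, tdef: CellTypeDef | SynapseTypeDef) -> Path | None:
        """Register and, when a user directory is set, persist to JSON."""
        self.register(tdef)
        if self.user_dir is None:
            return None
        path = self.user_dir / f"{tdef.name}.json"
        save_type(tdef, path)
        self._files[tdef.name] = path
        return path

    def delete_type(self, name: str) -> None:
        """Remove an unprotected type; its user JSON file is deleted too."""
        if name not in self._defs:
            raise NotFoundError(f"no model type named {name!r}")
        if self._defs[name].protected:
            raise ProtectionError(f"{name!r} is protected and cannot be deleted")
        del self._defs[name]
        path = self._files.pop(name, None)
        if path is not None and path.exists() and (
                self.user_dir is not None and path.is_relative_to(self.user_dir)):
            path.unlink()


def load_builtin_registry(user_dir: str | Path | None = None) -> ModelRegistry:
    """Registry pre-loaded with every shipped cell and synapse definition."""
    reg = ModelRegistry(user_dir=user_dir)
    root = importlib.resources.files("lamina") / "models"
    builtin = {}
    for res in sorted(root.iterdir(), key=lambda r: r.name):
        if res.name.endswith(".json"):
            tdef = def_from_dict(json.loads(res.read_text()))
            builtin[tdef.name] = tdef
    # builtins load first; user files already in reg may shadow unprotected ones
    user_defs = dict(reg._defs)
    reg._defs = {**builtin, **{k: v for k, v in user_defs.items()
                               if not (k in builtin and builtin[k].protected)}}
    clobbered = [k for k in user_defs if k in builtin and builtin[k].protected]
    if clobbered:
        raise ProtectionError(
            f"user definitions may not shadow protected types: {sorted(clobbered)}")
    return reg
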