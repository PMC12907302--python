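"""Arithmetic expression compiler for declarative cell and synapse models.

Model vector fields, outputs and synaptic rules are entered as plain text
(an ASCII infix dialect, with a small LaTeX subset normalised away) and
compiled into vectorised numpy callables.  The grammar covers the binary
operators ``+ - * / ^``, unary minus, comparisons (usable inside the
``where`` conditional), numeric literals, symbol references and calls to a
fixed whitelist of functions::

    exp log erf tanh sqrt min max pow heaviside abs where

Every symbol must be declared up front (state variable, parameter, input
slot or auxiliary function of the owning model type); evaluation is pure.
Division by zero and ``log``/``sqrt`` of out-of-domain values raise
:class:`EvaluationError` instead of silently propagating NaNs through a
long simulation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Expression",
    "ExpressionError",
    "ParseError",
    "SymbolError",
    "FunctionError",
    "EvaluationError",
    "compile_expression",
    "normalize_latex",
    "FUNCTIONS",
]


class ExpressionError(ValueError):
    """Base class for expression compilation/evaluation failures."""


class ParseError(ExpressionError):
    """Malformed source text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class SymbolError(ExpressionError):
    """A symbol that is not declared in the owning type's symbol table."""


class FunctionError(ExpressionError):
    """Call to a function outside the fixed whitelist."""


class EvaluationError(ExpressionError):
    """Domain error at evaluation time (division by zero, log(x<=0), ...)."""


# ---------------------------------------------------------------------------
# AST nodes (frozen dataclasses -> structural equality for free)


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class Neg:
    operand: "Node"


@dataclass(frozen=True)
class Bin:
    op: str  # one of + - * / ^
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Cmp:
    op: str  # one of < <= > >= ==
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple


Node = Num | Sym | Neg | Bin | Cmp | Call


# ---------------------------------------------------------------------------
# Guarded primitives.  All accept scalars or numpy arrays.


def _g_div(a, b):
    if np.any(b == 0):
        raise EvaluationError("division by zero")
    return np.true_divide(a, b)


def _g_log(x):
    if np.any(np.asarray(x) <= 0):
        raise EvaluationError("log of non-positive value")
    return np.log(x)


def _g_sqrt(x):
    if np.any(np.asarray(x) < 0):
        raise EvaluationError("sqrt of negative value")
    return np.sqrt(x)


def _heaviside(x):
    # strict step: H(0) = 0, matching the strict inequality of the
    # piecewise-linear rectifier N(V)
    return np.where(np.asarray(x) > 0, 1.0, 0.0)


def _where(c, a, b):
    return np.where(c, a, b)


#: name -> (implementation, arity); arity None means "1 or 2" (min/max are 2)
FUNCTIONS: dict[str, tuple[Callable, int]] = {
    "exp": (np.exp, 1),
    "log": (_g_log, 1),
    "erf": (_erf, 1),
    "tanh": (np.tanh, 1),
    "sqrt": (_g_sqrt, 1),
    "abs": (np.abs, 1),
    "cosh": (np.cosh, 1),
    "sinh": (np.sinh, 1),
    "min": (np.minimum, 2),
    "max": (np.maximum, 2),
    "pow": (np.power, 2),
    "heaviside": (_heaviside, 1),
    "where": (_where, 3),
}


# ---------------------------------------------------------------------------
# LaTeX normalisation (small subset -> ASCII)

_GREEK = (
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu "
    "xi pi rho sigma tau upsilon phi chi psi omega Gamma Delta Theta Lambda "
    "Xi Pi Sigma Phi Psi Omega"
).split()


def _match_braced(s: str, i: int) -> tuple[str, int]:
    """Return the contents of the brace group starting at ``s[i]`` and the
    index just past its closing brace."""
    if i >= len(s) or s[i] != "{":
        raise ParseError("expected '{' in LaTeX macro", i)
    depth, j = 1, i + 1
    while j < len(s) and depth:
        if s[j] == "{":
            depth += 1
        elif s[j] == "}":
            depth -= 1
        j += 1
    if depth:
        raise ParseError("unbalanced '{' in LaTeX macro", i)
    return s[i + 1 : j - 1], j


def normalize_latex(src: str) -> str:
    """Rewrite a small LaTeX subset to the plain-ASCII dialect.

    Handles ``\\frac{a}{b}``, ``\\exp``/``\\log``/``\\sqrt``/``\\tanh``,
    ``\\cdot``/``\\times``, Greek-letter macros, ``\\left``/``\\right`` and
    ``{...}`` grouping.  Plain-ASCII input passes through unchanged.
    """
    if "\\" not in src:
        return src
    out = []
    i = 0
    while i < len(src):
        ch = src[i]
        if ch != "\\":
            out.append(ch)
            i += 1
            continue
        m = re.match(r"\\([A-Za-z]+)", src[i:])
        if not m:
            raise ParseError("stray backslash", i)
        name = m.group(1)
        i += m.end()
        if name == "frac":
            num, i = _match_braced(src, i)
            den, i = _match_braced(src, i)
            out.append(f"(({normalize_latex(num)})/({normalize_latex(den)}))")
        elif name == "sqrt":
            arg, i = _match_braced(src, i)
            out.append(f"sqrt({normalize_latex(arg)})")
        elif name in ("exp", "log", "tanh", "erf", "min", "max"):
            out.append(name)
        elif name in ("cdot", "times"):
            out.append("*")
        elif name in ("left", "right"):
            pass
        elif name in _GREEK:
            out.append(name)
        else:
            raise FunctionError(f"unsupported LaTeX macro \\{name}")
    s = "".join(out)
    # residual grouping braces act as parentheses
    return s.replace("{", "(").replace("}", ")")


# ---------------------------------------------------------------------------
# Tokeniser

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<cmp><=|>=|==|<|>)"
    r"|(?P<op>[-+*/^(),])"
    r")"
)


def _tokenize(src: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(src):
        m = _TOKEN_RE.match(src, pos)
        if not m or m.end() == m.start():
            if src[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {src[pos:].strip()[0]!r}", pos)
        pos = m.end()
        for kind in ("num", "name", "cmp", "op"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start(kind)))
                break
    tokens.append(("end", "", len(src)))
    return tokens


# ---------------------------------------------------------------------------
# Pratt parser.  Precedence: cmp < +- < */ < unary- < ^ (right assoc).


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", pos)

    def parse(self) -> Node:
        node = self.comparison()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ParseError(f"unexpected trailing {val!r}", pos)
        return node

    def comparison(self) -> Node:
        left = self.additive()
        kind, val, _ = self.peek()
        if kind == "cmp":
            self.next()
            right = self.additive()
            return Cmp(val, left, right)
        return left

    def additive(self) -> Node:
        node = self.multiplicative()
        while self.peek()[1] in ("+", "-"):
            _, op, _ = self.next()
            node = Bin(op, node, self.multiplicative())
        return node

    def multiplicative(self) -> Node:
        node = self.unary()
        while self.peek()[1] in ("*", "/"):
            _, op, _ = self.next()
            node = Bin(op, node, self.unary())
        return node

    def unary(self) -> Node:
        kind, val, _ = self.peek()
        if val == "-":
            self.next()
            return Neg(self.unary())
        if val == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        if self.peek()[1] == "^":
            self.next()
            # right-associative; exponent may carry unary minus
            return Bin("^", base, self.unary())
        return base

    def atom(self) -> Node:
        kind, val, pos = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "name":
            if self.peek()[1] == "(":
                self.next()
                args = [self.comparison()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.comparison())
                self.expect(")")
                return Call(val, tuple(args))
            return Sym(val)
        if val == "(":
            node = self.comparison()
            self.expect(")")
            return node
        raise ParseError(f"unexpected {val or 'end of input'!r}", pos)


# ---------------------------------------------------------------------------
# Expression: validated AST + compiled vectorised callable


def _symbols_of(node: Node) -> set[str]:
    if isinstance(node, Sym):
        return {node.name}
    if isinstance(node, Neg):
        return _symbols_of(node.operand)
    if isinstance(node, (Bin, Cmp)):
        return _symbols_of(node.left) | _symbols_of(node.right)
    if isinstance(node, Call):
        out: set[str] = set()
        for a in node.args:
            out |= _symbols_of(a)
        return out
    return set()


def _codegen(node: Node) -> str:
    if isinstance(node, Num):
        return repr(node.value)
    if isinstance(node, Sym):
        return f"_s[{node.name!r}]"
    if isinstance(node, Neg):
        return f"(-{_codegen(node.operand)})"
    if isinstance(node, Bin):
        a, b = _codegen(node.left), _codegen(node.right)
        if node.op == "/":
            return f"_div({a}, {b})"
        if node.op == "^":
            return f"_pow({a}, {b})"
        return f"({a} {node.op} {b})"
    if isinstance(node, Cmp):
        return f"({_codegen(node.left)} {node.op} {_codegen(node.right)})"
    if isinstance(node, Call):
        args = ", ".join(_codegen(a) for a in node.args)
        return f"_f[{node.func!r}]({args})"
    raise TypeError(node)


class Expression:
    """A compiled, pure, vectorised arithmetic expression.

    Instances are produced by :func:`compile_expression`; two expressions
    compare equal iff their ASTs are structurally identical.
    """

    def __init__(self, src: str, ast: Node):
        self.src = src
        self.ast = ast
        self.symbols: frozenset[str] = frozenset(_symbols_of(ast))
        code = compile(_codegen(ast), f"<expr {src!r}>", "eval")
        funcs = {name: impl for name, (impl, _) in FUNCTIONS.items()}
        ns = {"_f": funcs, "_div": _g_div, "_pow": np.power, "__builtins__": {}}

        def _eval(env: Mapping[str, object]):
            return eval(code, ns, {"_s": env})

        self._eval = _eval

    def __call__(self, env: Mapping[str, object]):
        """Evaluate at a symbol assignment (scalars or numpy arrays)."""
        return self._eval(env)

    def __eq__(self, other):
        return isinstance(other, Expression) and self.ast == other.ast

    def __hash__(self):
        return hash(self.ast)

    def __repr__(self):
        return f"Expression({self.src!r})"


def _inline_aux(node: Node, aux: Mapping[str, tuple[Sequence[str], Node]],
                stack: tuple[str, ...] = ()) -> Node:
    """Substitute auxiliary-function calls by their bodies (macro expansion)."""
    if isinstance(node, (Num, Sym)):
        return node
    if isinstance(node, Neg):
        return Neg(_inline_aux(node.operand, aux, stack))
    if isinstance(node, Bin):
        return Bin(node.op, _inline_aux(node.left, aux, stack),
                   _inline_aux(node.right, aux, stack))
    if isinstance(node, Cmp):
        return Cmp(node.op, _inline_aux(node.left, aux, stack),
                   _inline_aux(node.right, aux, stack))
    if isinstance(node, Call):
        args = tuple(_inline_aux(a, aux, stack) for a in node.args)
        if node.func in aux:
            if node.func in stack:
                raise SymbolError(f"recursive auxiliary function {node.func!r}")
            argnames, body = aux[node.func]
            if len(args) != len(argnames):
                raise FunctionError(
                    f"auxiliary function {node.func!r} takes {len(argnames)} "
                    f"argument(s), got {len(args)}")
            sub = dict(zip(argnames, args))
            return _substitute(_inline_aux(body, aux, stack + (node.func,)), sub)
        return Call(node.func, args)
    raise TypeError(node)


def _substitute(node: Node, sub: Mapping[str, Node]) -> Node:
    if isinstance(node, Sym):
        return sub.get(node.name, node)
    if isinstance(node, Num):
        return node
    if isinstance(node, Neg):
        return Neg(_substitute(node.operand, sub))
    if isinstance(node, Bin):
        return Bin(node.op, _substitute(node.left, sub), _substitute(node.right, sub))
    if isinstance(node, Cmp):
        return Cmp(node.op, _substitute(node.left, sub), _substitute(node.right, sub))
    if isinstance(node, Call):
        return Call(node.func, tuple(_substitute(a, sub) for a in node.args))
    raise TypeError(node)


def compile_expression(
    src: str,
    symbols: Iterable[str],
    aux: Mapping[str, tuple[Sequence[str], str]] | None = None,
) -> Expression:
    """Compile equation text into an :class:`Expression`.

    Parameters
    ----------
    src:
        Equation text in the ASCII dialect (a small LaTeX subset is
        normalised first).
    symbols:
        Names the expression may reference (state variables, parameters,
        input slots of the owning type).
    aux:
        Optional auxiliary functions ``name -> (arg_names, body_src)``;
        calls to them are inlined at compile time, so evaluation never
        recurses.

    Raises
    ------
    ParseError, SymbolError, FunctionError
    """
    text = normalize_latex(src)
    ast = _Parser(_tokenize(text)).parse()

    aux_compiled: dict[str, tuple[Sequence[str], Node]] = {}
    if aux:
        for name, (argnames, body_src) in aux.items():
            body_ast = _Parser(_tokenize(normalize_latex(body_src))).parse()
            aux_compiled[name] = (tuple(argnames), body_ast)
        ast = _inline_aux(ast, aux_compiled)

    declared = set(symbols)
    if aux:
        # an aux body may only use its own args plus declared symbols
        for name, (argnames, body_ast) in aux_compiled.items():
            free = _symbols_of(body_ast) - set(argnames) - declared
            if free:
                raise SymbolError(
                    f"auxiliary function {name!r} references undeclared "
                    f"symbol(s): {sorted(free)}")

    undeclared = _symbols_of(ast) - declared
    if undeclared:
        raise SymbolError(f"undeclared symbol(s): {sorted(undeclared)}")

    def check_calls(node: Node):
        if isinstance(node, Call):
            if node.func not in FUNCTIONS:
                raise FunctionError(f"unknown function {node.func!r}")
            _, arity = FUNCTIONS[node.func]
            if len(node.args) != arity:
                raise FunctionError(
                    f"{node.func} takes {arity} argument(s), got {len(node.args)}")
            for a in node.args:
                check_calls(a)
        elif isinstance(node, Neg):
            check_calls(node.operand)
        elif isinstance(node, (Bin, Cmp)):
            check_calls(node.left)
            check_calls(node.right)

    check_calls(ast)
    return Expression(src, ast)
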