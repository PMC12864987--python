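"""Mathematical expression language for model definitions.

Reaction terms, diffusivities, noise amplitudes and initial conditions are all
written as free-form mathematical expressions over named model entities. This
module provides the parser (infix grammar with ``+ - * / ^``, parentheses,
unary minus and a fixed set of builtin functions), a renderer that round-trips
through the parser, and compilation of an expression tree into a vectorised
numpy callable evaluated over per-element arrays.

Builtin functions
-----------------
``sin, cos, exp, log, sqrt, abs`` (arity 1), ``min, max`` (arity 2, elementwise),
``step(z)`` (0 for z < 0, else 1 — the value at exactly 0 is 1 by convention),
``hillact(u, K, n) = u^n / (K^n + u^n)`` and ``hillrep(u, K, n) =
K^n / (K^n + u^n)``, the standard Hill-type up-/down-regulation forms.

The reserved symbols ``t`` (time, hours) and ``x``, ``y`` (domain coordinates)
are bound by the simulation engine and are never free symbols of an expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "Expression",
    "ExpressionSyntaxError",
    "EvaluationError",
    "parse_expression",
    "evaluate_expression",
    "BUILTIN_FUNCTIONS",
    "BUILTIN_SYMBOLS",
]

# name -> arity
BUILTIN_FUNCTIONS: dict[str, int] = {
    "sin": 1,
    "cos": 1,
    "exp": 1,
    "log": 1,
    "sqrt": 1,
    "abs": 1,
    "min": 2,
    "max": 2,
    "step": 1,
    "hillact": 3,
    "hillrep": 3,
}

#: symbols bound by the engine, excluded from free_symbols
BUILTIN_SYMBOLS = frozenset({"t", "x", "y"})


class ExpressionSyntaxError(ValueError):
    """Raised on malformed expression source; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvaluationError(ValueError):
    """Raised when an expression cannot be evaluated (e.g. unbound symbol)."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------


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
class BinOp:
    op: str  # one of + - * / ^
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple["Node", ...]


Node = Union[Num, Sym, Neg, BinOp, Call]


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_OPERATORS = set("+-*/^(),")


@dataclass
class _Token:
    kind: str  # "num", "ident", "op", "end"
    text: str
    pos: int


def _tokenize(source: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(source)
    while i < n:
        c = source[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and source[i + 1].isdigit()):
            j = i
            seen_dot = False
            while j < n and (source[j].isdigit() or (source[j] == "." and not seen_dot)):
                if source[j] == ".":
                    seen_dot = True
                j += 1
            # scientific notation
            if j < n and source[j] in "eE":
                k = j + 1
                if k < n and source[k] in "+-":
                    k += 1
                if k < n and source[k].isdigit():
                    while k < n and source[k].isdigit():
                        k += 1
                    j = k
            tokens.append(_Token("num", source[i:j], i))
            i = j
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (source[j].isalnum() or source[j] == "_"):
                j += 1
            tokens.append(_Token("ident", source[i:j], i))
            i = j
        elif c in _OPERATORS:
            tokens.append(_Token("op", c, i))
            i += 1
        else:
            raise ExpressionSyntaxError(f"unexpected character {c!r}", i)
    tokens.append(_Token("end", "", n))
    return tokens


# ---------------------------------------------------------------------------
# Pratt parser: ^ binds tightest (right-assoc), then unary -, then * /, then + -
# ---------------------------------------------------------------------------

_BINDING = {"+": 10, "-": 10, "*": 20, "/": 20, "^": 40}
_UNARY_BP = 30


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> None:
        tok = self.peek()
        if tok.kind != "op" or tok.text != text:
            raise ExpressionSyntaxError(
                f"expected {text!r} but found {tok.text or 'end of input'!r}", tok.pos
            )
        self.advance()

    def parse(self) -> Node:
        node = self.parse_expr(0)
        tok = self.peek()
        if tok.kind != "end":
            raise ExpressionSyntaxError(f"unexpected {tok.text!r}", tok.pos)
        return node

    def parse_expr(self, min_bp: int) -> Node:
        node = self.parse_prefix()
        while True:
            tok = self.peek()
            if tok.kind != "op" or tok.text not in _BINDING:
                break
            bp = _BINDING[tok.text]
            if bp < min_bp:
                break
            self.advance()
            # right-associative power: recurse at bp, not bp + 1
            right = self.parse_expr(bp if tok.text == "^" else bp + 1)
            node = BinOp(tok.text, node, right)
        return node

    def parse_prefix(self) -> Node:
        tok = self.advance()
        if tok.kind == "num":
            return Num(float(tok.text))
        if tok.kind == "ident":
            if self.peek().kind == "op" and self.peek().text == "(":
                return self.parse_call(tok)
            if tok.text in BUILTIN_FUNCTIONS:
                raise ExpressionSyntaxError(
                    f"builtin function {tok.text!r} used without arguments", tok.pos
                )
            return Sym(tok.text)
        if tok.kind == "op" and tok.text == "-":
            return Neg(self.parse_expr(_UNARY_BP))
        if tok.kind == "op" and tok.text == "+":
            return self.parse_expr(_UNARY_BP)
        if tok.kind == "op" and tok.text == "(":
            node = self.parse_expr(0)
            self.expect(")")
            return node
        raise ExpressionSyntaxError(
            f"unexpected {tok.text or 'end of input'!r}", tok.pos
        )

    def parse_call(self, name_tok: _Token) -> Node:
        name = name_tok.text
        if name not in BUILTIN_FUNCTIONS:
            raise ExpressionSyntaxError(f"unknown function {name!r}", name_tok.pos)
        self.expect("(")
        args: list[Node] = []
        if not (self.peek().kind == "op" and self.peek().text == ")"):
            args.append(self.parse_expr(0))
            while self.peek().kind == "op" and self.peek().text == ",":
                self.advance()
                args.append(self.parse_expr(0))
        self.expect(")")
        arity = BUILTIN_FUNCTIONS[name]
        if len(args) != arity:
            raise ExpressionSyntaxError(
                f"function {name!r} takes {arity} argument(s), got {len(args)}",
                name_tok.pos,
            )
        return Call(name, tuple(args))


# ---------------------------------------------------------------------------
# Rendering (minimal parentheses; parse(render(ast)) == ast)
# ---------------------------------------------------------------------------


def _render(node: Node, parent_bp: int = 0) -> str:
    if isinstance(node, Num):
        v = node.value
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    if isinstance(node, Sym):
        return node.name
    if isinstance(node, Neg):
        inner = _render(node.operand, _UNARY_BP)
        s = f"-{inner}"
        return f"({s})" if parent_bp > _UNARY_BP else s
    if isinstance(node, Call):
        args = ", ".join(_render(a, 0) for a in node.args)
        return f"{node.func}({args})"
    if isinstance(node, BinOp):
        bp = _BINDING[node.op]
        if node.op == "^":
            left = _render(node.left, bp + 1)
            right = _render(node.right, bp)
        else:
            left = _render(node.left, bp)
            right = _render(node.right, bp + 1)
        s = f"{left} {node.op} {right}" if node.op in "+-" else f"{left}{node.op}{right}"
        return f"({s})" if parent_bp > bp else s
    raise TypeError(f"unknown node {node!r}")


# ---------------------------------------------------------------------------
# Numeric builtins (numpy-vectorised, scalar-friendly)
# ---------------------------------------------------------------------------


def _step(z):
    return np.where(np.asarray(z) < 0, 0.0, 1.0)


def _hillact(u, K, n):
    un = np.power(u, n)
    return un / (np.power(K, n) + un)


def _hillrep(u, K, n):
    Kn = np.power(K, n)
    return Kn / (Kn + np.power(u, n))


_NUMPY_FUNCS: dict[str, Callable] = {
    "sin": np.sin,
    "cos": np.cos,
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "min": np.minimum,
    "max": np.maximum,
    "step": _step,
    "hillact": _hillact,
    "hillrep": _hillrep,
}


def _collect_symbols(node: Node, out: set[str]) -> None:
    if isinstance(node, Sym):
        out.add(node.name)
    elif isinstance(node, Neg):
        _collect_symbols(node.operand, out)
    elif isinstance(node, BinOp):
        _collect_symbols(node.left, out)
        _collect_symbols(node.right, out)
    elif isinstance(node, Call):
        for a in node.args:
            _collect_symbols(a, out)


def _compile_node(node: Node) -> Callable[[Mapping[str, object]], object]:
    """Compile the tree into a closure over an environment mapping."""
    if isinstance(node, Num):
        v = node.value
        return lambda env: v
    if isinstance(node, Sym):
        name = node.name
        return lambda env: env[name]
    if isinstance(node, Neg):
        f = _compile_node(node.operand)
        return lambda env: -f(env)
    if isinstance(node, BinOp):
        lf = _compile_node(node.left)
        rf = _compile_node(node.right)
        op = node.op
        if op == "+":
            return lambda env: lf(env) + rf(env)
        if op == "-":
            return lambda env: lf(env) - rf(env)
        if op == "*":
            return lambda env: lf(env) * rf(env)
        if op == "/":
            return lambda env: lf(env) / rf(env)
        if op == "^":
            return lambda env: np.power(lf(env), rf(env))
        raise ValueError(op)
    if isinstance(node, Call):
        func = _NUMPY_FUNCS[node.func]
        arg_fns = [_compile_node(a) for a in node.args]
        if len(arg_fns) == 1:
            (a0,) = arg_fns
            return lambda env: func(a0(env))
        if len(arg_fns) == 2:
            a0, a1 = arg_fns
            return lambda env: func(a0(env), a1(env))
        a0, a1, a2 = arg_fns
        return lambda env: func(a0(env), a1(env), a2(env))
    raise TypeError(f"unknown node {node!r}")


# ---------------------------------------------------------------------------
# Public interface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Expression:
    """A parsed mathematical expression.

    Attributes
    ----------
    source : str
        Original text the expression was parsed from.
    ast : Node
        Parsed tree (literals, symbols, unary/binary operators, calls).
    free_symbols : frozenset[str]
        Identifiers appearing in the source that are neither builtin functions
        nor the engine-bound symbols ``t``, ``x``, ``y``.
    """

    source: str
    ast: Node
    free_symbols: frozenset[str]
    _fn: Callable = field(repr=False, compare=False)

    @property
    def used_symbols(self) -> frozenset[str]:
        """All identifiers used, including the builtin symbols t, x, y."""
        syms: set[str] = set()
        _collect_symbols(self.ast, syms)
        return frozenset(syms)

    def render(self) -> str:
        """Re-render the tree as source text (parses back to an equal tree)."""
        return _render(self.ast)

    @property
    def is_zero(self) -> bool:
        """True when the expression is the literal constant 0."""
        return isinstance(self.ast, Num) and self.ast.value == 0.0

    def __call__(self, env: Mapping[str, object]):
        return self._fn(env)


def parse_expression(source: str) -> Expression:
    """Parse expression text into an :class:`Expression`.

    Raises :class:`ExpressionSyntaxError` (with a character position) for
    malformed input, unknown function names or wrong call arity.
    """
    if not source or not source.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    ast = _Parser(source).parse()
    syms: set[str] = set()
    _collect_symbols(ast, syms)
    free = frozenset(syms - BUILTIN_SYMBOLS)
    return Expression(source=source, ast=ast, free_symbols=free, _fn=_compile_node(ast))


def evaluate_expression(expr: Expression, env: Mapping[str, float]):
    """Evaluate ``expr`` under a name→value binding (which may include t, x, y).

    Unbound symbols raise :class:`EvaluationError` naming the symbol. Domain
    errors (log of a non-positive value, 0/0, ...) produce non-finite results
    (``nan``/``inf``) rather than raising, so the engine's finiteness check can
    report them with spatial context.
    """
    missing = expr.used_symbols - set(env)
    if missing:
        raise EvaluationError(
            f"unbound symbol(s) in {expr.source!r}: {', '.join(sorted(missing))}"
        )
    with np.errstate(all="ignore"):
        out = expr._fn(env)
    if np.isscalar(out) or isinstance(out, (int, float)):
        return float(out)
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out
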