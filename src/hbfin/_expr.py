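"""Tiny safe arithmetic evaluator for condition-band bound expressions.

Bounds in the condition table may be arithmetic expressions over the
anthropometric variables ``Wt`` (weight, kg), ``L`` (height, cm) and the
body-size factor ``Q``.  Only literals, the four arithmetic operators,
unary minus, and the functions ``min``/``max``/``abs`` are admitted; the
expression is compiled through :mod:`ast` with an explicit whitelist so a
condition table can never execute arbitrary code.
"""

from __future__ import annotations

import ast
from typing import Mapping

from .errors import ConfigError

_FUNCS = {"min": min, "max": max, "abs": abs}

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Pow: lambda a, b: a**b,
}


def evaluate(expr: str, env: Mapping[str, float]) -> float:
    """Evaluate *expr* with variables drawn from *env*.

    Raises :class:`ConfigError` on syntax errors, unknown variables or
    disallowed constructs.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message formatting
        raise ConfigError(f"malformed expression {expr!r}: {exc.msg}") from exc
    return float(_eval(tree.body, expr, env))


def _eval(node: ast.AST, expr: str, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
            return float(node.value)
        raise ConfigError(f"non-numeric literal in expression {expr!r}")
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise ConfigError(f"unknown variable {node.id!r} in expression {expr!r}")
        return float(env[node.id])
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](
            _eval(node.left, expr, env), _eval(node.right, expr, env)
        )
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        val = _eval(node.operand, expr, env)
        return -val if isinstance(node.op, ast.USub) else val
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCS:
            raise ConfigError(f"disallowed function call in expression {expr!r}")
        if node.keywords:
            raise ConfigError(f"keyword arguments not allowed in expression {expr!r}")
        args = [_eval(a, expr, env) for a in node.args]
        return float(_FUNCS[node.func.id](*args))
    raise ConfigError(f"disallowed syntax in expression {expr!r}")


def variables(expr: str) -> set[str]:
    """Names referenced by *expr* (without evaluating it)."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"malformed expression {expr!r}: {exc.msg}") from exc
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name) and n.id not in _FUNCS}
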