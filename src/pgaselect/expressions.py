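"""Safe arithmetic/boolean mini-grammar for derived-feature definitions.

Derived low-cost features are declared in the schema as expressions over
administrative feature names, e.g. ``"(adm_01 >= 2) and (adm_02 >= 2)"`` or
``"max(adm_03, adm_04)"``.  Only a small whitelist of Python expression nodes
is permitted — names, numeric constants, ``+ - * /``, comparisons,
``and/or/not``, unary minus, and calls to ``min``/``max``/``abs`` — so schema
files can never execute arbitrary code.
"""

from __future__ import annotations

import ast
from typing import Mapping

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    """Raised for syntactically invalid or non-whitelisted expressions."""


_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.true_divide,
}
_CMPOPS = {
    ast.Gt: np.greater,
    ast.GtE: np.greater_equal,
    ast.Lt: np.less,
    ast.LtE: np.less_equal,
    ast.Eq: np.equal,
    ast.NotEq: np.not_equal,
}
_CALLS = {
    "min": lambda args: np.minimum.reduce(args),
    "max": lambda args: np.maximum.reduce(args),
    "abs": lambda args: np.abs(args[0]),
}


def _parse(expression: str) -> ast.expr:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message carries position
        raise ExpressionError(f"invalid expression {expression!r}: {exc}") from exc
    return tree.body


def referenced_names(expression: str) -> tuple[str, ...]:
    """Feature names referenced by *expression*, in first-appearance order."""
    names: list[str] = []

    def walk(node: ast.AST) -> None:
        if isinstance(node, ast.Call):
            # the callee Name is a function, not a feature
            for arg in node.args:
                walk(arg)
            return
        if isinstance(node, ast.Name) and node.id not in names:
            names.append(node.id)
        for child in ast.iter_child_nodes(node):
            walk(child)

    walk(_parse(expression))
    return tuple(names)


def _evaluate(node: ast.expr, env: Mapping[str, np.ndarray]) -> np.ndarray:
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant {node.value!r}")
        return np.asarray(float(node.value))
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise ExpressionError(f"unknown feature {node.id!r} in expression")
        return env[node.id]
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](_evaluate(node.left, env), _evaluate(node.right, env))
    if isinstance(node, ast.UnaryOp):
        if isinstance(node.op, ast.USub):
            return -_evaluate(node.operand, env)
        if isinstance(node.op, ast.Not):
            return np.logical_not(_evaluate(node.operand, env) != 0).astype(float)
        raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
    if isinstance(node, ast.BoolOp):
        parts = [_evaluate(v, env) != 0 for v in node.values]
        op = np.logical_and if isinstance(node.op, ast.And) else np.logical_or
        out = parts[0]
        for part in parts[1:]:
            out = op(out, part)
        return out.astype(float)
    if isinstance(node, ast.Compare):
        left = _evaluate(node.left, env)
        out = None
        for op, comparator in zip(node.ops, node.comparators):
            if type(op) not in _CMPOPS:
                raise ExpressionError(f"comparison {type(op).__name__} not allowed")
            right = _evaluate(comparator, env)
            piece = _CMPOPS[type(op)](left, right)
            out = piece if out is None else np.logical_and(out, piece)
            left = right
        return np.asarray(out).astype(float)
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _CALLS:
            raise ExpressionError("only min/max/abs calls are allowed")
        if node.keywords:
            raise ExpressionError("keyword arguments are not allowed")
        args = [_evaluate(a, env) for a in node.args]
        if not args:
            raise ExpressionError(f"{node.func.id}() needs at least one argument")
        return np.asarray(_CALLS[node.func.id](args), dtype=float)
    raise ExpressionError(f"expression node {type(node).__name__} not allowed")


def evaluate_expression(expression: str, frame: pd.DataFrame) -> pd.Series:
    """Evaluate *expression* row-wise over *frame*.

    Any row where a referenced feature is missing (NaN) yields NaN in the
    result — missingness propagates into derived features.
    """
    refs = referenced_names(expression)
    unknown = [r for r in refs if r not in frame.columns]
    if unknown:
        raise ExpressionError(f"unknown feature(s) {unknown} in expression {expression!r}")
    env = {r: frame[r].to_numpy(dtype=float) for r in refs}
    if refs:
        masked = np.logical_or.reduce([np.isnan(env[r]) for r in refs])
        env = {r: np.nan_to_num(v, nan=0.0) for r, v in env.items()}
    else:
        masked = np.zeros(len(frame), dtype=bool)
    values = np.broadcast_to(
        np.asarray(_evaluate(_parse(expression), env), dtype=float), (len(frame),)
    ).copy()
    values[masked] = np.nan
    return pd.Series(values, index=frame.index)
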