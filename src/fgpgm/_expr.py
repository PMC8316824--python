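"""Safe evaluation of small arithmetic expressions for user-defined systems.

Grammar: numbers, named variables, ``+ - * / ^`` (``^`` is power),
unary minus, ``exp(...)`` and parentheses.  Parsed through the Python
``ast`` module with a strict node whitelist; nothing else evaluates.
"""

from __future__ import annotations

import ast
from typing import Callable, Mapping, Sequence

import numpy as np

_ALLOWED_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.divide,
    ast.Pow: np.power,
}
_ALLOWED_UNARY = {ast.USub: np.negative, ast.UAdd: lambda v: v}
_FUNCTIONS = {"exp": np.exp}


class ExpressionError(ValueError):
    pass


def compile_expression(
    expr: str, names: Sequence[str]
) -> Callable[[Mapping[str, object]], object]:
    """Compile ``expr`` into a function of an environment dict.

    ``names`` lists the identifiers the expression may reference.
    """
    source = expr.replace("^", "**")
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expr!r}: {exc}") from None
    allowed = set(names)

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BinOp):
            if type(node.op) not in _ALLOWED_BINOPS:
                raise ExpressionError(f"operator not allowed in {expr!r}")
            check(node.left)
            check(node.right)
        elif isinstance(node, ast.UnaryOp):
            if type(node.op) not in _ALLOWED_UNARY:
                raise ExpressionError(f"unary operator not allowed in {expr!r}")
            check(node.operand)
        elif isinstance(node, ast.Call):
            if (
                not isinstance(node.func, ast.Name)
                or node.func.id not in _FUNCTIONS
                or node.keywords
                or len(node.args) != 1
            ):
                raise ExpressionError(
                    f"only {sorted(_FUNCTIONS)} calls allowed in {expr!r}"
                )
            check(node.args[0])
        elif isinstance(node, ast.Name):
            if node.id not in allowed:
                raise ExpressionError(
                    f"unknown identifier {node.id!r} in {expr!r}; known: {sorted(allowed)}"
                )
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ExpressionError(f"non-numeric literal in {expr!r}")
        else:
            raise ExpressionError(
                f"construct {type(node).__name__} not allowed in {expr!r}"
            )

    check(tree)

    def evaluate(env: Mapping[str, object]):
        def rec(node):
            if isinstance(node, ast.Expression):
                return rec(node.body)
            if isinstance(node, ast.BinOp):
                return _ALLOWED_BINOPS[type(node.op)](rec(node.left), rec(node.right))
            if isinstance(node, ast.UnaryOp):
                return _ALLOWED_UNARY[type(node.op)](rec(node.operand))
            if isinstance(node, ast.Call):
                return _FUNCTIONS[node.func.id](rec(node.args[0]))
            if isinstance(node, ast.Name):
                return env[node.id]
            if isinstance(node, ast.Constant):
                return node.value
            raise AssertionError("unreachable")

        return rec(tree)

    return evaluate
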