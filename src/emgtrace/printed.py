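"""The two published evolved formulas as fixed, evaluable predictors.

The original study's best within-group models, F(x) and F(y), map the seven
window-RMS features d1..d7 (muV; see ``features.CHANNEL_MUSCLES``) to a
predicted coordinate difference.  They are transcribed here as expression
trees and evaluated under the same protected arithmetic as the evolution
engine, so every input yields a finite prediction (e.g. a zero denominator
in the d5/d4 term resolves to 1).

The published typography collapses fraction bars and exponents, so a few
terms admit two readings.  The transcription table in ``docs/methods.md``
records one documented reading per term; the two genuinely ambiguous terms
are switchable here:

``x_inner_d7``
    the d7 inside F(x)'s double exponential, ``exp((exp(cos(d1+d4+42.63)
    <op> d7))^2)`` — default ``"multiply"``.
``y_12_21_d2``
    F(y)'s ``12.21 d2`` inside the first exponential — default
    ``"divide"`` (the multiplicative reading saturates the exponential for
    physiological RMS magnitudes; both are provided).

F(x) references all seven terminals; F(y) references exactly six — d4
(flexor carpi radialis) dropped out during the original training.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .gep.karva import evaluate_tree

__all__ = ["PrintedModel", "printed_model", "eval_printed", "terminals_used"]


def _c(v):
    return ("const", float(v))


def _t(name):
    return (name,)


def _add(*xs):
    out = xs[0]
    for x in xs[1:]:
        out = ("+", out, x)
    return out


def _sub(a, b):
    return ("-", a, b)


def _mul(*xs):
    out = xs[0]
    for x in xs[1:]:
        out = ("*", out, x)
    return out


def _div(a, b):
    return ("/", a, b)


d1, d2, d3, d4, d5, d6, d7 = (_t(f"d{i}") for i in range(1, 8))


def _fx_tree(x_inner_d7: str = "multiply"):
    """F(x): six additively linked terms, all seven terminals present."""
    # sin(d5 - d1 - d5/d4 + d4 - 1.74 + 2.09*d2 - 4.37*d5)
    t1 = ("sin", _sub(_sub(_add(_sub(_sub(d5, d1), _div(d5, d4)), d4, _mul(_c(2.09), d2)),
                           _c(1.74)), _mul(_c(4.37), d5)))
    # 4.3 + d7 - d1 + d7 / exp((exp(cos(d1+d4+42.63) <op> d7))^2)
    inner = ("cos", _add(d1, d4, _c(42.63)))
    inner = _mul(inner, d7) if x_inner_d7 == "multiply" else _div(inner, d7)
    t2 = _add(_c(4.3), _sub(d7, d1), _div(d7, ("exp", ("sqr", ("exp", inner)))))
    # - d2*sin(d3 + 8.89 - d5)/(d7 - d4) - exp(sin(d1))*(d2 - 3.53)^2/62.73
    t3 = _sub(
        _c(0.0),
        _add(
            _div(_mul(d2, ("sin", _sub(_add(d3, _c(8.89)), d5))), _sub(d7, d4)),
            _div(_mul(("exp", ("sin", d1)), ("sqr", _sub(d2, _c(3.53)))), _c(62.73)),
        ),
    )
    # cos(2*d1 - 0.45 + 1/d3) + sin(d7)
    t4 = _add(("cos", _add(_sub(_mul(_c(2.0), d1), _c(0.45)), ("inv", d3))), ("sin", d7))
    # cos(d1 + 7.63 - cos(cos(d3) + 2*d5) - d5)
    t5 = ("cos", _sub(_sub(_add(d1, _c(7.63)), ("cos", _add(("cos", d3), _mul(_c(2.0), d5)))), d5))
    # - d6 + d2 + d5 - d3
    t6 = _sub(_add(_sub(_c(0.0), d6), d2, d5), d3)
    return _add(t1, t2, t3, t4, t5, t6)


def _fy_tree(y_12_21_d2: str = "divide"):
    """F(y): five additively linked terms; d4 absent."""
    coef = _div(_c(12.21), d2) if y_12_21_d2 == "divide" else _mul(_c(12.21), d2)
    # d1*sin(d1)*exp(sin(-0.36*d6) + 12.21/d2)
    t1 = _mul(d1, ("sin", d1), ("exp", _add(("sin", _sub(_c(0.0), _mul(_c(0.36), d6))), coef)))
    # - 2*d6 + 2*d1 + d7 - sin(d2 + 0.96)
    t2 = _sub(_add(_sub(_mul(_c(2.0), d1), _mul(_c(2.0), d6)), d7), ("sin", _add(d2, _c(0.96))))
    # sin(d1 - d5 - (exp(-0.78*d5*d3 + sin(d7)))^2)
    t3 = ("sin", _sub(_sub(d1, d5),
                      ("sqr", ("exp", _add(_sub(_c(0.0), _mul(_c(0.78), d5, d3)), ("sin", d7))))))
    # cos((d3 - d6 + 6.67 - 0.09*d2)^2) - 8.33 + 1/d7
    t4 = _add(("cos", ("sqr", _sub(_add(_sub(d3, d6), _c(6.67)), _mul(_c(0.09), d2)))),
              _sub(("inv", d7), _c(8.33)))
    return _add(t1, t2, t3, t4)


@dataclass(frozen=True)
class PrintedModel:
    """One fixed published predictor (coordinate ``"x"`` or ``"y"``)."""

    coordinate: str
    expression: tuple = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.coordinate not in ("x", "y"):
            raise ValueError("coordinate must be 'x' or 'y'")
        if self.expression is None:
            tree = _fx_tree() if self.coordinate == "x" else _fy_tree()
            object.__setattr__(self, "expression", tree)

    @property
    def required_terminals(self) -> frozenset:
        return terminals_used(self)

    def predict(self, features) -> np.ndarray:
        return eval_printed(self, features)


def printed_model(coordinate: str, **readings) -> PrintedModel:
    """Build F(x) or F(y), optionally with alternative ambiguous readings."""
    if coordinate == "x":
        tree = _fx_tree(readings.get("x_inner_d7", "multiply"))
    else:
        tree = _fy_tree(readings.get("y_12_21_d2", "divide"))
    return PrintedModel(coordinate, tree)


def eval_printed(model: PrintedModel, features) -> np.ndarray:
    """Evaluate the transcribed formula on d1..d7 (dict, DataFrame or array).

    Arrays are taken column-ordered d1..d7.  Missing terminals raise.
    """
    if isinstance(features, Mapping):
        data = {k: np.asarray(v, dtype=float) for k, v in features.items()}
    elif hasattr(features, "columns"):  # DataFrame
        data = {c: features[c].to_numpy(dtype=float) for c in features.columns}
    else:
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        data = {f"d{j + 1}": arr[:, j] for j in range(arr.shape[1])}
    missing = sorted(terminals_used(model) - set(data))
    if missing:
        raise KeyError(f"missing terminal values: {missing}")
    return np.asarray(evaluate_tree(model.expression, data), dtype=float)


def terminals_used(model: PrintedModel) -> frozenset:
    """Distinct d-terminals appearing in the transcribed expression."""

    def walk(node, acc):
        if node[0] == "const":
            return
        if len(node) == 1:
            acc.add(node[0])
            return
        for child in node[1:]:
            walk(child, acc)

    acc: set = set()
    walk(model.expression, acc)
    return frozenset(acc)
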