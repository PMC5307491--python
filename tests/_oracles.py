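"""Independent reference implementations used as oracles by the tests.

Everything here is written from first principles, deliberately *not*
importing the package's evaluators: a naive recursive karva decoder and
tree-walk evaluator, a textbook Kalman filter, normal-equations OLS, and
two-pass statistics.  Agreement between these and the package is what the
oracle tests assert.
"""
from __future__ import annotations

import math

import numpy as np

# -- naive karva decoding + scalar tree evaluation --------------------------

ARITY = {"+": 2, "-": 2, "*": 2, "/": 2,
         "sqrt": 1, "exp": 1, "inv": 1, "sqr": 1, "sin": 1, "cos": 1}

_BIG = 1e300


def _clamp(v: float) -> float:
    if math.isnan(v):
        return 0.0
    return max(-_BIG, min(_BIG, v))


def naive_decode(symbols):
    """Breadth-first decode of a symbol string into nested lists."""
    root = [symbols[0], []]
    queue = [root]
    i = 1
    while queue:
        node = queue.pop(0)
        for _ in range(ARITY.get(node[0], 0)):
            child = [symbols[i], []]
            i += 1
            node[1].append(child)
            queue.append(child)
    return root


def naive_eval_node(node, env) -> float:
    sym, children = node
    if sym not in ARITY:
        return float(env[sym])
    vals = [naive_eval_node(c, env) for c in children]
    # transcendentals go through numpy's array kernel on a singleton: scalar
    # libm and the SIMD loops differ by ulps, which later divisions or huge
    # trig arguments amplify — this oracle checks karva decoding, not libm
    def _np1(fn, x):
        return float(fn(np.array([x]))[0])

    if sym == "+":
        v = vals[0] + vals[1]
    elif sym == "-":
        v = vals[0] - vals[1]
    elif sym == "*":
        v = vals[0] * vals[1]
    elif sym == "/":
        v = 1.0 if vals[1] == 0 else vals[0] / vals[1]
    elif sym == "sqrt":
        v = _np1(np.sqrt, abs(vals[0]))
    elif sym == "exp":
        v = _np1(np.exp, max(-700.0, min(700.0, vals[0])))
    elif sym == "inv":
        v = 1.0 if vals[0] == 0 else 1.0 / vals[0]
    elif sym == "sqr":
        try:
            v = vals[0] * vals[0]
        except OverflowError:
            v = _BIG
    elif sym == "sin":
        v = _np1(np.sin, max(-1e15, min(1e15, vals[0])))
    elif sym == "cos":
        v = _np1(np.cos, max(-1e15, min(1e15, vals[0])))
    else:  # pragma: no cover
        raise KeyError(sym)
    try:
        return _clamp(v)
    except OverflowError:  # pragma: no cover
        return _BIG if v > 0 else -_BIG


def naive_eval_gene(symbols, env) -> float:
    return naive_eval_node(naive_decode(symbols), env)


# -- textbook Kalman filter -------------------------------------------------

def textbook_filter(A, Q, H, R, s0, P0, Z):
    """Reference filter for the 'measurement = regression prediction' form."""
    s = np.asarray(s0, float).copy()
    P = np.asarray(P0, float).copy()
    out = []
    for z in np.atleast_2d(Z):
        s_pred = A @ s
        P_pred = A @ P @ A.T + Q
        K = P_pred @ np.linalg.inv(P_pred + R)
        s = s_pred + K @ (H @ z - s_pred)
        P = P_pred - K @ P_pred
        P = 0.5 * (P + P.T)
        out.append(s.copy())
    return np.asarray(out)


# -- normal-equations OLS ---------------------------------------------------

def ols_normal_equations(X, Y):
    """argmin ||Y - X B||_F via (X'X)^{-1} X'Y."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    return np.linalg.solve(X.T @ X, X.T @ Y)


# -- two-pass statistics ----------------------------------------------------

def twopass_rms(values) -> float:
    total = 0.0
    n = 0
    for v in values:
        total += float(v) ** 2
        n += 1
    return math.sqrt(total / n)


def twopass_cc2(actual, predicted) -> float:
    a = [float(v) for v in actual]
    p = [float(v) for v in predicted]
    mean = sum(a) / len(a)
    sse = sum((y - x) ** 2 for x, y in zip(a, p))
    sstot = sum((x - mean) ** 2 for x in a)
    return 1.0 - sse / sstot
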