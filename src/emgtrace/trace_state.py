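"""Coordinate state transition: traces <-> first differences.

A drawing trace sampled every 50 ms is encoded as the sequence of
differences between successive coordinate states,

    dx_i = x_i - x_{i-1},   dy_i = y_i - y_{i-1},   i = 1..n-1,

which serve as regression targets.  Predicted differences are turned back
into a trace by recursive accumulation from the known pen start point,

    x^_i = dx^_i + x^_{i-1},

so reconstruction is causal and exact for the true deltas.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeltaSeries", "to_deltas", "reconstruct"]


@dataclass(frozen=True)
class DeltaSeries:
    """First differences of a 2-D trace plus its start point.

    ``deltas`` has shape (n-1, 2) for an n-point trace; ``start_point`` is
    the (x, y) of the first coordinate sample.
    """

    deltas: np.ndarray
    start_point: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        s = np.asarray(self.start_point, dtype=float)
        if d.ndim != 2 or d.shape[1] != 2:
            raise ValueError("deltas must have shape (n-1, 2)")
        if s.shape != (2,):
            raise ValueError("start_point must be a length-2 vector")
        object.__setattr__(self, "deltas", d)
        object.__setattr__(self, "start_point", s)

    def __len__(self) -> int:
        return self.deltas.shape[0]


def to_deltas(coords: np.ndarray) -> DeltaSeries:
    """Convert an (n, 2) coordinate series to its first differences.

    Raises ``ValueError`` for traces with fewer than two points.
    """
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("coords must have shape (n, 2)")
    if c.shape[0] < 2:
        raise ValueError("need at least 2 coordinate samples to form deltas")
    return DeltaSeries(deltas=np.diff(c, axis=0), start_point=c[0].copy())


def reconstruct(deltas: DeltaSeries | np.ndarray, start_point=None) -> np.ndarray:
    """Recursively rebuild an (n, 2) trace from (n-1, 2) deltas.

    ``start_point`` overrides the one stored in a :class:`DeltaSeries`;
    it must be given when raw arrays are passed.  The start point is the
    true stroke start, never the origin.
    """
    if isinstance(deltas, DeltaSeries):
        d = deltas.deltas
        s = deltas.start_point if start_point is None else np.asarray(start_point, float)
    else:
        if start_point is None:
            raise ValueError("start_point required when deltas is a bare array")
        d = np.asarray(deltas, dtype=float)
        s = np.asarray(start_point, dtype=float)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("deltas must have shape (n-1, 2)")
    out = np.empty((d.shape[0] + 1, 2), dtype=float)
    out[0] = s
    np.cumsum(d, axis=0, out=out[1:])
    out[1:] += s
    return out
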