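"""Parametric one-stroke drawing shapes.

Twelve basic one-stroke shapes: the four straight lines (horizontal,
vertical, forward slash, backslash), arch and inverted arch (half
ellipses), circle and ellipse, plus the four lines traversed in the
reverse direction.  A reversed shape covers exactly the same point set as
its counterpart, in reverse order.  Coordinates are in tablet units with a
y-down convention (larger y = lower on the tablet); the default extent
emulates a 12 x 12 cm drawing template.

Traces are sampled every 50 ms to match the pen-coordinate acquisition
grid.  Two stochastic components emulate human trial-to-trial variability:
small iid jitter on each sample and a smooth low-frequency drift of the
whole stroke (people never trace a template twice identically, and in
particular wander off a line's nominal axis).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["SHAPE_IDS", "ShapeSpec", "generate_trace"]

_BASE_SHAPES = (
    "horizontal_line",
    "vertical_line",
    "forward_slash",
    "backslash",
    "arch",
    "inverted_arch",
    "circle",
    "ellipse",
)
_REVERSED = (
    "reversed_horizontal_line",
    "reversed_vertical_line",
    "reversed_forward_slash",
    "reversed_backslash",
)
SHAPE_IDS = _BASE_SHAPES + _REVERSED

COORD_INTERVAL_MS = 50.0


@dataclass(frozen=True)
class ShapeSpec:
    """One shape template: geometry plus traversal.

    ``size`` is the stroke extent in tablet units (default 400, standing in
    for the 12 cm template); ``duration_ms`` the stroke time; ``direction``
    is +1 for canonical traversal and -1 for the reversed variants;
    ``start_point``, when given, translates the trace so its first sample
    lands exactly there.
    """

    shape_id: str
    start_point: Optional[tuple] = None
    direction: int = 1
    duration_ms: float = 1500.0
    size: float = 400.0
    jitter_frac: float = 0.01
    drift_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.shape_id not in SHAPE_IDS:
            raise ValueError(f"unknown shape_id: {self.shape_id!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.shape_id in _REVERSED and self.direction != -1:
            object.__setattr__(self, "direction", -1)

    @property
    def n_points(self) -> int:
        return int(round(self.duration_ms / COORD_INTERVAL_MS)) + 1

    @property
    def base_shape(self) -> str:
        return self.shape_id.removeprefix("reversed_")


def _base_curve(shape: str, s: np.ndarray, L: float) -> np.ndarray:
    """Ideal curve on parameter s in [0, 1]; y-down tablet frame."""
    h = L / 2.0
    if shape == "horizontal_line":
        x, y = L * s, np.full_like(s, h)
    elif shape == "vertical_line":
        x, y = np.full_like(s, h), L * s  # drawn downward
    elif shape == "forward_slash":
        x, y = L * s, L * (1.0 - s)  # bottom-left to top-right
    elif shape == "backslash":
        x, y = L * s, L * s  # top-left to bottom-right
    elif shape == "arch":
        x, y = h * (1.0 - np.cos(np.pi * s)), h - h * np.sin(np.pi * s)
    elif shape == "inverted_arch":
        x, y = h * (1.0 - np.cos(np.pi * s)), h + h * np.sin(np.pi * s)
    elif shape == "circle":
        th = 2.0 * np.pi * s
        x, y = h + h * np.sin(th), h - h * np.cos(th)  # clockwise from top
    elif shape == "ellipse":
        th = 2.0 * np.pi * s
        x, y = h + h * np.sin(th), h - 0.5 * h * np.cos(th)
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(f"unknown shape_id: {shape!r}")
    return np.column_stack([x, y])


def _smooth_drift(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random wander, zero at the first sample, sd ~= amplitude."""
    if amplitude <= 0 or n < 3:
        return np.zeros((n, 2))
    steps = rng.standard_normal((n + 6, 2))
    kern = np.hanning(7)
    kern /= kern.sum()
    smooth = np.column_stack(
        [np.convolve(steps[:, j], kern, mode="valid") for j in range(2)]
    )[:n]
    walk = np.cumsum(smooth, axis=0)
    walk -= walk[0]
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk * (amplitude / sd)


def generate_trace(spec: ShapeSpec, rng_seed) -> np.ndarray:
    """Sample a (n, 2) coordinate trace for ``spec`` at 50 ms spacing.

    ``rng_seed`` may be an int seed or a ``numpy.random.Generator``.
    The reversed shape variants return the same point set as their
    counterpart (same seed) in reverse order.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = spec.n_points
    s = np.linspace(0.0, 1.0, n)
    pts = _base_curve(spec.base_shape, s, spec.size)

    jitter = rng.standard_normal((n, 2)) * (spec.jitter_frac * spec.size)
    jitter[0] = 0.0
    drift = _smooth_drift(n, spec.drift_frac * spec.size, rng)
    pts = pts + jitter + drift

    if spec.direction < 0:
        pts = pts[::-1].copy()
    if spec.start_point is not None:
        pts = pts + (np.asarray(spec.start_point, float) - pts[0])
    return pts
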