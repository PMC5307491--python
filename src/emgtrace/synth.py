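"""Synthetic paired trace/EMG trials.

Forward model
-------------
Real decoders are trained on recordings where arm-muscle activity covaries
with pen velocity.  The generator plants that structure explicitly: each of
the 7 decoding channels has a preferred drawing direction p_m and gain g_m,
and its amplitude envelope over a 50 ms window with pen displacement
v = (dx, dy) is

    env_m = baseline + g_m * max(0, p_m . v)      [muV]

i.e. rectified cosine tuning, the standard first-order picture of a muscle
that pulls the pen one way and goes silent for the opposite motion.  The
channel signal is this envelope modulating a zero-mean band-limited carrier
whose per-window RMS is normalised to 1, plus additive sensor noise, so the
window RMS recovers the envelope up to noise.  With opposite-direction
channel pairs at equal gain, (d_i - d_j) = g * (p . v): the planted
RMS -> (dx, dy) mapping is exactly representable in the decoder's function
set, which makes recovery a fair, well-posed test.  The eighth channel is a
trigger that bursts above the 40 muV onset threshold when the stroke starts.

This is a deliberately simple stand-in for muscle physiology: no synergies,
fatigue or electrode shift; results on it are statements about the decoding
pipeline, not about real muscles.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .shapes import COORD_INTERVAL_MS, SHAPE_IDS, ShapeSpec, generate_trace

__all__ = [
    "MuscleModel",
    "TrialRecord",
    "DatasetConfig",
    "generate_emg",
    "generate_dataset",
]

_SAMPLE_RATE = 1000.0
_WIN = int(COORD_INTERVAL_MS)  # samples per 50 ms window at 1 kHz

# Preferred directions (degrees): two axis-aligned opponent pairs so that the
# planted mapping is linearly invertible, plus three oblique channels.
_DEFAULT_ANGLES = (0.0, 180.0, 90.0, 270.0, 45.0, 135.0, 225.0)


def _unit_vectors(angles_deg: Sequence[float]) -> np.ndarray:
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class MuscleModel:
    """Directional-tuning forward model for the 7 decoding channels.

    ``tuning`` is (7, 2) unit preferred directions; ``gains`` are muV per
    (tablet unit / window); the trigger channel bursts at ``trigger_amp``
    for ``trigger_dur_ms`` from movement onset.
    """

    tuning: np.ndarray = field(default_factory=lambda: _unit_vectors(_DEFAULT_ANGLES))
    gains: np.ndarray = field(default_factory=lambda: np.ones(7))
    baseline: float = 8.0
    noise_sd: float = 2.0
    trigger_amp: float = 200.0
    trigger_dur_ms: float = 100.0
    trigger_rest_sd: float = 3.0

    def __post_init__(self) -> None:
        t = np.asarray(self.tuning, dtype=float)
        g = np.asarray(self.gains, dtype=float)
        if t.shape != (g.shape[0], 2):
            raise ValueError("tuning must be (n_channels, 2) matching gains")
        if (g <= 0).any():
            raise ValueError("gains must be positive")
        if np.linalg.matrix_rank(t) < 2:
            raise ValueError(
                "rank-deficient tuning: preferred directions do not span the "
                "plane, so pen velocity is unidentifiable from the channels"
            )
        object.__setattr__(self, "tuning", t)
        object.__setattr__(self, "gains", g)

    @property
    def n_channels(self) -> int:
        return self.tuning.shape[0]


@dataclass
class TrialRecord:
    """One drawing trial: 50 ms pen coordinates plus 8-channel EMG at 1 kHz."""

    shape_id: str
    coords: np.ndarray          # (n, 2) tablet units
    emg: np.ndarray             # (8, T) muV
    sample_rate: float
    onset_index: int
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.coords.shape[0] < 2:
            raise ValueError("a trial needs at least 2 coordinate samples")
        span = (self.coords.shape[0] - 1) * _WIN
        if self.emg.shape[1] - self.onset_index < span:
            raise ValueError("EMG does not cover the coordinate span")

    @property
    def trigger(self) -> np.ndarray:
        return self.emg[-1]

    @property
    def decoding_channels(self) -> np.ndarray:
        return self.emg[:-1]


def _bandlimited_carrier(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """White noise band-passed to 10-450 Hz, per-50 ms-window RMS = 1."""
    sos = _sig.butter(4, [10.0, 450.0], btype="bandpass", fs=_SAMPLE_RATE, output="sos")
    x = _sig.sosfilt(sos, rng.standard_normal(n_samples))
    w = x[: (n_samples // _WIN) * _WIN].reshape(-1, _WIN)
    r = np.sqrt(np.mean(w * w, axis=1, keepdims=True))
    r[r == 0] = 1.0
    w /= r
    out = np.empty(n_samples)
    out[: w.size] = w.ravel()
    out[w.size:] = 0.0
    return out


def generate_emg(
    trace: np.ndarray,
    model: MuscleModel,
    rng_seed,
    pre_ms: float = 150.0,
    post_ms: float = 50.0,
) -> tuple[np.ndarray, int]:
    """Synthesize the 8-channel EMG for one trace.

    Returns ``(emg, onset_index)`` with ``emg`` of shape (8, T) in muV at
    1 kHz.  Movement onset (start of envelope modulation and of the trigger
    burst) is at ``onset_index = pre_ms`` samples; the trigger's first burst
    sample is also its 20 ms peak, so threshold-crossing onset detection
    recovers the true onset exactly.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    c = np.asarray(trace, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("trace must be (n>=2, 2)")
    deltas = np.diff(c, axis=0)                       # (n_w, 2) units/window
    n_w = deltas.shape[0]
    pre = int(round(pre_ms / 1000.0 * _SAMPLE_RATE))
    post = int(round(post_ms / 1000.0 * _SAMPLE_RATE))
    T = pre + n_w * _WIN + post
    onset = pre

    drive = model.tuning @ deltas.T                   # (7, n_w)
    env_w = model.baseline + model.gains[:, None] * np.maximum(0.0, drive)
    envelope = np.full((model.n_channels, T), model.baseline)
    envelope[:, onset : onset + n_w * _WIN] = np.repeat(env_w, _WIN, axis=1)

    emg = np.empty((model.n_channels + 1, T))
    for m in range(model.n_channels):
        carrier = _bandlimited_carrier(T, rng)
        emg[m] = envelope[m] * carrier
    if model.noise_sd > 0:
        emg[:-1] += rng.normal(0.0, model.noise_sd, size=(model.n_channels, T))

    trig = rng.normal(0.0, model.trigger_rest_sd, size=T)
    dur = int(round(model.trigger_dur_ms / 1000.0 * _SAMPLE_RATE))
    stop = min(onset + dur, T)
    trig[onset:stop] = rng.uniform(45.0, 0.9 * model.trigger_amp, size=stop - onset)
    trig[onset] = model.trigger_amp  # sharp click peak: first crossing is the max
    emg[-1] = trig
    return emg, onset


@dataclass(frozen=True)
class DatasetConfig:
    """Study-design parameters for a synthetic recording session.

    The defaults emulate one subject's session: 12 one-stroke shapes, 40
    repetitions each (480 trials), randomized template order.
    """

    shapes: tuple = SHAPE_IDS
    repetitions: int = 40
    seed: int = 0
    size: float = 400.0
    duration_ms: float = 1500.0
    jitter_frac: float = 0.01
    drift_frac: float = 0.10
    muscle_model: MuscleModel = field(default_factory=MuscleModel)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for s in self.shapes:
            if s not in SHAPE_IDS:
                raise ValueError(f"unknown shape_id: {s!r}")


def iter_trials(config: DatasetConfig):
    """Yield TrialRecords one at a time (lazy counterpart of generate_dataset).

    Deterministic given ``config.seed``: per-trial RNGs are spawned from a
    single root SeedSequence, and the shape order is a seeded permutation of
    the balanced shape list.
    """
    labels = np.repeat(np.arange(len(config.shapes)), config.repetitions)
    order_rng = np.random.default_rng(config.seed)
    labels = labels[order_rng.permutation(labels.size)]
    children = np.random.SeedSequence(config.seed).spawn(labels.size)
    for tid, (lab, ss) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(ss)
        spec = ShapeSpec(
            shape_id=config.shapes[lab],
            duration_ms=config.duration_ms,
            size=config.size,
            jitter_frac=config.jitter_frac,
            drift_frac=config.drift_frac,
        )
        coords = generate_trace(spec, rng)
        emg, onset = generate_emg(coords, config.muscle_model, rng)
        yield TrialRecord(
            shape_id=spec.shape_id,
            coords=coords,
            emg=emg.astype(np.float32),
            sample_rate=_SAMPLE_RATE,
            onset_index=onset,
            trial_id=tid,
        )


def generate_dataset(config: DatasetConfig) -> list:
    """Materialise the whole session (default 12 x 40 = 480 TrialRecords)."""
    return list(iter_trials(config))
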