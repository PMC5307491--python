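"""sEMG feature extraction: adjacent RMS windows and trigger-based onset.

The decoder uses a single time-domain feature, the root mean square of each
channel over adjacent, disjoint 50 ms analysis windows.  Windowing starts at
the movement onset detected on the trigger channel, so that feature row i
aligns with the coordinate difference (dx_i, dy_i) of the 50 ms pen-sampling
grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "CHANNEL_MUSCLES",
    "FeatureMatrix",
    "rms",
    "segment_adjacent",
    "detect_onset",
    "preprocess",
]

# Decoding-channel legend: feature d_k <- muscle. Channel 8 (not listed) is
# the trigger over Adductor Pollicis, used only for onset detection.
CHANNEL_MUSCLES = {
    "d1": "ECRB",  # extensor carpi radialis brevis
    "d2": "ED",    # extensor digitorum
    "d3": "ECU",   # extensor carpi ulnaris
    "d4": "FCR",   # flexor carpi radialis
    "d5": "TB",    # triceps brachii
    "d6": "BB",    # biceps brachii
    "d7": "DM",    # deltoid
}

TERMINALS = tuple(CHANNEL_MUSCLES)


@dataclass
class FeatureMatrix:
    """Per-window RMS features, one row per 50 ms analysis window.

    ``values`` is (n_windows, n_channels) in microvolts, channels ordered
    d1..d7 per :data:`CHANNEL_MUSCLES`.
    """

    values: np.ndarray
    window_ms: float = 50.0
    channels: tuple = field(default=TERMINALS)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if (v < 0).any():
            raise ValueError("RMS features must be non-negative")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channels[: self.values.shape[1]]))
        df.index.name = "window_index"
        return df

    def as_dict(self) -> dict:
        """Column vectors keyed by terminal name (d1..)."""
        return {name: self.values[:, j] for j, name in enumerate(self.channels[: self.values.shape[1]])}


def rms(window: np.ndarray) -> float:
    """Root mean square sqrt(mean(v_i^2)) of one analysis window (muV)."""
    v = np.asarray(window, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(v * v)))


def segment_adjacent(
    emg: np.ndarray,
    sample_rate: float = 1000.0,
    window_ms: float = 50.0,
    onset_index: int = 0,
) -> FeatureMatrix:
    """Extract adjacent disjoint RMS windows starting at the trial onset.

    ``emg`` is (n_channels, T) or (T,).  Windows are ``window_ms`` long
    (50 samples at 1 kHz), back-to-back from ``onset_index``; a trailing
    partial window is discarded.
    """
    x = np.asarray(emg, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("emg must be 1-D or (n_channels, T)")
    nwin_samples = int(round(window_ms * sample_rate / 1000.0))
    if nwin_samples < 1:
        raise ValueError("window shorter than one sample")
    if not (0 <= onset_index < x.shape[1]):
        raise ValueError("onset_index outside the signal")
    avail = x.shape[1] - onset_index
    n_windows = avail // nwin_samples
    if n_windows < 1:
        raise ValueError(
            f"signal holds {avail} samples after onset; "
            f"need at least one {nwin_samples}-sample window"
        )
    seg = x[:, onset_index : onset_index + n_windows * nwin_samples]
    seg = seg.reshape(x.shape[0], n_windows, nwin_samples)
    vals = np.sqrt(np.mean(seg * seg, axis=2)).T  # (n_windows, n_channels)
    return FeatureMatrix(values=vals, window_ms=window_ms)


def detect_onset(
    trigger: np.ndarray,
    threshold: float = 40.0,
    peak_window_ms: float = 20.0,
    sample_rate: float = 1000.0,
) -> int:
    """Trial onset from the trigger channel.

    Finds the first sample whose absolute amplitude crosses ``threshold``
    (40 muV), then returns the index of the maximum absolute value within
    the following ``peak_window_ms`` (20 samples at 1 kHz, inclusive of the
    crossing sample; ties broken by earliest index).
    """
    a = np.abs(np.asarray(trigger, dtype=float).ravel())
    above = np.nonzero(a >= threshold)[0]
    if above.size == 0:
        raise ValueError("no trial detected: trigger never crosses threshold")
    k = int(above[0])
    span = int(round(peak_window_ms * sample_rate / 1000.0))
    window = a[k : k + max(span, 1)]
    return k + int(np.argmax(window))


def preprocess(
    emg: np.ndarray,
    sample_rate: float = 1000.0,
    band: tuple = (10.0, 500.0),
    notch: float = 50.0,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass (10-500 Hz, 4th-order Butterworth) plus 50 Hz notch.

    The contract is the attenuation profile (>= 20 dB at the notch, <= 3 dB
    in the passband), not a specific filter family.  A band edge at or above
    Nyquist is clipped just below it; inverted or non-positive edges raise.
    """
    x = np.asarray(emg, dtype=float)
    lo, hi = band
    nyq = sample_rate / 2.0
    if lo <= 0 or hi <= lo:
        raise ValueError("band edges must satisfy 0 < low < high")
    if lo >= nyq:
        raise ValueError("band low edge at or above Nyquist")
    hi = min(hi, 0.99 * nyq)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    y = _sig.sosfiltfilt(sos, x, axis=-1)
    if notch:
        if not (0 < notch < nyq):
            raise ValueError("notch frequency inconsistent with Nyquist")
        b, a = _sig.iirnotch(notch, notch_q, fs=sample_rate)
        y = _sig.filtfilt(b, a, y, axis=-1)
    return y
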