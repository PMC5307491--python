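"""Kalman-filter baseline: MVAR state transition + linear RMS measurement.

The comparison model fuses two information sources about the 2-vector state
s_i = (dx_i, dy_i):

* a first-order multivariate autoregression s_i = A s_{i-1} + v_i with
  process noise covariance Q (the "physical characteristics of drawing"),
* a linear measurement model s_i = H z_i + w_i with the 7-vector of window
  RMS values z_i and noise covariance R.

A (2x2) and H (2x7) are fitted by ordinary least squares without intercept
on pooled training windows (lag pairs never straddle trial boundaries);
Q and R are the sample covariances of the respective residuals.  Filtering
follows the three-step recursion: predict s^_{i|i-1} = A s^_{i-1},
P_{i|i-1} = A P A' + Q; gain K = P_{i|i-1}(P_{i|i-1} + R)^{-1}; update
against the regression prediction s^_{i|z} = H z_i.  The gain takes this
form because the "measurement" fed to the filter is already a state-space
prediction, so the observation matrix is the identity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace_state import reconstruct

__all__ = ["KalmanTrace", "KalmanTraceResults", "kf_step"]


def _as_trial_list(arrs, width, name):
    out = []
    for a in arrs:
        a = np.atleast_2d(np.asarray(a, dtype=float))
        if a.shape[1] != width:
            raise ValueError(f"{name} trials must have {width} columns")
        out.append(a)
    return out


class KalmanTrace:
    """Kalman baseline fitted to per-trial delta targets and RMS features.

    Parameters
    ----------
    deltas : sequence of (n_i, 2) arrays
        Coordinate differences per training trial.
    features : sequence of (n_i, 7) arrays
        Aligned window-RMS observations per trial.
    ridge : float
        Optional Tikhonov term added to (P + R) at inversion time; use when
        the filter reports singularity.
    """

    def __init__(self, deltas: Sequence, features: Sequence, ridge: float = 0.0):
        if len(deltas) != len(features):
            raise ValueError("deltas and features must list the same trials")
        self.deltas = _as_trial_list(deltas, 2, "delta")
        n_obs = np.atleast_2d(np.asarray(features[0], float)).shape[1]
        self.features = _as_trial_list(features, n_obs, "feature")
        for s, z in zip(self.deltas, self.features):
            if s.shape[0] != z.shape[0]:
                raise ValueError("trial delta/feature row counts differ")
        self.ridge = float(ridge)
        self.n_obs = n_obs

    def fit(self) -> "KalmanTraceResults":
        S = np.vstack(self.deltas)
        Z = np.vstack(self.features)
        S_prev = np.vstack([s[:-1] for s in self.deltas if s.shape[0] > 1])
        S_next = np.vstack([s[1:] for s in self.deltas if s.shape[0] > 1])
        if Z.shape[0] < self.n_obs + 1 or S_prev.shape[0] < 2:
            raise ValueError("not enough aligned rows to fit the model")
        rank = np.linalg.matrix_rank(Z)
        if rank < self.n_obs:
            _, _, vt = np.linalg.svd(Z)
            ch = int(np.argmax(np.abs(vt[-1]))) + 1
            raise ValueError(
                f"rank-deficient features (rank {rank} < {self.n_obs}); "
                f"channel d{ch} is linearly dependent on the others"
            )
        # OLS, no intercept: argmin ||S_next - S_prev A'||, ||S - Z H'||
        A = np.linalg.lstsq(S_prev, S_next, rcond=None)[0].T
        H = np.linalg.lstsq(Z, S, rcond=None)[0].T
        res_a = S_next - S_prev @ A.T
        res_h = S - Z @ H.T
        Q = res_a.T @ res_a / max(res_a.shape[0] - 1, 1)
        R = res_h.T @ res_h / max(res_h.shape[0] - 1, 1)
        return KalmanTraceResults(
            model=self, A=A, H=H, Q=Q, R=R,
            s0=S.mean(axis=0), P0=Q.copy(),
            n_train_rows=S.shape[0],
        )


def kf_step(
    A: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    H: np.ndarray,
    s_prev: np.ndarray,
    P_prev: np.ndarray,
    z: np.ndarray,
    ridge: float = 0.0,
):
    """One predict/gain/update cycle; returns (s, P).

    P is re-symmetrised after the update so it stays PSD over long trials.
    """
    s_pred = A @ s_prev
    P_pred = A @ P_prev @ A.T + Q
    M = P_pred + R
    if ridge:
        M = M + ridge * np.eye(M.shape[0])
    try:
        K = P_pred @ np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular innovation covariance (P + R); pass ridge > 0 to regularise"
        ) from exc
    s_meas = H @ z
    s = s_pred + K @ (s_meas - s_pred)
    P = P_pred - K @ P_pred
    P = 0.5 * (P + P.T)
    return s, P


@dataclass
class KalmanTraceResults:
    """Fitted matrices plus filtering / reconstruction methods."""

    model: KalmanTrace
    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    s0: np.ndarray
    P0: np.ndarray
    n_train_rows: int

    def step(self, s_prev, P_prev, z):
        return kf_step(self.A, self.Q, self.R, self.H,
                       np.asarray(s_prev, float), np.asarray(P_prev, float),
                       np.asarray(z, float), self.model.ridge)

    def filter(self, features: np.ndarray) -> np.ndarray:
        """Filtered delta estimates for one trial's (n, 7) feature sequence."""
        Z = np.atleast_2d(np.asarray(features, dtype=float))
        s, P = self.s0.copy(), self.P0.copy()
        out = np.empty((Z.shape[0], 2))
        for i, z in enumerate(Z):
            s, P = self.step(s, P, z)
            out[i] = s
        return out

    predict = filter

    def reconstruct(self, features: np.ndarray, start_point) -> np.ndarray:
        """Filter the deltas then rebuild the trace from the stroke start."""
        return reconstruct(self.filter(features), start_point=start_point)

    def summary(self) -> str:
        fmt = lambda M: np.array2string(M, precision=4, suppress_small=True)
        return "\n".join([
            "Kalman trace baseline (OLS-trained)",
            "=" * 46,
            f"training rows: {self.n_train_rows}",
            f"A (state transition):\n{fmt(self.A)}",
            f"Q (process noise):\n{fmt(self.Q)}",
            f"H (measurement, 2x{self.H.shape[1]}):\n{fmt(self.H)}",
            f"R (measurement noise):\n{fmt(self.R)}",
        ])

    def to_json_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("A", "H", "Q", "R", "s0", "P0")}
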