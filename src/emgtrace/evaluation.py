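"""Reconstruction scoring and the two experiment designs.

Reconstruction quality per trial and coordinate is the squared correlation
coefficient in its coefficient-of-determination form,

    CC^2 = 1 - sum_i (s^_i - s_i)^2 / sum_i (s_i - s_bar)^2,

computed within each trial and then averaged across trials (never pooled
residuals).  CC^2 <= 1 and may be negative; negative values are reported
as-is.

Two calibration designs mirror the study protocol: *within-group* trains a
single model pair F(x), F(y) on the pooled training trials of all shapes;
*between-group* trains a separate pair per shape and tests it on that
shape's held-out trials.  The train/test split is a random 70/30 partition
of trials, stratified by shape so every shape appears in the test set.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import detect_onset, preprocess as _preprocess, segment_adjacent
from .gep.model import GepConfig, GEPRegression
from .kalman import KalmanTrace
from .printed import printed_model
from .trace_state import reconstruct, to_deltas

__all__ = [
    "cc2",
    "PreparedTrial",
    "prepare_trials",
    "stratified_split",
    "EvalResult",
    "GepTrainer",
    "KalmanTrainer",
    "PrintedTrainer",
    "OracleTrainer",
    "run_within_group",
    "run_between_group",
    "get_trainer",
]


def cc2(actual: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SStot for one coordinate of one trial.

    Raises when the actual series is constant (zero variance): the score is
    undefined and the trial should be flagged rather than silently scored.
    """
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError("actual and predicted must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    sstot = float(np.sum((a - a.mean()) ** 2))
    if sstot == 0:
        raise ValueError("actual series is constant; CC^2 undefined for this trial")
    return 1.0 - float(np.sum((p - a) ** 2)) / sstot


@dataclass
class PreparedTrial:
    """One trial reduced to aligned features and targets.

    ``features`` (n, 7) window RMS; ``deltas`` (n, 2) coordinate
    differences; ``start_point`` the true stroke start used to anchor
    reconstruction.
    """

    trial_id: int
    shape_id: str
    features: np.ndarray
    deltas: np.ndarray
    start_point: np.ndarray
    coords: np.ndarray


def prepare_trial(record, use_detected_onset: bool = True, filter_emg: bool = False) -> PreparedTrial:
    emg = np.asarray(record.emg, dtype=float)
    onset = detect_onset(emg[-1]) if use_detected_onset else record.onset_index
    chans = emg[:-1]
    if filter_emg:
        chans = _preprocess(chans, record.sample_rate)
    fm = segment_adjacent(chans, sample_rate=record.sample_rate, onset_index=onset)
    ds = to_deltas(record.coords)
    n = min(fm.n_windows, len(ds))
    return PreparedTrial(
        trial_id=record.trial_id,
        shape_id=record.shape_id,
        features=fm.values[:n],
        deltas=ds.deltas[:n],
        start_point=ds.start_point,
        coords=record.coords[: n + 1],
    )


def prepare_trials(records: Iterable, **kw) -> list:
    return [prepare_trial(r, **kw) for r in records]


def stratified_split(trials: Sequence[PreparedTrial], train_frac: float = 0.7,
                     seed: Optional[int] = None):
    """Random per-shape 70/30 trial split; every shape lands in both sets."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_shape: dict = {}
    for i, t in enumerate(trials):
        by_shape.setdefault(t.shape_id, []).append(i)
    train_idx, test_idx = [], []
    for shape in sorted(by_shape):
        idx = np.asarray(by_shape[shape])
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    if not test_idx:
        raise ValueError("split produced an empty test set")
    return [trials[i] for i in sorted(train_idx)], [trials[i] for i in sorted(test_idx)]


# ---------------------------------------------------------------------------
# trainers: fit(train_trials, seed) -> predictor with predict_deltas(features)

class GepTrainer:
    """Evolves one GEP model per coordinate on pooled training windows."""

    def __init__(self, config: Optional[GepConfig] = None, n_restarts: int = 1):
        self.config = config or GepConfig.scaled_down()
        self.n_restarts = n_restarts

    def fit(self, trials: Sequence[PreparedTrial], seed=None):
        X = np.vstack([t.features for t in trials])
        D = np.vstack([t.deltas for t in trials])
        ss = np.random.SeedSequence(seed).spawn(2)
        results = [
            GEPRegression(D[:, j], X, self.config).fit(seed=ss[j], n_restarts=self.n_restarts)
            for j in (0, 1)
        ]

        class _Predictor:
            def __init__(self, rx, ry):
                self.results = (rx, ry)

            def predict_deltas(self, features):
                return np.column_stack([r.predict(features) for r in self.results])

        return _Predictor(*results)


class KalmanTrainer:
    """Fits the OLS-trained Kalman baseline; prediction filters each trial."""

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, trials: Sequence[PreparedTrial], seed=None):
        res = KalmanTrace(
            [t.deltas for t in trials], [t.features for t in trials], ridge=self.ridge
        ).fit()

        class _Predictor:
            def __init__(self, res):
                self.results = res

            def predict_deltas(self, features):
                return self.results.filter(features)

        return _Predictor(res)


class PrintedTrainer:
    """No training: evaluates the fixed published formulas F(x), F(y)."""

    def __init__(self, **readings):
        self.models = (printed_model("x", **readings), printed_model("y", **readings))

    def fit(self, trials, seed=None):
        models = self.models

        class _Predictor:
            def predict_deltas(self, features):
                return np.column_stack([m.predict(features) for m in models])

        return _Predictor()


class OracleTrainer:
    """Harness sanity check: 'predicts' the true deltas (test-time oracle)."""

    def fit(self, trials, seed=None):
        class _Predictor:
            def predict_deltas(self, features):
                raise RuntimeError("oracle predictor needs the trial, not features")

        return _Predictor()


_TRAINERS = {"gep": GepTrainer, "kf": KalmanTrainer, "printed": PrintedTrainer,
             "oracle": OracleTrainer}


def get_trainer(name, **kw):
    if isinstance(name, str):
        try:
            return _TRAINERS[name](**kw)
        except KeyError:
            raise ValueError(f"unknown trainer {name!r}; choose from {sorted(_TRAINERS)}")
    return name


# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-trial, per-shape and overall CC^2 for both coordinates."""

    per_trial: pd.DataFrame
    design: str

    @property
    def per_shape(self) -> pd.DataFrame:
        """Mean +- sd per shape plus an 'All' row (X, Y, average columns)."""
        rows = []
        groups = list(self.per_trial.groupby("shape_id", sort=False))
        groups.append(("All", self.per_trial))
        for shape, g in groups:
            rows.append({
                "shape": shape,
                "cc2_x_mean": g["cc2_x"].mean(), "cc2_x_sd": g["cc2_x"].std(ddof=1),
                "cc2_y_mean": g["cc2_y"].mean(), "cc2_y_sd": g["cc2_y"].std(ddof=1),
                "cc2_avg_mean": g["cc2_avg"].mean(), "cc2_avg_sd": g["cc2_avg"].std(ddof=1),
            })
        return pd.DataFrame(rows)

    @property
    def overall(self) -> dict:
        pt = self.per_trial
        return {
            "cc2_x": float(pt["cc2_x"].mean()),
            "cc2_y": float(pt["cc2_y"].mean()),
            "cc2_avg": float(pt["cc2_avg"].mean()),
            "n_test_trials": int(len(pt)),
        }

    def summary(self) -> str:
        ov = self.overall
        tab = self.per_shape
        lines = [
            f"{self.design} design: {ov['n_test_trials']} test trials",
            f"mean CC^2  x: {ov['cc2_x']:.3f}  y: {ov['cc2_y']:.3f}  "
            f"avg: {ov['cc2_avg']:.3f}",
            "",
            tab.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def _score_trials(predictor, test_trials, oracle: bool = False) -> pd.DataFrame:
    rows = []
    for t in test_trials:
        deltas_hat = t.deltas if oracle else predictor.predict_deltas(t.features)
        coords_hat = reconstruct(deltas_hat, start_point=t.start_point)
        actual = reconstruct(t.deltas, start_point=t.start_point)
        rows.append({
            "trial_id": t.trial_id,
            "shape_id": t.shape_id,
            "cc2_x": cc2(actual[:, 0], coords_hat[:, 0]),
            "cc2_y": cc2(actual[:, 1], coords_hat[:, 1]),
        })
    df = pd.DataFrame(rows)
    df["cc2_avg"] = 0.5 * (df["cc2_x"] + df["cc2_y"])
    return df


def run_within_group(trials: Sequence[PreparedTrial], trainer="gep",
                     split: float = 0.7, seed: Optional[int] = None,
                     **trainer_kw) -> EvalResult:
    """One pooled model pair over all shapes, scored on the held-out 30%."""
    trainer = get_trainer(trainer, **trainer_kw)
    train, test = stratified_split(trials, split, seed)
    predictor = trainer.fit(train, seed=seed)
    df = _score_trials(predictor, test, oracle=isinstance(trainer, OracleTrainer))
    return EvalResult(per_trial=df, design="within-group")


def run_between_group(trials: Sequence[PreparedTrial], trainer="gep",
                      split: float = 0.7, seed: Optional[int] = None,
                      **trainer_kw) -> EvalResult:
    """A separate model pair per shape (12 F(x) + 12 F(y) by default)."""
    trainer = get_trainer(trainer, **trainer_kw)
    train, test = stratified_split(trials, split, seed)
    frames = []
    shapes = sorted({t.shape_id for t in trials})
    for k, shape in enumerate(shapes):
        tr = [t for t in train if t.shape_id == shape]
        te = [t for t in test if t.shape_id == shape]
        if not tr or not te:
            raise ValueError(f"shape {shape!r} missing from a split")
        shape_seed = None if seed is None else seed + 1000 * (k + 1)
        predictor = trainer.fit(tr, seed=shape_seed)
        frames.append(_score_trials(predictor, te,
                                    oracle=isinstance(trainer, OracleTrainer)))
    df = pd.concat(frames, ignore_index=True)
    return EvalResult(per_trial=df, design="between-group")
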