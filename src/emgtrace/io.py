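"""On-disk trial formats: per-trial coordinate/EMG CSVs plus a manifest.

A dataset directory holds, per trial, ``trial_<id>_coords.csv``
(``t_ms,x,y`` at 50 ms) and ``trial_<id>_emg.csv`` (``t_ms,ch1..ch8`` in
muV at 1 kHz), indexed by ``manifest.csv`` (trial_id, shape_id, paths,
onset_index, sample_rate).  Everything is plain text so datasets diff and
version cleanly.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .synth import TrialRecord

__all__ = ["save_dataset", "load_dataset", "save_results"]

MANIFEST = "manifest.csv"


def save_dataset(records: Iterable[TrialRecord], outdir) -> Path:
    """Write trials + manifest under ``outdir``; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        cpath = out / f"trial_{rec.trial_id:04d}_coords.csv"
        epath = out / f"trial_{rec.trial_id:04d}_emg.csv"
        n = rec.coords.shape[0]
        cdf = pd.DataFrame({
            "t_ms": np.arange(n) * 50.0,
            "x": rec.coords[:, 0],
            "y": rec.coords[:, 1],
        })
        cdf.to_csv(cpath, index=False, float_format="%.4f")
        T = rec.emg.shape[1]
        edf = pd.DataFrame(rec.emg.T, columns=[f"ch{i+1}" for i in range(rec.emg.shape[0])])
        edf.insert(0, "t_ms", np.arange(T) * 1000.0 / rec.sample_rate)
        edf.to_csv(epath, index=False, float_format="%.3f")
        rows.append({
            "trial_id": rec.trial_id,
            "shape_id": rec.shape_id,
            "coords_path": cpath.name,
            "emg_path": epath.name,
            "onset_index": rec.onset_index,
            "sample_rate": rec.sample_rate,
        })
    mpath = out / MANIFEST
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


def load_dataset(path) -> Iterator[TrialRecord]:
    """Yield TrialRecords from a dataset directory (or its manifest path)."""
    p = Path(path)
    mpath = p / MANIFEST if p.is_dir() else p
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest at {mpath}")
    base = mpath.parent
    manifest = pd.read_csv(mpath)
    required = {"trial_id", "shape_id", "coords_path", "emg_path",
                "onset_index", "sample_rate"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for row in manifest.itertuples(index=False):
        cdf = pd.read_csv(base / row.coords_path)
        edf = pd.read_csv(base / row.emg_path)
        ch_cols = [c for c in edf.columns if c.startswith("ch")]
        if not ch_cols:
            raise ValueError(f"{row.emg_path}: no chN columns")
        yield TrialRecord(
            shape_id=row.shape_id,
            coords=cdf[["x", "y"]].to_numpy(dtype=float),
            emg=edf[ch_cols].to_numpy(dtype=float).T,
            sample_rate=float(row.sample_rate),
            onset_index=int(row.onset_index),
            trial_id=int(row.trial_id),
        )


def save_results(result, outdir, models: dict | None = None) -> Path:
    """Write per-trial/per-shape CSVs and a JSON summary for one run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_trial.to_csv(out / "per_trial.csv", index=False)
    result.per_shape.to_csv(out / "per_shape.csv", index=False, float_format="%.4f")
    summary = {"design": result.design, **result.overall}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if models:
        (out / "models.json").write_text(json.dumps(models, indent=2))
    return out
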