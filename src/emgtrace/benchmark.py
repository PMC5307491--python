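"""The default synthetic benchmark: dataset -> features -> designs.

Builds the 12-shape x 40-repetition synthetic session trial by trial
(EMG is synthesized, reduced to window-RMS features via trigger-detected
onsets, and discarded), then runs the within-group / between-group designs
with a chosen trainer.  This is the path the acceptance script and the
pipeline-level tests exercise; problem sizes are keyword-tunable so small
variants run quickly.
"""
from __future__ import annotations

from typing import Optional

from .evaluation import (
    EvalResult,
    GepTrainer,
    KalmanTrainer,
    prepare_trial,
    run_between_group,
    run_within_group,
)
from .gep.model import GepConfig
from .synth import DatasetConfig, iter_trials

__all__ = ["benchmark_trials", "gep_benchmark", "kalman_benchmark"]


def benchmark_trials(seed: int = 0, repetitions: int = 40, **config_kw) -> list:
    """Prepared trials of the default synthetic session (streamed)."""
    cfg = DatasetConfig(seed=seed, repetitions=repetitions, **config_kw)
    return [prepare_trial(rec) for rec in iter_trials(cfg)]


def _default_gep_config(max_fitness_cases: Optional[int], generations: int) -> GepConfig:
    return GepConfig.scaled_down(
        population=100,
        generations=generations,
        max_fitness_cases=max_fitness_cases,
    )


def gep_benchmark(
    seed: int = 0,
    design: str = "within",
    repetitions: int = 40,
    n_restarts: int = 5,
    generations: int = 200,
    max_fitness_cases: Optional[int] = 2000,
    trials: Optional[list] = None,
    split: float = 0.7,
) -> EvalResult:
    """Hybrid-pipeline benchmark with the reduced evolution budget.

    ``design`` is ``"within"`` or ``"between"``; ``n_restarts`` independent
    evolution runs are made per model and the best kept (best-of-seeds).
    """
    if trials is None:
        trials = benchmark_trials(seed=seed, repetitions=repetitions)
    cfg = _default_gep_config(max_fitness_cases, generations)
    trainer = GepTrainer(cfg, n_restarts=n_restarts)
    runner = run_within_group if design == "within" else run_between_group
    return runner(trials, trainer=trainer, split=split, seed=seed)


def kalman_benchmark(
    seed: int = 0,
    design: str = "within",
    repetitions: int = 40,
    trials: Optional[list] = None,
    split: float = 0.7,
) -> EvalResult:
    """Kalman baseline on the same benchmark and split."""
    if trials is None:
        trials = benchmark_trials(seed=seed, repetitions=repetitions)
    runner = run_within_group if design == "within" else run_between_group
    return runner(trials, trainer=KalmanTrainer(), split=split, seed=seed)
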