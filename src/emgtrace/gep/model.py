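"""Gene expression programming as a statsmodels-style regression model.

:class:`GEPRegression` holds the training data (RMS feature matrix as
exogenous variables, one coordinate-difference series as the endogenous
target) and a :class:`GepConfig`; ``fit()`` runs the evolutionary loop and
returns a :class:`GEPRegressionResults` carrying the best-ever individual,
its explicit formula, the fitness trajectory, and prediction/summary
methods.

Fitness of individual i is f_i = f_max / (RMSE_i + 1) with f_max = 1000,
so f = 1000 exactly when the individual reproduces every fitness case and
f -> 0 as the error grows.  Selection is roulette-wheel with elitism: the
single best individual of each generation is copied unchanged into the
next, which makes the best-so-far fitness non-decreasing.  Termination is
a generation cap or reaching max fitness; an optional stagnation patience
stops runs whose best fitness has stopped improving.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .karva import (
    DEFAULT_FUNCTIONS,
    RNC_SYMBOL,
    Chromosome,
    FunctionSet,
    Gene,
    evaluate_chromosome,
    orf_key,
    to_infix,
)
from .operators import apply_operators, roulette_select

__all__ = ["GepConfig", "GEPRegression", "GEPRegressionResults", "fitness", "rmse"]

F_MAX = 1000.0
DEFAULT_TERMINALS = ("d1", "d2", "d3", "d4", "d5", "d6", "d7")


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Root mean square error over the fitness cases."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal length")
    if p.size == 0:
        raise ValueError("no fitness cases")
    with np.errstate(all="ignore"):
        # protected predictions are bounded by 1e300; clamp the error so the
        # square cannot overflow (such individuals get ~zero fitness anyway)
        err = np.clip(p - t, -1e150, 1e150)
        return float(np.sqrt(np.mean(err * err)))


def fitness(predictions: np.ndarray, targets: np.ndarray) -> float:
    """f = f_max / (RMSE + 1); equals 1000 iff the fit is perfect."""
    return F_MAX / (rmse(predictions, targets) + 1.0)


@dataclass(frozen=True)
class GepConfig:
    """Evolution parameters.

    Defaults reproduce the published training setup: 200 chromosomes of 6
    genes with head 15 (tail 16, gene size 31), addition linking, the
    ten-function set over terminals d1..d7, per-symbol mutation 0.0014,
    inversion/transposition 0.0055, recombination 0.0028, terminating at
    2000 generations or max fitness.  ``scaled_down()`` returns a preset
    for small compute budgets with canonical textbook operator rates.
    """

    population: int = 200
    n_genes: int = 6
    head: int = 15
    generations: int = 2000
    mutation_rate: float = 0.0014
    inversion_rate: float = 0.0055
    is_rate: float = 0.0055
    ris_rate: float = 0.0055
    gene_transposition_rate: float = 0.0055
    one_point_rate: float = 0.0028
    two_point_rate: float = 0.0028
    gene_recombination_rate: float = 0.0028
    terminals: tuple = DEFAULT_TERMINALS
    functions: FunctionSet = field(default_factory=lambda: DEFAULT_FUNCTIONS)
    rnc: bool = False
    rnc_range: tuple = (-10.0, 10.0)
    target_fitness: float = F_MAX
    patience: Optional[int] = None
    max_fitness_cases: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in (
            "mutation_rate", "inversion_rate", "is_rate", "ris_rate",
            "gene_transposition_rate", "one_point_rate", "two_point_rate",
            "gene_recombination_rate",
        ):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def tail(self) -> int:
        """t = h(n_max - 1) + 1, guaranteeing decodability."""
        return self.head * (self.functions.max_arity - 1) + 1

    @property
    def gene_size(self) -> int:
        return self.head + self.tail

    @property
    def head_terminals(self) -> tuple:
        return self.terminals + ((RNC_SYMBOL,) if self.rnc else ())

    tail_terminals = head_terminals

    @classmethod
    def scaled_down(cls, **overrides) -> "GepConfig":
        """Small-budget preset: population 100, 200 generations, classic
        Ferreira-strength operator rates, stagnation patience."""
        base = dict(
            population=100,
            generations=200,
            mutation_rate=2.0 / 186.0,  # ~2 point mutations per chromosome
            inversion_rate=0.1,
            is_rate=0.1,
            ris_rate=0.1,
            gene_transposition_rate=0.1,
            one_point_rate=0.3,
            two_point_rate=0.3,
            gene_recombination_rate=0.1,
            patience=40,
        )
        base.update(overrides)
        return cls(**base)


def random_gene(cfg: GepConfig, rng: np.random.Generator) -> Gene:
    head_alpha = list(cfg.functions) + list(cfg.head_terminals)
    tail_alpha = list(cfg.tail_terminals)
    syms = tuple(rng.choice(head_alpha) for _ in range(cfg.head)) + tuple(
        rng.choice(tail_alpha) for _ in range(cfg.tail)
    )
    if cfg.rnc:
        lo, hi = cfg.rnc_range
        consts = tuple(float(x) for x in rng.uniform(lo, hi, size=cfg.tail))
        dc = tuple(int(x) for x in rng.integers(0, cfg.tail, size=cfg.tail))
        return Gene(syms, cfg.head, dc, consts)
    return Gene(syms, cfg.head)


def random_chromosome(cfg: GepConfig, rng: np.random.Generator) -> Chromosome:
    return Chromosome(tuple(random_gene(cfg, rng) for _ in range(cfg.n_genes)))


class _GeneValueCache:
    """Memoises gene phenotype values on the training data, keyed by ORF."""

    def __init__(self, data: Mapping[str, np.ndarray], functions: FunctionSet,
                 max_entries: int = 40000):
        self.data = data
        self.functions = functions
        self.max_entries = max_entries
        self._store: dict = {}

    def value(self, gene: Gene) -> np.ndarray:
        key = orf_key(gene, self.functions)
        v = self._store.get(key)
        if v is None:
            from .karva import evaluate_gene

            v = evaluate_gene(gene, self.data, self.functions)
            if len(self._store) >= self.max_entries:
                self._store.clear()
            self._store[key] = v
        return v


class GEPRegression:
    """Symbolic regression of one coordinate-difference series on RMS features.

    Parameters
    ----------
    endog : (m,) array
        Target values (dx or dy per 50 ms window), pooled over trials.
    exog : (m, k) array or DataFrame
        RMS features; columns map to the terminals in ``config.terminals``.
    config : GepConfig, optional
    """

    def __init__(self, endog, exog, config: Optional[GepConfig] = None):
        self.config = config or GepConfig()
        if isinstance(exog, pd.DataFrame):
            exog = exog[list(self.config.terminals)].to_numpy(dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog row counts differ")
        if self.exog.shape[1] != len(self.config.terminals):
            raise ValueError(
                f"exog has {self.exog.shape[1]} columns; config names "
                f"{len(self.config.terminals)} terminals"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str,
                       config: Optional[GepConfig] = None) -> "GEPRegression":
        config = config or GepConfig()
        return cls(df[target], df[list(config.terminals)], config)

    def _data_dict(self, X: np.ndarray) -> dict:
        return {t: X[:, j] for j, t in enumerate(self.config.terminals)}

    def fit(self, seed=None, n_restarts: int = 1, verbose: bool = False
            ) -> "GEPRegressionResults":
        """Evolve; with ``n_restarts`` > 1 keep the best run by final fitness."""
        root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        best = None
        for ss in root.spawn(max(1, n_restarts)):
            res = self._run(np.random.default_rng(ss), verbose)
            if best is None or res.fitness > best.fitness:
                best = res
        return best

    def _run(self, rng: np.random.Generator, verbose: bool) -> "GEPRegressionResults":
        cfg = self.config
        X, y = self.exog, self.endog
        if cfg.max_fitness_cases and y.size > cfg.max_fitness_cases:
            idx = rng.choice(y.size, size=cfg.max_fitness_cases, replace=False)
            X, y = X[idx], y[idx]
        data = self._data_dict(X)
        cache = _GeneValueCache(data, cfg.functions)
        chrom_fit: dict = {}

        def chrom_fitness(c: Chromosome) -> float:
            f = chrom_fit.get(c)
            if f is None:
                pred = cache.value(c.genes[0]).copy()
                for g in c.genes[1:]:
                    pred = pred + cache.value(g)
                np.clip(pred, -1e300, 1e300, out=pred)
                f = F_MAX / (rmse(pred, y) + 1.0)
                if len(chrom_fit) > 200000:
                    chrom_fit.clear()
                chrom_fit[c] = f
            return f

        pop = [random_chromosome(cfg, rng) for _ in range(cfg.population)]
        best_chrom, best_fit = None, -np.inf
        history = []
        stagnant = 0
        for gen in range(cfg.generations):
            fits = np.array([chrom_fitness(c) for c in pop])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit:
                best_fit = float(fits[gen_best])
                best_chrom = pop[gen_best]
                stagnant = 0
            else:
                stagnant += 1
            history.append(best_fit)
            if verbose and gen % 20 == 0:
                print(f"gen {gen:4d}  best fitness {best_fit:.3f}")
            if best_fit >= cfg.target_fitness:
                break
            if cfg.patience is not None and stagnant >= cfg.patience:
                break
            parents = roulette_select(fits, cfg.population - 1, rng)
            offspring = apply_operators([pop[i] for i in parents], cfg, rng)
            pop = [best_chrom] + offspring  # elitism: best copied unmodified
        return GEPRegressionResults(
            model=self,
            chromosome=best_chrom,
            fitness=best_fit,
            history=np.asarray(history),
            n_fitness_cases=y.size,
        )


@dataclass
class GEPRegressionResults:
    """Best-ever individual of one evolution run, with diagnostics."""

    model: GEPRegression
    chromosome: Chromosome
    fitness: float
    history: np.ndarray
    n_fitness_cases: int

    @property
    def rmse(self) -> float:
        """Training RMSE implied by f = 1000/(RMSE+1)."""
        return F_MAX / self.fitness - 1.0

    @property
    def formula(self) -> str:
        return to_infix(self.chromosome, self.model.config.functions)

    def predict(self, exog) -> np.ndarray:
        cfg = self.model.config
        if isinstance(exog, pd.DataFrame):
            exog = exog[list(cfg.terminals)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        data = {t: X[:, j] for j, t in enumerate(cfg.terminals)}
        return evaluate_chromosome(self.chromosome, data, cfg.functions)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "GEP symbolic regression results",
            "=" * 46,
            f"fitness cases:        {self.n_fitness_cases}",
            f"population:           {cfg.population}",
            f"generations run:      {len(self.history)}",
            f"best fitness:         {self.fitness:.3f} / {F_MAX:.0f}",
            f"training RMSE:        {self.rmse:.4f}",
            "formula:",
            "  " + self.formula,
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        cfg = self.model.config
        return {
            "fitness": self.fitness,
            "rmse": self.rmse,
            "formula": self.formula,
            "genes": [list(g.symbols) for g in self.chromosome.genes],
            "head": cfg.head,
            "terminals": list(cfg.terminals),
            "history": [float(h) for h in self.history],
        }
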