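import numpy as np
import pytest

from emgtrace.gep import (
    GepConfig,
    GEPRegression,
    apply_operators,
    fitness,
    random_chromosome,
    rmse,
    roulette_select,
)
from emgtrace.gep.karva import validate_gene


class TestFitness:
    def test_perfect_fit_reaches_max(self, rng):
        y = rng.normal(size=50)
        assert fitness(y, y) == pytest.approx(1000.0)

    def test_unit_rmse_halves_fitness(self):
        t = np.zeros(4)
        p = np.ones(4)
        assert rmse(p, t) == pytest.approx(1.0)
        assert fitness(p, t) == pytest.approx(500.0)

    def test_matches_two_pass_reference(self, rng):
        p, t = rng.normal(size=64), rng.normal(size=64)
        ref = (sum((a - b) ** 2 for a, b in zip(p, t)) / 64) ** 0.5
        assert rmse(p, t) == pytest.approx(ref, rel=1e-12)
        assert fitness(p, t) == pytest.approx(1000.0 / (ref + 1.0), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fitness([], [])


class TestSelection:
    def test_single_fit_member_dominates(self, rng):
        f = np.array([0.0, 0.0, 7.0, 0.0])
        idx = roulette_select(f, 1000, rng)
        assert (idx == 2).all()

    def test_all_zero_falls_back_to_uniform(self, rng):
        idx = roulette_select(np.zeros(5), 2000, rng)
        assert set(idx) == set(range(5))

    def test_sampling_frequencies_proportional(self, rng):
        """Observed draw frequencies sit inside 5-sigma binomial bands."""
        f = np.array([100.0, 300.0, 600.0])
        n = 100000
        idx = roulette_select(f, n, rng)
        for j, fj in enumerate(f):
            p = fj / f.sum()
            obs = np.mean(idx == j)
            assert abs(obs - p) < 5 * np.sqrt(p * (1 - p) / n)


class TestOperators:
    def test_zero_rates_leave_population_unchanged(self, rng):
        cfg = GepConfig(mutation_rate=0.0, inversion_rate=0.0, is_rate=0.0,
                        ris_rate=0.0, gene_transposition_rate=0.0,
                        one_point_rate=0.0, two_point_rate=0.0,
                        gene_recombination_rate=0.0)
        pop = [random_chromosome(cfg, rng) for _ in range(10)]
        assert apply_operators(pop, cfg, rng) == pop

    def test_offspring_validity_under_fuzzing(self, rng):
        """10^4 operator applications never break head/tail invariants."""
        cfg = GepConfig.scaled_down(population=20, mutation_rate=0.05)
        pop = [random_chromosome(cfg, rng) for _ in range(20)]
        for _ in range(500):  # 500 rounds x 20 chromosomes = 10^4 applications
            pop = apply_operators(pop, cfg, rng)
            for c in pop:
                assert len(c.genes) == cfg.n_genes
                for g in c.genes:
                    assert len(g.symbols) == cfg.gene_size
                    validate_gene(g, cfg.functions, cfg.terminals)

    def test_observed_mutation_frequency_matches_rate(self, rng):
        """Per-symbol substitution frequency ~ the configured 0.0014."""
        rate = 0.0014
        cfg = GepConfig(mutation_rate=rate, inversion_rate=0.0, is_rate=0.0,
                        ris_rate=0.0, gene_transposition_rate=0.0,
                        one_point_rate=0.0, two_point_rate=0.0,
                        gene_recombination_rate=0.0)
        n_head_alpha = len(cfg.functions.symbols) + len(cfg.terminals)
        pop = [random_chromosome(cfg, rng) for _ in range(200)]
        changed = total = 0
        for _ in range(25):
            new = apply_operators(pop, cfg, rng)
            for a, b in zip(pop, new):
                for ga, gb in zip(a.genes, b.genes):
                    for i, (sa, sb) in enumerate(zip(ga.symbols, gb.symbols)):
                        total += 1
                        changed += sa != sb
            pop = new
        # a draw can re-pick the original symbol, so the visible change
        # probability is rate * (1 - 1/alphabet) per region
        h, t = cfg.head, cfg.tail
        p_vis = rate * (
            (h / (h + t)) * (1 - 1 / n_head_alpha)
            + (t / (h + t)) * (1 - 1 / len(cfg.terminals))
        )
        obs = changed / total
        assert abs(obs - p_vis) < 5 * np.sqrt(p_vis * (1 - p_vis) / total)


class TestEvolution:
    def test_zero_targets_trivially_solved(self, rng):
        X = rng.uniform(1, 10, size=(30, 7))
        y = np.zeros(30)
        cfg = GepConfig.scaled_down(population=100, generations=300, patience=None,
                                    target_fitness=995.0)
        res = GEPRegression(y, X, cfg).fit(seed=0)
        assert res.fitness > 990.0

    def test_elitism_monotone_best_fitness(self, rng):
        X = rng.uniform(0.5, 5, size=(40, 7))
        y = X[:, 0] - X[:, 1]
        cfg = GepConfig.scaled_down(population=40, generations=60, patience=None)
        res = GEPRegression(y, X, cfg).fit(seed=3)
        assert (np.diff(res.history) >= 0).all()

    def test_fixed_seed_reproducible(self, rng):
        X = rng.uniform(0.5, 5, size=(30, 7))
        y = X[:, 0] * X[:, 2]
        cfg = GepConfig.scaled_down(population=40, generations=40)
        r1 = GEPRegression(y, X, cfg).fit(seed=11)
        r2 = GEPRegression(y, X, cfg).fit(seed=11)
        assert r1.formula == r2.formula
        assert r1.fitness == r2.fitness

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            GEPRegression(np.zeros(5), rng.normal(size=(6, 7)))

    def test_planted_formula_recovery(self):
        """Median best fitness over 10 seeds >= 900 for a depth-3 target."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0.1, 10.0, size=(64, 7))
        y = X[:, 0] + X[:, 1] * X[:, 2]  # d1 + d2*d3
        cfg = GepConfig.scaled_down(
            population=200, generations=500, patience=None, target_fitness=901.0)
        fits = [GEPRegression(y, X, cfg).fit(seed=s).fitness for s in range(10)]
        assert np.median(fits) >= 900.0


class TestRnc:
    def test_constants_appear_and_evaluate(self, rng):
        cfg = GepConfig.scaled_down(population=30, generations=30, rnc=True,
                                    rnc_range=(-2.0, 2.0))
        X = rng.uniform(0.5, 5, size=(20, 7))
        y = X[:, 0] + 1.5
        res = GEPRegression(y, X, cfg).fit(seed=2)
        assert np.isfinite(res.predict(X)).all()
        for g in res.chromosome.genes:
            assert g.dc is not None and len(g.dc) == cfg.tail
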