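import numpy as np
import pandas as pd
import pytest

from gepess import engine, karva
from gepess.engine import (Chromosome, ConfusionCounts, GepConfig,
                           chromosome_fitness, classify_by_rank, evolve,
                           fitness_sspn, mutate, recombine, select_eugenic,
                           transpose)
from gepess.karva import gene_length, random_chromosome, tail_length

TERMINALS = ("x1", "x2") + karva.CONSTANT_TERMINALS


class TestSspn:
    def test_perfect_classifier_scores_one(self):
        assert fitness_sspn(ConfusionCounts(tp=10, tn=40, fp=0, fn=0)) == 1.0

    def test_zero_true_positives_scores_zero(self):
        assert fitness_sspn(ConfusionCounts(tp=0, tn=30, fp=10, fn=10)) == 0.0

    def test_direct_arithmetic(self):
        c = ConfusionCounts(tp=3, fn=1, tn=5, fp=1)
        assert fitness_sspn(c) == pytest.approx(0.75 * (5 / 6) * 0.75 * (5 / 6))
        assert fitness_sspn(c) == pytest.approx(0.390625)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 20, 4)
            s = fitness_sspn(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert 0.0 <= s <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestClassifyByRank:
    def test_top_scorer_selected(self):
        s = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        assert classify_by_rank(s, 1).to_dict() == {"A": 1, "B": 0, "C": 0}

    def test_ties_broken_lexicographically(self):
        s = pd.Series({"B": 1.0, "A": 1.0})
        assert classify_by_rank(s, 1).to_dict() == {"B": 0, "A": 1}

    def test_cardinality(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=100), index=[f"P{i}" for i in range(100)])
        assert classify_by_rank(s, 25).sum() == 25


class TestChromosomeFitness:
    def test_label_feature_gives_perfect_fitness(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(0, 2, 40), index=[f"P{i:02d}" for i in range(40)])
        x = pd.DataFrame({"truth": y.astype(float), "junk": rng.normal(size=40)},
                         index=y.index)
        h = 3
        syms = ("truth",) * gene_length(h)
        assert chromosome_fitness(Chromosome(syms, h), x, y) == 1.0

    def test_constant_chromosome_is_deterministic(self):
        y = pd.Series([1, 0, 1, 0], index=list("ABCD"))
        x = pd.DataFrame({"f": [0.0, 0.0, 0.0, 0.0]}, index=y.index)
        syms = ("0.5",) * gene_length(2)
        f1 = chromosome_fitness(Chromosome(syms, 2), x, y)
        f2 = chromosome_fitness(Chromosome(syms, 2), x, y)
        assert f1 == f2  # lexicographic ties make this reproducible

    def test_planted_expression_beats_random_chromosomes(self, dataset, labels_series):
        # a chromosome combining the planted features outranks random ones
        h = 5
        head = ("add", "add", "NC", "ION", "nucleus")
        syms = head + ("ION",) * (gene_length(h) - len(head))
        planted = Chromosome(syms, h)
        fit = chromosome_fitness(planted, dataset.features, labels_series)
        rng = np.random.default_rng(11)
        terminals = engine.default_terminals(dataset.features.columns)
        rand_fits = [
            chromosome_fitness(
                random_chromosome(h, terminals, rng), dataset.features, labels_series)
            for _ in range(100)
        ]
        assert fit > max(rand_fits)


class TestSelection:
    def test_selected_count(self):
        rng = np.random.default_rng(0)
        pop = [random_chromosome(3, TERMINALS, rng) for _ in range(10)]
        assert len(select_eugenic(pop, list(range(10)), 0.30)) == 3
        pop200 = [random_chromosome(3, TERMINALS, rng) for _ in range(200)]
        fits = list(np.linspace(0, 1, 200))
        sel = select_eugenic(pop200, fits, 0.30)
        assert len(sel) == 60
        assert sel[0] == pop200[-1]  # highest fitness first

    def test_equal_fitness_uses_symbol_tie_break(self):
        rng = np.random.default_rng(1)
        pop = [random_chromosome(3, TERMINALS, rng) for _ in range(10)]
        sel = select_eugenic(pop, [0.5] * 10, 0.30)
        assert sel == sorted(pop, key=lambda c: c.symbols)[:3]


class TestOperators:
    def test_mutation_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        c = random_chromosome(10, TERMINALS, rng)
        assert mutate(c, 0.0, TERMINALS, rng) == c

    def test_mutation_rate_one_keeps_tail_terminal(self):
        rng = np.random.default_rng(0)
        c = random_chromosome(10, TERMINALS, rng)
        m = mutate(c, 1.0, TERMINALS, rng)
        assert m.validate_domains()
        assert len(m.symbols) == len(c.symbols)

    def test_mutation_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(42)
        c = Chromosome(("x1",) * gene_length(20), 20)  # length 41
        total = 0
        trials = 2000
        for _ in range(trials):
            m = mutate(c, 0.25, ("x2",), rng, functions=())
            total += sum(a != b for a, b in zip(c.symbols, m.symbols))
        assert total / trials == pytest.approx(41 * 0.25, rel=0.05)

    def test_transposition_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        c = random_chromosome(10, TERMINALS, rng)
        assert transpose(c, 0.0, 0.0, rng) == c

    def test_transposition_reproducible_under_seed(self):
        c = random_chromosome(10, TERMINALS, np.random.default_rng(3))
        a = transpose(c, 1.0, 1.0, np.random.default_rng(9))
        b = transpose(c, 1.0, 1.0, np.random.default_rng(9))
        assert a == b

    def test_recombination_rate_zero_returns_parents(self):
        rng = np.random.default_rng(0)
        p1 = random_chromosome(6, TERMINALS, rng)
        p2 = random_chromosome(6, TERMINALS, rng)
        assert recombine(p1, p2, 0.0, rng) == (p1, p2)

    def test_self_crossover_is_identity(self):
        rng = np.random.default_rng(0)
        p = random_chromosome(6, TERMINALS, rng)
        c1, c2 = recombine(p, p, 1.0, rng)
        assert c1 == p and c2 == p

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        p1 = random_chromosome(4, TERMINALS, rng)
        p2 = random_chromosome(6, TERMINALS, rng)
        with pytest.raises(ValueError):
            recombine(p1, p2, 1.0, rng)

    @pytest.mark.parametrize("seed", range(3))
    def test_all_operators_preserve_structure(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            c = random_chromosome(7, TERMINALS, rng)
            m = mutate(c, 0.3, TERMINALS, rng)
            t = transpose(m, 0.5, 0.5, rng)
            o = random_chromosome(7, TERMINALS, rng)
            r1, r2 = recombine(t, o, 0.8, rng)
            for out in (m, t, r1, r2):
                assert len(out.symbols) == gene_length(7)
                assert out.validate_domains()
                karva.decode(out)  # closure: every result decodes


def _toy_problem(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame({"x1": rng.uniform(-1, 1, n), "x2": rng.uniform(-1, 1, n)},
                     index=[f"P{i:03d}" for i in range(n)])
    score = x["x1"] + 0.5 * x["x2"]
    y = (score >= score.quantile(0.75)).astype(int)
    return x, y


class TestEvolve:
    CFG = GepConfig.desk(population_size=40, generation_count=8, head_length=6,
                         rng_seed=5)

    def test_generation_best_fitness_is_non_decreasing(self):
        x, y = _toy_problem()
        res = evolve(x, y, self.CFG)
        best = res.history["best_fitness"].to_numpy()
        assert (np.diff(best) >= 0).all()  # elitism guarantee
        assert res.best_fitness == best[-1]

    def test_fixed_seed_gives_identical_history(self):
        x, y = _toy_problem()
        r1 = evolve(x, y, self.CFG)
        r2 = evolve(x, y, self.CFG)
        assert r1.history.equals(r2.history)
        assert r1.best_chromosome == r2.best_chromosome

    def test_degenerate_labels_rejected(self):
        x, y = _toy_problem()
        with pytest.raises(ValueError):
            evolve(x, pd.Series(1, index=x.index), self.CFG)

    def test_steady_state_with_full_selection_and_zero_rates(self):
        x, y = _toy_problem()
        cfg = self.CFG.replace(eugenic_fraction=1.0, mutation_rate=0.0,
                               crossover_rate=0.0, is_transposition_rate=0.0,
                               ris_transposition_rate=0.0, generation_count=5)
        res = evolve(x, y, cfg)
        # without variation or truncation the population never changes
        assert res.history["best_fitness"].nunique() == 1
        assert res.history["mean_fitness"].nunique() == 1

    def test_history_shape_and_expression(self):
        x, y = _toy_problem()
        res = evolve(x, y, self.CFG)
        assert list(res.history.columns) == ["generation", "best_fitness", "mean_fitness"]
        assert len(res.history) == self.CFG.generation_count
        text = res.expression
        tree = karva.parse_expression(text, list(x.columns))
        assert karva.render_expression(tree) == text


class TestConfig:
    def test_structural_chromosome_length(self):
        cfg = GepConfig()
        assert cfg.head_length == 20
        assert cfg.chromosome_length == 41  # head 20 + tail 21

    def test_tail_length_formula(self):
        assert tail_length(20) == 21

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            GepConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            GepConfig(eugenic_fraction=0.0)

    def test_desk_profile(self):
        cfg = GepConfig.desk(rng_seed=3)
        assert cfg.population_size == 200
        assert cfg.generation_count == 50
        assert cfg.rng_seed == 3
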