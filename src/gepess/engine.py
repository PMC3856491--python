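"""The GEP evolutionary loop: fitness, selection, genetic operators.

A population of Karva chromosomes is evolved for a fixed number of
generations. Each chromosome is decoded, scores every training protein,
and is binarized by *rank*: the top-k proteins are called essential, with
k equal to the number of essential proteins in the training set (the same
protocol used at evaluation time with the top-1167 cutoff). Fitness is the
SSPN product SN * SP * PPV * NPV of the resulting confusion counts.

Reproduction: the single best chromosome is carried over unchanged
(elitism), the top 30% ("eugenic") chromosomes become the parent pool, and
the population is refilled by uniformly sampling parent pairs and applying
one-point recombination, per-position mutation, and IS/RIS transposition.
All randomness flows through one seeded generator, so runs are exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import karva
from .karva import Chromosome, Node, gene_length

#: Table of evolution parameters, by conventional name (P1..P9).
#: P1 population size, P2 gene count, P4 head length, P5 mutation rate,
#: P6 crossover rate, P7 generation count, P8 function set, P9 fitness.


@dataclass(frozen=True)
class GepConfig:
    """All evolution parameters.

    Defaults are the full-scale settings (population 12000, 500
    generations) used for the yeast network; :meth:`desk` returns the
    desk-scale profile (population 200, 50 generations) used throughout
    the test fixtures. Mutation rate is the per-position replacement
    probability; crossover rate is the per-pair recombination probability.
    """

    population_size: int = 12_000          # P1
    gene_count: int = 1                    # P2
    head_length: int = 20                  # P4
    mutation_rate: float = 0.25            # P5
    crossover_rate: float = 0.1            # P6
    is_transposition_rate: float = 0.1
    ris_transposition_rate: float = 0.1
    generation_count: int = 500            # P7
    function_set: tuple[str, ...] = tuple(karva.FUNCTIONS)  # P8
    fitness_name: str = "SSPN"             # P9
    eugenic_fraction: float = 0.30
    elitism_count: int = 1
    rng_seed: int = 42

    def __post_init__(self):
        if self.head_length < 1:
            raise ValueError("head_length must be >= 1")
        for name in ("mutation_rate", "crossover_rate",
                     "is_transposition_rate", "ris_transposition_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.eugenic_fraction <= 1.0:
            raise ValueError("eugenic_fraction must be in (0, 1]")
        unknown = set(self.function_set) - set(karva.FUNCTIONS)
        if unknown:
            raise ValueError(f"unknown function symbols {sorted(unknown)}")

    @classmethod
    def desk(cls, **overrides) -> "GepConfig":
        """Desk-scale profile: small population and generation count so a
        full run completes in seconds on one core."""
        base = dict(population_size=200, generation_count=50)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "GepConfig":
        return replace(self, **changes)

    @property
    def chromosome_length(self) -> int:
        return self.gene_count * gene_length(self.head_length)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the derived rates and the SSPN fitness."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return num / den if den else 0.0

    @property
    def sn(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def fpr(self) -> float:
        return self._rate(self.fp, self.fp + self.tn)

    @property
    def f_measure(self) -> float:
        s = self.ppv + self.sn
        return 2.0 * self.ppv * self.sn / s if s else 0.0

    @property
    def acc(self) -> float:
        n = self.tp + self.tn + self.fp + self.fn
        return self._rate(self.tp + self.tn, n)

    @property
    def mcc(self) -> float:
        factors = ((self.tp + self.fp) * (self.tp + self.fn)
                   * (self.tn + self.fp) * (self.tn + self.fn))
        if factors == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(factors)

    @property
    def sspn(self) -> float:
        return self.sn * self.sp * self.ppv * self.npv


def fitness_sspn(counts: ConfusionCounts) -> float:
    """SSPN = SN * SP * PPV * NPV, each factor 0 when undefined."""
    return counts.sspn


def classify_by_rank(scores: pd.Series, positive_count: int) -> pd.Series:
    """Label the ``positive_count`` highest-scoring proteins 1, the rest 0.

    Ties at the cutoff are broken by lexicographic protein ID, so the
    split is deterministic.
    """
    if positive_count > len(scores):
        raise ValueError("positive_count exceeds the number of scored proteins")
    order = sorted(scores.index, key=lambda p: (-scores[p], p))
    positive = set(order[:positive_count])
    return pd.Series([1 if p in positive else 0 for p in scores.index],
                     index=scores.index, dtype=int)


def confusion_at_k(scores: pd.Series, labels: pd.Series, k: int) -> ConfusionCounts:
    """Confusion counts from the rank-based split at cutoff k."""
    pred = classify_by_rank(scores, k)
    y = labels.reindex(scores.index).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


class _FitnessEvaluator:
    """Vectorized fitness of chromosomes on a fixed training table."""

    def __init__(self, features: pd.DataFrame, labels: pd.Series):
        labels = labels.reindex(features.index)
        if labels.isna().any():
            raise ValueError("labels missing for some proteins in the feature table")
        self.y = labels.to_numpy(dtype=int)
        self.positives = int(self.y.sum())
        self.negatives = len(self.y) - self.positives
        if self.positives == 0 or self.negatives == 0:
            raise ValueError("training labels must contain both classes")
        self.frame = {col: np.ascontiguousarray(features[col].to_numpy(dtype=float))
                      for col in features.columns}
        # lexicographic rank of each protein ID, for deterministic ties
        ids = np.asarray(features.index)
        self.id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")

    def scores(self, chromosome: Chromosome) -> np.ndarray:
        tree = karva.decode(chromosome)
        raw = karva.evaluate(tree, self.frame)
        return np.broadcast_to(np.asarray(raw, dtype=float), self.y.shape).copy()

    def counts(self, scores: np.ndarray) -> ConfusionCounts:
        order = np.lexsort((self.id_rank, -scores))
        k = self.positives
        tp = int(self.y[order[:k]].sum())
        fp = k - tp
        fn = self.positives - tp
        tn = self.negatives - fp
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    def fitness(self, chromosome: Chromosome) -> float:
        return self.counts(self.scores(chromosome)).sspn


def chromosome_fitness(chromosome: Chromosome, features: pd.DataFrame,
                       labels: pd.Series) -> float:
    """Decode, score every training protein, binarize at the number of
    essential proteins, and return the SSPN of the confusion counts."""
    return _FitnessEvaluator(features, labels).fitness(chromosome)


# ---------------------------------------------------------------------------
# genetic operators


def select_eugenic(population: Sequence[Chromosome],
                   fitnesses: Sequence[float],
                   fraction: float = 0.30) -> list[Chromosome]:
    """Keep the ceil(fraction * size) fittest chromosomes; ties broken by
    the chromosome string so selection is deterministic."""
    n_sel = max(1, math.ceil(fraction * len(population)))
    order = sorted(range(len(population)),
                   key=lambda i: (-fitnesses[i], population[i].symbols))
    return [population[i] for i in order[:n_sel]]


def mutate(chromosome: Chromosome, rate: float, terminals: tuple[str, ...],
           rng: np.random.Generator,
           functions: tuple[str, ...] = tuple(karva.FUNCTIONS)) -> Chromosome:
    """Point mutation: each position independently resampled with
    probability ``rate`` from its domain (head: functions + terminals,
    tail: terminals only)."""
    if rate == 0.0:
        return chromosome
    head_pool = tuple(functions) + tuple(terminals)
    g = chromosome.gene_size
    h = chromosome.head_length
    syms = list(chromosome.symbols)
    hits = rng.random(len(syms)) < rate
    for pos in np.nonzero(hits)[0]:
        in_head = (pos % g) < h
        pool = head_pool if in_head else terminals
        syms[pos] = pool[rng.integers(0, len(pool))]
    return Chromosome(tuple(syms), chromosome.head_length, chromosome.gene_count)


def _is_transpose_gene(gene: list[str], h: int, rng: np.random.Generator) -> list[str]:
    # insertion-sequence transposition: copy a short segment anywhere in
    # the gene to a head position after the root, shifting the head right.
    length = int(rng.integers(1, 4))
    start = int(rng.integers(0, len(gene) - length + 1))
    segment = gene[start:start + length]
    if h < 2:
        return gene
    target = int(rng.integers(1, h))
    head = gene[:h]
    new_head = head[:target] + segment + head[target:]
    return new_head[:h] + gene[h:]


def _ris_transpose_gene(gene: list[str], h: int, rng: np.random.Generator) -> list[str]:
    # root-insertion-sequence transposition: a segment starting at a
    # function symbol in the head is copied to the head start.
    start_scan = int(rng.integers(0, h))
    start = next((i for i in range(start_scan, h) if karva.is_function(gene[i])), None)
    if start is None:
        return gene
    length = int(rng.integers(1, 4))
    segment = gene[start:start + length]
    head = gene[:h]
    new_head = segment + head
    return new_head[:h] + gene[h:]


def transpose(chromosome: Chromosome, is_rate: float, ris_rate: float,
              rng: np.random.Generator) -> Chromosome:
    """IS and RIS transposition. The tail is never altered, and anything
    shifted past the head end is truncated, so head/tail domains are
    preserved by construction."""
    h = chromosome.head_length
    genes = [list(g) for g in chromosome.genes()]
    changed = False
    for i, gene in enumerate(genes):
        if is_rate and rng.random() < is_rate:
            genes[i] = _is_transpose_gene(genes[i], h, rng)
            changed = True
        if ris_rate and rng.random() < ris_rate:
            genes[i] = _ris_transpose_gene(genes[i], h, rng)
            changed = True
    if not changed:
        return chromosome
    syms = tuple(s for gene in genes for s in gene)
    return Chromosome(syms, h, chromosome.gene_count)


def recombine(parent1: Chromosome, parent2: Chromosome, rate: float,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """One-point crossover with probability ``rate``. Both chromosomes
    share the head/tail layout, so any cut preserves the domains."""
    if len(parent1.symbols) != len(parent2.symbols):
        raise ValueError("parents must have equal chromosome length")
    if rate == 0.0 or rng.random() >= rate:
        return parent1, parent2
    n = len(parent1.symbols)
    cut = int(rng.integers(1, n))
    s1, s2 = parent1.symbols, parent2.symbols
    c1 = s1[:cut] + s2[cut:]
    c2 = s2[:cut] + s1[cut:]
    h, g = parent1.head_length, parent1.gene_count
    return Chromosome(c1, h, g), Chromosome(c2, h, g)


# ---------------------------------------------------------------------------
# the generational loop


@dataclass
class EvolveResult:
    """Outcome of one evolution run."""

    best_chromosome: Chromosome
    best_fitness: float
    history: pd.DataFrame  # columns: generation, best_fitness, mean_fitness
    config: GepConfig
    terminals: tuple[str, ...] = field(default_factory=tuple)

    @property
    def best_tree(self) -> Node:
        return karva.decode(self.best_chromosome)

    @property
    def expression(self) -> str:
        return karva.render_expression(self.best_tree)


def default_terminals(feature_names: Sequence[str]) -> tuple[str, ...]:
    """Feature-name terminals plus the four coefficient constants."""
    return tuple(feature_names) + karva.CONSTANT_TERMINALS


def evolve(features: pd.DataFrame, labels: pd.Series, config: GepConfig,
           rng: np.random.Generator | None = None) -> EvolveResult:
    """Run the full generational loop and return the best chromosome ever
    seen plus the per-generation best/mean fitness history.

    Raises if the training labels are degenerate (a single class).
    """
    evaluator = _FitnessEvaluator(features, labels)
    terminals = default_terminals(features.columns)
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    population = [
        karva.random_chromosome(config.head_length, terminals, rng,
                                functions=config.function_set,
                                gene_count=config.gene_count)
        for _ in range(config.population_size)
    ]

    best_chrom: Chromosome | None = None
    best_fit = -np.inf
    rows = []
    for generation in range(config.generation_count):
        fits = [evaluator.fitness(c) for c in population]
        gen_order = sorted(range(len(population)),
                           key=lambda i: (-fits[i], population[i].symbols))
        gen_best = gen_order[0]
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_chrom = population[gen_best]
        rows.append((generation, fits[gen_best], float(np.mean(fits))))

        if generation == config.generation_count - 1:
            break
        elite = [population[i] for i in gen_order[:config.elitism_count]]
        parents = select_eugenic(population, fits, config.eugenic_fraction)
        next_pop: list[Chromosome] = list(elite)
        # Parents are paired cyclically in fitness order rather than drawn
        # at random: every eugenic chromosome then contributes equally, and
        # with all operator rates at zero and eugenic_fraction 1 the
        # population is exactly invariant across generations.
        t = config.elitism_count
        while len(next_pop) < config.population_size:
            p1 = parents[t % len(parents)]
            p2 = parents[(t + 1) % len(parents)]
            t += 2
            c1, c2 = recombine(p1, p2, config.crossover_rate, rng)
            for child in (c1, c2):
                child = mutate(child, config.mutation_rate, terminals, rng,
                               functions=config.function_set)
                child = transpose(child, config.is_transposition_rate,
                                  config.ris_transposition_rate, rng)
                next_pop.append(child)
                if len(next_pop) >= config.population_size:
                    break
        population = next_pop

    history = pd.DataFrame(rows, columns=["generation", "best_fitness", "mean_fitness"])
    assert best_chrom is not None
    return EvolveResult(best_chromosome=best_chrom, best_fitness=best_fit,
                        history=history, config=config, terminals=terminals)
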