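"""Model/Results interface over the GEP essentiality classifier.

``EssentialityGEP`` is built from a feature table and binary labels (or
directly from the raw network + biology tables), ``fit()`` runs the
evolutionary search and returns a :class:`GepResults` carrying the evolved
expression, its training fitness, the per-generation history, and
evaluation helpers.

Example
-------
>>> from gepess.synthetic import SyntheticSpec, generate_dataset
>>> from gepess import EssentialityGEP, GepConfig
>>> data = generate_dataset(SyntheticSpec(rng_seed=7))
>>> model = EssentialityGEP(data.features, data.labels, GepConfig.desk(rng_seed=7))
>>> res = model.fit()
>>> print(res.expression)            # doctest: +SKIP
>>> print(res.summary())             # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import karva
from .engine import GepConfig, EvolveResult, evolve
from .evaluation import CrossValidationReport, MetricReport, cross_validate, topk_metrics
from .features import FeatureConfig, assemble_feature_table
from .io import EssentialityLabels, InteractionNetwork


def _as_label_series(labels, index) -> pd.Series:
    if isinstance(labels, EssentialityLabels):
        s = labels.to_series()
    else:
        s = pd.Series(labels)
    s = s.reindex(index)
    if s.isna().any():
        missing = list(s.index[s.isna()])[:5]
        raise ValueError(f"labels missing for proteins {missing}")
    return s.astype(int)


class EssentialityGEP:
    """GEP classifier for protein essentiality.

    Parameters
    ----------
    features : DataFrame
        Normalized feature table, proteins in rows (see
        :func:`gepess.features.assemble_feature_table`).
    labels : EssentialityLabels or Series/mapping of 0/1
        Essentiality of every protein in ``features``.
    config : GepConfig, optional
        Evolution parameters; defaults to the full-scale profile.
    """

    def __init__(self, features: pd.DataFrame, labels, config: GepConfig | None = None):
        self.features = features
        self.labels = _as_label_series(labels, features.index)
        if self.labels.sum() in (0, len(self.labels)):
            raise ValueError("labels must contain both classes")
        self.config = config or GepConfig()

    @classmethod
    def from_network_data(cls, network: InteractionNetwork, labels,
                          expression: pd.DataFrame | None = None,
                          localization: pd.DataFrame | None = None,
                          orthology: pd.Series | None = None,
                          config: GepConfig | None = None,
                          feature_config: FeatureConfig | None = None) -> "EssentialityGEP":
        """Featurize the raw inputs, then construct the model."""
        features = assemble_feature_table(network, expression, localization,
                                          orthology, config=feature_config)
        if isinstance(labels, (set, frozenset, list, tuple)):
            labels = EssentialityLabels(essential=set(labels) & set(features.index),
                                        universe=set(features.index))
        return cls(features, labels, config=config)

    def fit(self, rng: np.random.Generator | None = None) -> "GepResults":
        """Evolve the classifier and return the results object."""
        result = evolve(self.features, self.labels, self.config, rng=rng)
        return GepResults(self, result)

    def cross_validate(self, k: int = 10,
                       rng: np.random.Generator | int | None = None) -> CrossValidationReport:
        """Stratified k-fold cross-validation with per-fold evolution."""
        if rng is None:
            rng = self.config.rng_seed
        return cross_validate(self.features, self.labels, self.config, k=k, rng=rng)


def score_expression(expression: str | karva.Node, features: pd.DataFrame) -> pd.Series:
    """Apply a classifier expression (text or tree) to a feature table."""
    tree = expression if isinstance(expression, karva.Node) \
        else karva.parse_expression(expression, features.columns)
    frame = {c: features[c].to_numpy(dtype=float) for c in features.columns}
    vals = np.broadcast_to(np.asarray(karva.evaluate(tree, frame), dtype=float),
                           (len(features),)).copy()
    return pd.Series(vals, index=features.index, name="score")


def published_classifier_scores(features: pd.DataFrame) -> pd.Series:
    """Scores of the canonicalized reported yeast classifier expression."""
    return score_expression(karva.PUBLISHED_CLASSIFIER, features)


@dataclass
class GepResults:
    """Fit results: the evolved classifier and its diagnostics."""

    model: EssentialityGEP
    evolve_result: EvolveResult

    @property
    def expression(self) -> str:
        """The evolved classifier as infix expression text."""
        return self.evolve_result.expression

    @property
    def best_fitness(self) -> float:
        """Training SSPN fitness of the best chromosome."""
        return self.evolve_result.best_fitness

    @property
    def history(self) -> pd.DataFrame:
        """Per-generation best and mean fitness."""
        return self.evolve_result.history

    def predict(self, features: pd.DataFrame | None = None) -> pd.Series:
        """Essentiality scores (higher = more likely essential)."""
        x = features if features is not None else self.model.features
        return score_expression(self.evolve_result.best_tree, x)

    def evaluate(self, features: pd.DataFrame | None = None, labels=None,
                 k: int | None = None) -> MetricReport:
        """Rate metrics + ROC/AUC of the classifier on a labelled set.

        ``k`` defaults to the number of essential proteins in the set (the
        top-|positives| cutoff protocol).
        """
        x = features if features is not None else self.model.features
        y = _as_label_series(labels, x.index) if labels is not None \
            else self.model.labels.reindex(x.index)
        scores = self.predict(x)
        k = k if k is not None else int(y.sum())
        return topk_metrics(scores, y, k)

    def summary(self) -> str:
        """Text summary of the fit in the style of a regression results
        table: data shape, evolution parameters, fitness, expression, and
        the training-set metric row."""
        m = self.model
        cfg = m.config
        report = self.evaluate()
        lines = [
            "=" * 70,
            "GEP essentiality classifier".center(70),
            "=" * 70,
            f"Proteins: {len(m.features):>6d}    Essential: {int(m.labels.sum()):>5d}"
            f"    Nonessential: {int((1 - m.labels).sum()):>5d}",
            f"Features: {m.features.shape[1]:>6d}    "
            f"Population: {cfg.population_size}    Generations: {cfg.generation_count}",
            f"Head length: {cfg.head_length}    Genes: {cfg.gene_count}    "
            f"Chromosome length: {cfg.chromosome_length}",
            f"Mutation: {cfg.mutation_rate}    Crossover: {cfg.crossover_rate}    "
            f"Eugenic fraction: {cfg.eugenic_fraction}    Seed: {cfg.rng_seed}",
            "-" * 70,
            f"Best training fitness (SSPN): {self.best_fitness:.6f}",
            "Expression:",
            f"  {self.expression}",
            "-" * 70,
            "Training metrics at k = |essential|:",
            "  " + "  ".join(f"{k_}={v:.4f}" for k_, v in report.row().items()),
            "=" * 70,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Best/mean fitness per generation (matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["generation"], h["best_fitness"], label="best")
        ax.plot(h["generation"], h["mean_fitness"], label="mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("SSPN fitness")
        ax.legend()
        return ax

    def plot_roc(self, features=None, labels=None, ax=None):
        """ROC curve of the classifier on a labelled set (matplotlib)."""
        import matplotlib.pyplot as plt
        report = self.evaluate(features, labels)
        if ax is None:
            _, ax = plt.subplots()
        pts = np.array(report.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"AUC = {report.auc:.4f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
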