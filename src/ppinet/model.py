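"""Random-forest interaction classifier: model and results objects.

The estimator follows the model/results split familiar from statistical
modelling packages: :class:`InteractionForest` is constructed from a
:class:`LabeledFeatureTable` (pairs x 11 features + labels) and a
:class:`ForestConfig`; :meth:`InteractionForest.fit` returns an
:class:`InteractionForestResults` carrying the fitted ensemble, in-sample
scores, feature importances and a ``summary()`` table, with prediction,
cross-validation and network calling as methods.

Class imbalance is handled the way interactome classifiers are trained in
practice: a large random-pair negative pool at a controlled
positive:negative ratio, with SMOTE oversampling of the positive class;
``sweep_ratios`` reproduces the ratio x SMOTE optimisation protocol.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import features as ft
from .pairs import GoldStandardSet, Pair, canonical_pair
from .smote import SmoteConfig, smote_oversample

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0
    threshold: float = 0.5  # ensemble vote fraction calling an interaction

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


@dataclass
class LabeledFeatureTable:
    """Per-pair raw features (NaN = missing) with interaction labels."""

    features: pd.DataFrame
    labels: pd.Series  # bool, aligned with features

    def __post_init__(self) -> None:
        ft.validate_feature_table(self.features)
        self.labels = self.labels.astype(bool)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must align")

    @classmethod
    def from_tables(
        cls, positives: pd.DataFrame, negatives: pd.DataFrame
    ) -> "LabeledFeatureTable":
        overlap = positives.index.intersection(negatives.index)
        if len(overlap):
            raise ValueError(f"{len(overlap)} pairs appear in both classes")
        features = pd.concat([positives, negatives])
        labels = pd.Series(
            [True] * len(positives) + [False] * len(negatives), index=features.index
        )
        return cls(features=features, labels=labels)

    @property
    def class_counts(self) -> tuple[int, int]:
        pos = int(self.labels.sum())
        return pos, len(self.labels) - pos

    def subset(self, mask) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.features.loc[mask], self.labels.loc[mask])


def sample_negatives(
    universe: list[str] | set[str],
    positives: GoldStandardSet | set[Pair],
    n: int,
    seed: int,
) -> set[Pair]:
    """Draw n unique random pairs with no experimental interaction evidence.

    Negatives are canonical pairs over ``universe`` that are not in the
    positive set; reproducible under ``seed``.
    """
    pos = positives.positives if isinstance(positives, GoldStandardSet) else positives
    proteins = sorted({p for p in universe})
    rng = np.random.default_rng(seed)
    total = len(proteins) * (len(proteins) - 1) // 2
    available = total - len(pos)
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} non-positive pairs exist")
    if n > available // 2 or len(proteins) <= 2000:
        candidates = sorted(
            p for p in itertools.combinations(proteins, 2) if p not in pos
        )
        idx = rng.choice(len(candidates), size=n, replace=False)
        return {candidates[i] for i in sorted(idx)}
    negatives: set[Pair] = set()
    while len(negatives) < n:
        i, j = rng.integers(0, len(proteins), size=2)
        if i == j:
            continue
        pair = canonical_pair(proteins[i], proteins[j])
        if pair not in pos:
            negatives.add(pair)
    return negatives


class InteractionForest:
    """Random-forest interaction model over a labeled feature table."""

    def __init__(self, table: LabeledFeatureTable, config: ForestConfig | None = None):
        pos, neg = table.class_counts
        if pos == 0 or neg == 0:
            raise ValueError("training table must contain both classes")
        self.table = table
        self.config = config or ForestConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, label_column: str = "label", config: ForestConfig | None = None
    ) -> "InteractionForest":
        labels = frame[label_column].astype(bool)
        return cls(LabeledFeatureTable(frame.drop(columns=[label_column]), labels), config)

    def fit(self, *, smote: SmoteConfig | None = None) -> "InteractionForestResults":
        """Fit the ensemble, optionally SMOTE-oversampling the positive class.

        SMOTE runs on the imputed design matrix of the positive rows; the
        synthetic rows carry interpolated missingness indicators, which is
        deliberate (a fraction between two flag states is still informative
        for the forest).
        """
        design = ft.design_matrix(self.table.features)
        labels = self.table.labels.to_numpy()
        if smote is not None:
            pos_design = design.loc[self.table.labels.to_numpy()]
            augmented = smote_oversample(pos_design, smote)
            design = pd.concat([augmented, design.loc[~self.table.labels.to_numpy()]])
            labels = np.r_[
                np.ones(len(augmented), dtype=bool),
                np.zeros((~self.table.labels).sum(), dtype=bool),
            ]
        estimator = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            max_features=self.config.max_features,
            random_state=self.config.seed,
            n_jobs=1,
        )
        estimator.fit(design.to_numpy(), labels)
        return InteractionForestResults(
            model=self,
            estimator=estimator,
            design_columns=list(design.columns),
            smote=smote,
            training_design=design,
            training_labels=labels,
        )


@dataclass
class InteractionForestResults:
    """Fitted interaction forest with scores, importances and diagnostics."""

    model: InteractionForest
    estimator: RandomForestClassifier
    design_columns: list[str]
    smote: SmoteConfig | None = None
    training_design: pd.DataFrame | None = field(default=None, repr=False)
    training_labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.estimator.feature_importances_, index=self.design_columns
        ).sort_values(ascending=False)

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        design = ft.design_matrix(features)
        if list(design.columns) != self.design_columns:
            raise ValueError("feature schema mismatch with the trained model")
        return design.to_numpy()

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Ensemble vote fraction in [0, 1] per candidate pair."""
        proba = self.estimator.predict_proba(self._design(features))
        positive_col = list(self.estimator.classes_).index(True)
        return proba[:, positive_col]

    def predict_interactome(
        self, features: pd.DataFrame, threshold: float | None = None
    ) -> tuple[pd.Series, "object"]:
        """Score candidate pairs and call the network at the vote threshold.

        Returns ``(scores, network)`` where scores is indexed by pair and
        the network is an :class:`~ppinet.network.InteractionNetwork` over
        the called pairs.
        """
        from .network import InteractionNetwork

        threshold = self.model.config.threshold if threshold is None else threshold
        scores = pd.Series(self.predict_scores(features), index=features.index, name="score")
        called = [tuple(p) for p in scores.index[scores >= threshold]]
        return scores, InteractionNetwork.from_pairs(called)

    def training_scores(self) -> np.ndarray:
        return self.estimator.predict_proba(self.training_design.to_numpy())[
            :, list(self.estimator.classes_).index(True)
        ]

    def summary(self) -> str:
        pos, neg = self.model.table.class_counts
        lines = [
            "Interaction forest results",
            "==========================",
            f"trees: {self.config.n_trees}   max_features: {self.config.max_features}   seed: {self.config.seed}",
            f"training pairs: {pos} positive / {neg} negative"
            + (f"  (SMOTE -> {int(self.training_labels.sum())} positive)" if self.smote else ""),
            f"call threshold: {self.config.threshold}",
            "",
            "top feature importances:",
        ]
        for name, value in self.feature_importances.head(8).items():
            lines.append(f"  {name:<35s} {value:.4f}")
        return "\n".join(lines)

    @property
    def config(self) -> ForestConfig:
        return self.model.config


# ---------------------------------------------------------------------------
# ratio sweep


def train_forest(
    table: LabeledFeatureTable,
    config: ForestConfig | None = None,
    *,
    smote: SmoteConfig | None = None,
) -> InteractionForestResults:
    """Functional wrapper over ``InteractionForest(table, config).fit()``."""
    return InteractionForest(table, config).fit(smote=smote)


def sweep_ratios(
    positives: pd.DataFrame,
    negative_pool: pd.DataFrame,
    *,
    ratios: list[int] = (1, 5, 10, 40),
    smote_ratios: list[int] = (10, 20, 40),
    config: ForestConfig | None = None,
    smote_k: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Positive:negative ratio optimisation with and without SMOTE.

    Protocol: positives and the negative pool are split into train/test
    once (held out, stratified by construction).  Without SMOTE, each ratio
    1:r trains on all training positives plus r x as many pool negatives.
    With SMOTE, the *entire* training negative pool is used and the
    positive class is oversampled to pool/r — the fixed-pool design of
    ratio optimisation for genome-scale prediction.  Metrics are computed
    at the calling threshold on the training rows (original positives) and
    on the held-out test rows.  Infeasible ratios are skipped with a
    warning.
    """
    from .evaluation import ConfusionCounts, confusion_metrics

    config = config or ForestConfig()
    rng = np.random.default_rng(seed)

    def split(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = rng.permutation(len(frame))
        n_test = max(1, int(round(test_fraction * len(frame))))
        return frame.iloc[np.sort(idx[n_test:])], frame.iloc[np.sort(idx[:n_test])]

    pos_train, pos_test = split(positives)
    neg_train, neg_test = split(negative_pool)
    test_table = LabeledFeatureTable.from_tables(pos_test, neg_test)
    rows = []

    def evaluate(results: InteractionForestResults, train_table: LabeledFeatureTable):
        threshold = config.threshold
        for name, table in (("train", train_table), ("test", test_table)):
            scores = results.predict_scores(table.features)
            counts = ConfusionCounts.from_scores(scores, table.labels.to_numpy(), threshold)
            metrics = confusion_metrics(counts)
            yield name, metrics

    configs = [(r, False) for r in ratios] + [(r, True) for r in smote_ratios]
    for ratio, use_smote in configs:
        if use_smote:
            target = int(round(len(neg_train) / ratio))
            if target < len(pos_train):
                logger.warning("ratio 1:%d with SMOTE infeasible (target below positives); skipped", ratio)
                continue
            train_table = LabeledFeatureTable.from_tables(pos_train, neg_train)
            smote = SmoteConfig(k_neighbors=smote_k, target_count=target, seed=seed + ratio)
        else:
            n_neg = ratio * len(pos_train)
            if n_neg > len(neg_train):
                logger.warning("ratio 1:%d infeasible (pool too small); skipped", ratio)
                continue
            take = np.sort(rng.choice(len(neg_train), size=n_neg, replace=False))
            train_table = LabeledFeatureTable.from_tables(pos_train, neg_train.iloc[take])
            smote = None
        results = InteractionForest(train_table, replace(config, seed=config.seed + ratio)).fit(
            smote=smote
        )
        row = {"ratio": ratio, "smote": use_smote}
        for name, metrics in evaluate(results, train_table):
            row[f"{name}_tpr"] = metrics["tpr"]
            row[f"{name}_fpr"] = metrics["fpr"]
        pos_n = int(round(len(neg_train) / ratio)) if use_smote else len(pos_train)
        neg_n = len(neg_train) if use_smote else ratio * len(pos_train)
        row["n_positive_train"], row["n_negative_train"] = pos_n, neg_n
        rows.append(row)
    return pd.DataFrame(rows)
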