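"""Base predictors sharing a uniform fit/predict contract.

All four predictors produce averages of training responses and are therefore
bounded by the training response range:

* per-drug mean baseline,
* random-forest regressor (bootstrap per tree, random feature subset of size
  ``m = ceil(feature_fraction * M)`` per split, minimum node size),
* taxicab-distance KNN predicting the response directly from binary
  drug-target profiles, and
* taxicab KNN on mean-centered residuals, adding the per-drug mean back at
  predict time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datasets import LabeledDataset

__all__ = [
    "ForestConfig",
    "KnnConfig",
    "MeanModel",
    "ForestModel",
    "KnnDirectModel",
    "KnnResidualModel",
    "fit_mean",
    "fit_forest",
    "fit_knn_direct",
    "fit_knn_residual",
    "taxicab_distance",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``feature_fraction`` controls the size of the random candidate-feature
    subset at each split, ``m = ceil(feature_fraction * M)``.  A node with
    fewer than ``min_node_size`` training samples is not partitioned
    further.
    """

    n_trees: int = 50
    feature_fraction: float = 1.0 / 3.0
    min_node_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.feature_fraction <= 1.0):
            raise ValueError("feature_fraction must lie in (0, 1]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def m_features(self, n_features: int) -> int:
        return max(1, min(n_features, math.ceil(self.feature_fraction * n_features)))


@dataclass(frozen=True)
class KnnConfig:
    """K-nearest-neighbor settings; the distance is fixed to taxicab (L1)."""

    k: int = 5

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def taxicab_distance(phi: np.ndarray, psi: np.ndarray) -> float:
    """Sum of absolute coordinate differences between two profiles."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError(f"profile length mismatch: {phi.shape} vs {psi.shape}")
    return float(np.abs(phi - psi).sum())


class MeanModel:
    """Per-drug mean baseline: predict the training-set mean AUC of a drug."""

    kind = "mean"

    def __init__(self, drug_means: pd.Series):
        if drug_means.empty:
            raise ValueError("at least one drug mean is required")
        self.drug_means = drug_means.astype(float)

    def predict(self, drug_ids) -> np.ndarray:
        out = np.empty(len(drug_ids))
        for i, d in enumerate(drug_ids):
            if d not in self.drug_means.index:
                raise KeyError(f"drug {d!r} was not seen during fitting")
            out[i] = self.drug_means[d]
        return out


def fit_mean(auc_table: pd.DataFrame) -> MeanModel:
    """Fit the mean predictor from a long table with columns
    (cell_id, drug_id, auc) or any frame whose last two columns are
    (drug_id, auc)."""
    if {"drug_id", "auc"}.issubset(auc_table.columns):
        grouped = auc_table.groupby("drug_id")["auc"].mean()
    else:
        raise ValueError("auc_table must have columns 'drug_id' and 'auc'")
    if grouped.isna().any():
        raise ValueError("every drug needs at least one observation")
    return MeanModel(grouped)


class ForestModel:
    """Random-forest regressor wrapper keeping the training response range
    and the per-tree bootstrap indices accessible."""

    kind = "forest"

    def __init__(self, estimator: RandomForestRegressor, train: LabeledDataset, config: ForestConfig):
        self.estimator = estimator
        self.config = config
        self.feature_ids = train.feature_ids
        self.y_train = train.Y.copy()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} features, got {X.shape[1]}"
            )
        return self.estimator.predict(X)

    def bootstrap_indices(self) -> list[np.ndarray]:
        """Training-row indices drawn for each tree's bootstrap sample."""
        return [np.asarray(s) for s in self.estimator.estimators_samples_]


def fit_forest(train: LabeledDataset, config: ForestConfig) -> ForestModel:
    """Fit a random forest of ``n_trees`` regression trees.

    Each tree is grown on a bootstrap sample; each split considers a random
    subset of ``m`` features; a node below ``min_node_size`` samples is a
    leaf.  The forest prediction is the mean of tree predictions, which is
    the weighted average of training responses with weights given by leaf
    co-membership frequencies.
    """
    config.validate()
    if train.n_samples == 0:
        raise ValueError("cannot fit a forest on an empty training set")
    # a training set smaller than min_node_size yields a single-leaf tree
    est = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.m_features(train.n_features),
        min_samples_split=max(2, config.min_node_size),
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(train.X, train.Y)
    return ForestModel(est, train, config)


def _knn_neighbor_indices(
    train_profiles: np.ndarray, query: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k nearest rows under taxicab distance.

    Ties at the k-th distance are broken by the lowest training index
    (stable sort), making predictions deterministic.
    """
    d = np.abs(train_profiles - query[None, :]).sum(axis=1)
    order = np.argsort(d, kind="stable")
    return order[:k]


class KnnDirectModel:
    """Taxicab KNN on raw responses: predict the mean response of the k
    closest training profiles."""

    kind = "knn_direct"

    def __init__(self, profiles: np.ndarray, auc: np.ndarray, config: KnnConfig):
        self.profiles = np.asarray(profiles, dtype=float)
        self.auc = np.asarray(auc, dtype=float)
        self.config = config

    def predict(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self.profiles.shape[1]:
            raise ValueError("query profile length mismatch")
        out = np.empty(queries.shape[0])
        for i, q in enumerate(queries):
            nn = _knn_neighbor_indices(self.profiles, q, self.config.k)
            out[i] = self.auc[nn].mean()
        return out


def fit_knn_direct(
    target_profiles: np.ndarray, auc: np.ndarray, config: KnnConfig = KnnConfig()
) -> KnnDirectModel:
    """Fit the direct KNN estimator on (profile, response) pairs."""
    config.validate()
    profiles = np.asarray(target_profiles, dtype=float)
    auc = np.asarray(auc, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] != auc.shape[0]:
        raise ValueError("profiles must be 2-D and aligned with auc")
    if profiles.shape[0] < config.k:
        raise ValueError(
            f"need at least k={config.k} training profiles, got {profiles.shape[0]}"
        )
    return KnnDirectModel(profiles, auc, config)


class KnnResidualModel:
    """Taxicab KNN on mean-centered residuals.

    Trains on r = AUC - per-drug mean and adds the target drug's mean back
    onto the mean residual of the k nearest neighbors at predict time.
    """

    kind = "knn_residual"

    def __init__(
        self,
        profiles: np.ndarray,
        residuals: np.ndarray,
        drug_means: Mapping,
        config: KnnConfig,
    ):
        self.profiles = np.asarray(profiles, dtype=float)
        self.residuals = np.asarray(residuals, dtype=float)
        self.drug_means = dict(drug_means)
        self.config = config

    def predict(self, queries: np.ndarray, drug_ids) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[0] != len(drug_ids):
            raise ValueError("one drug id is required per query profile")
        out = np.empty(queries.shape[0])
        for i, (q, d) in enumerate(zip(queries, drug_ids)):
            if d not in self.drug_means:
                raise KeyError(f"no training mean for drug {d!r}")
            nn = _knn_neighbor_indices(self.profiles, q, self.config.k)
            out[i] = self.drug_means[d] + self.residuals[nn].mean()
        return out


def fit_knn_residual(
    target_profiles: np.ndarray,
    auc: np.ndarray,
    train_drug_ids,
    drug_means: Mapping,
    config: KnnConfig = KnnConfig(),
) -> KnnResidualModel:
    """Fit the residual KNN estimator.

    ``drug_means`` must be computed on the training partition only; each
    training row's residual is its response minus its drug's mean.
    """
    config.validate()
    profiles = np.asarray(target_profiles, dtype=float)
    auc = np.asarray(auc, dtype=float)
    if profiles.shape[0] != auc.shape[0] or profiles.shape[0] != len(train_drug_ids):
        raise ValueError("profiles, auc and train_drug_ids must be aligned")
    if profiles.shape[0] < config.k:
        raise ValueError(f"need at least k={config.k} training profiles")
    means = dict(drug_means)
    try:
        residuals = auc - np.array([means[d] for d in train_drug_ids], dtype=float)
    except KeyError as e:
        raise KeyError(f"no drug mean supplied for training drug {e.args[0]!r}") from e
    return KnnResidualModel(profiles, residuals, means, config)
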