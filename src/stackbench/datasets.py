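"""Domain types, table I/O and synthetic data generators.

Two generators are provided:

* :func:`generate_synthetic_dataset` builds the linear-model benchmark used
  throughout the stacking experiments: standard-normal covariates combined
  with a half-weak / half-strong weight vector, Gaussian noise scaled to a
  fraction of the signal variance, and min-max normalization of the response
  into ``[-1, 1]``.
* :func:`generate_pharmaco_dataset` emulates the structure of a multi-source
  pharmacogenomic screen (cell-line expression, drug descriptors, binary
  drug-target profiles, and a cell x drug AUC response table).  It is a
  synthetic stand-in whose sparse ground-truth effects are retained so that
  recovery can be checked; it makes no claim of biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SyntheticConfig",
    "SplitSpec",
    "PharmacoSimConfig",
    "PharmacoDataset",
    "generate_synthetic_dataset",
    "split_replicate",
    "generate_pharmaco_dataset",
    "read_feature_table",
    "read_response_table",
    "write_feature_table",
    "write_response_table",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with an aligned response vector.

    This is the unit every predictor consumes: ``X`` is ``n x M`` with one
    row per sample, ``Y`` holds the matching responses, and the id lists
    name rows and columns.
    """

    sample_ids: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if Y.ndim != 1:
            raise ValueError("Y must be a 1-D vector")
        if X.shape[0] != Y.shape[0] or X.shape[0] != len(self.sample_ids):
            raise ValueError("row count of X, length of Y and sample_ids must agree")
        if X.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must equal the number of columns of X")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            X=self.X[idx],
            Y=self.Y[idx],
            feature_ids=self.feature_ids,
        )

    def subset_features(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            sample_ids=self.sample_ids,
            X=self.X[:, idx],
            Y=self.Y,
            feature_ids=tuple(self.feature_ids[i] for i in idx),
        )

    @staticmethod
    def concat(a: "LabeledDataset", b: "LabeledDataset") -> "LabeledDataset":
        """Row-concatenate two datasets sharing the same feature ids."""
        if a.feature_ids != b.feature_ids:
            raise ValueError("cannot concatenate datasets with different features")
        return LabeledDataset(
            sample_ids=a.sample_ids + b.sample_ids,
            X=np.vstack([a.X, b.X]),
            Y=np.concatenate([a.Y, b.Y]),
            feature_ids=a.feature_ids,
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the linear-model synthetic benchmark.

    Half of the ``n_features`` weights are "weak" (uniform on
    ``[weak_low, weak_high]``), half "strong" (uniform on
    ``[strong_low, strong_high]``).  Gaussian noise has variance equal to
    ``noise_fraction`` times the sample variance of the noiseless response.
    """

    n_samples: int = 2000
    n_features: int = 100
    weak_low: float = 0.0
    weak_high: float = 0.5
    strong_low: float = 1.5
    strong_high: float = 3.0
    noise_fraction: float = 0.03
    intercept: float = 1.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_features < 2 or self.n_features % 2 != 0:
            raise ValueError(
                "n_features must be even (half weak, half strong predictors); "
                f"got {self.n_features}"
            )
        if self.noise_fraction <= 0:
            raise ValueError("noise_fraction must be > 0")
        if not (self.weak_low <= self.weak_high and self.strong_low <= self.strong_high):
            raise ValueError("weight bounds must be ordered low <= high")


@dataclass(frozen=True)
class SplitSpec:
    """Sample-partition sizes for one replicate of the learning-curve study."""

    n_train_init: int = 100
    n_validation: int = 50
    n_test: int = 500
    increment: int = 20
    n_replicates: int = 100

    def validate(self, n_samples: int | None = None) -> None:
        for name in ("n_train_init", "n_validation", "n_test", "increment", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if n_samples is not None:
            needed = self.n_train_init + self.n_validation + self.n_test
            if needed > n_samples:
                raise ValueError(
                    f"partition sizes require {needed} samples but only {n_samples} available"
                )


@dataclass(frozen=True)
class PharmacoSimConfig:
    """Shapes and effect scales of the synthetic pharmacogenomic screen."""

    n_cell_lines: int = 60
    n_drugs: int = 30
    n_genes: int = 80
    n_descriptors: int = 40
    n_targets: int = 25
    drug_effect_sd: float = 0.8
    cell_effect_sd: float = 0.8
    noise_sd: float = 0.15
    target_density: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_lines", "n_drugs", "n_genes", "n_descriptors", "n_targets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("drug_effect_sd", "cell_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 < self.target_density < 1.0):
            raise ValueError("target_density must lie strictly between 0 and 1")


@dataclass(frozen=True)
class PharmacoDataset:
    """Output of the pharmacogenomic simulator.

    ``auc`` is a cell-line x drug table of responses in ``[0, 1]``.
    ``truth`` retains the sparse ground-truth effects (gene weights, target
    weights, per-drug means) so downstream recovery tests can refer to them.
    """

    expression: pd.DataFrame  # cell lines x genes
    descriptors: pd.DataFrame  # drugs x descriptors
    targets: pd.DataFrame  # drugs x targets, binary
    auc: pd.DataFrame  # cell lines x drugs, values in [0, 1]
    truth: dict = field(repr=False, default_factory=dict)


def generate_synthetic_dataset(
    config: SyntheticConfig,
) -> tuple[LabeledDataset, set[int], set[int]]:
    """Generate one replicate of the linear synthetic benchmark.

    Covariates are i.i.d. standard normal.  A random half of the features
    receive weak weights and the other half strong weights; the response is
    the linear combination plus an intercept and Gaussian noise whose
    variance is ``noise_fraction`` times the sample variance of the noiseless
    response.  The noisy response is then affinely rescaled to span exactly
    ``[-1, 1]``.

    Returns the dataset together with the weak and strong feature index
    sets, which downstream layout construction uses for stratified feature
    splitting.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_features

    X = rng.standard_normal((n, m))
    weak_idx = set(rng.choice(m, size=m // 2, replace=False).tolist())
    strong_idx = set(range(m)) - weak_idx

    weights = np.empty(m)
    weak = sorted(weak_idx)
    strong = sorted(strong_idx)
    weights[weak] = rng.uniform(config.weak_low, config.weak_high, size=len(weak))
    weights[strong] = rng.uniform(config.strong_low, config.strong_high, size=len(strong))

    y_clean = X @ weights
    noise_var = config.noise_fraction * np.var(y_clean, ddof=1)
    y_noisy = y_clean + config.intercept + rng.normal(0.0, np.sqrt(noise_var), size=n)

    # min-max affine map onto exactly [-1, 1]
    lo, hi = y_noisy.min(), y_noisy.max()
    y = 2.0 * (y_noisy - lo) / (hi - lo) - 1.0

    ds = LabeledDataset(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        X=X,
        Y=y,
        feature_ids=tuple(f"f{j}" for j in range(m)),
    )
    return ds, weak_idx, strong_idx


def split_replicate(
    ds: LabeledDataset, spec: SplitSpec, seed: int
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition samples into train / validation / test / reserve.

    The reserve pool holds the remaining samples for later addition to the
    training set as the learning curve grows.  Partitions are disjoint and
    reproducible per seed.
    """
    spec.validate(ds.n_samples)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    a = spec.n_train_init
    b = a + spec.n_validation
    c = b + spec.n_test
    return (
        ds.subset_samples(perm[:a]),
        ds.subset_samples(perm[a:b]),
        ds.subset_samples(perm[b:c]),
        ds.subset_samples(perm[c:]),
    )


def generate_pharmaco_dataset(config: PharmacoSimConfig) -> PharmacoDataset:
    """Simulate a multi-source pharmacogenomic screen.

    The response for cell line ``c`` and drug ``d`` is

        AUC(c, d) = squash( m_d + g_c + t_d + noise )

    where ``m_d`` is a per-drug mean effect, ``g_c`` a cell-line genomic
    effect linear in a sparse subset of genes, ``t_d`` a drug effect linear
    in the drug's binary target profile, and ``squash`` the logistic map
    into ``[0, 1]``.  Descriptors are noisy linear readouts of the drug
    effect so that the descriptor source carries drug-level information.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cells = [f"cell{i}" for i in range(config.n_cell_lines)]
    drugs = [f"drug{j}" for j in range(config.n_drugs)]
    genes = [f"gene{g}" for g in range(config.n_genes)]
    descs = [f"desc{p}" for p in range(config.n_descriptors)]
    targets_ids = [f"target{t}" for t in range(config.n_targets)]

    expression = rng.standard_normal((config.n_cell_lines, config.n_genes))

    # sparse genomic effect: 10% of genes carry signal
    n_causal = max(1, config.n_genes // 10)
    causal_genes = rng.choice(config.n_genes, size=n_causal, replace=False)
    gene_weights = np.zeros(config.n_genes)
    gene_weights[causal_genes] = rng.normal(0.0, 1.0, size=n_causal)
    cell_effect = expression @ gene_weights
    if cell_effect.std() > 0:
        cell_effect = cell_effect / cell_effect.std() * config.cell_effect_sd
    else:  # degenerate single-gene edge case
        cell_effect = np.zeros_like(cell_effect)
    if config.cell_effect_sd == 0:
        cell_effect = np.zeros_like(cell_effect)

    target_matrix = (rng.uniform(size=(config.n_drugs, config.n_targets)) < config.target_density).astype(int)
    target_weights = rng.normal(0.0, 1.0, size=config.n_targets)
    drug_target_effect = target_matrix @ target_weights
    sd = drug_target_effect.std()
    if sd > 0 and config.drug_effect_sd > 0:
        drug_target_effect = drug_target_effect / sd * config.drug_effect_sd
    else:
        drug_target_effect = np.zeros_like(drug_target_effect, dtype=float)

    drug_mean_effect = rng.normal(0.0, config.drug_effect_sd, size=config.n_drugs)
    if config.drug_effect_sd == 0:
        drug_mean_effect = np.zeros(config.n_drugs)

    # descriptors: noisy linear readout of the drug-level effects
    loadings = rng.normal(0.0, 1.0, size=(2, config.n_descriptors))
    descriptors = (
        np.outer(drug_mean_effect, loadings[0])
        + np.outer(drug_target_effect, loadings[1])
        + rng.normal(0.0, 0.3, size=(config.n_drugs, config.n_descriptors))
    )

    linear = (
        drug_mean_effect[None, :]
        + cell_effect[:, None]
        + drug_target_effect[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_cell_lines, config.n_drugs))
    )
    auc = 1.0 / (1.0 + np.exp(-linear))

    return PharmacoDataset(
        expression=pd.DataFrame(expression, index=cells, columns=genes),
        descriptors=pd.DataFrame(descriptors, index=drugs, columns=descs),
        targets=pd.DataFrame(target_matrix, index=drugs, columns=targets_ids),
        auc=pd.DataFrame(auc, index=cells, columns=drugs),
        truth={
            "gene_weights": gene_weights,
            "target_weights": target_weights,
            "drug_mean_effect": drug_mean_effect,
            "drug_target_effect": drug_target_effect,
            "cell_effect": cell_effect,
        },
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O: CSV with a header row; first column is the sample id.


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature matrix CSV (first column = sample id)."""
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in feature table {path}")
    return df


def read_response_table(path) -> pd.Series:
    """Read a two-column (id, y) response CSV into a Series."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise ValueError("response file must have exactly two columns: id, y")
    return df.iloc[:, 0]


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id")


def write_response_table(y: pd.Series, path) -> None:
    y.rename("y").to_csv(path, index_label="sample_id")


def dataset_from_tables(features: pd.DataFrame, response: pd.Series) -> LabeledDataset:
    """Align a feature table with a response series by sample id."""
    common = features.index.intersection(response.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between features and response")
    features = features.loc[common]
    response = response.loc[common]
    return LabeledDataset(
        sample_ids=tuple(str(s) for s in common),
        X=features.to_numpy(dtype=float),
        Y=response.to_numpy(dtype=float),
        feature_ids=tuple(str(c) for c in features.columns),
    )
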