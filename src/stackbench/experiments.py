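"""Experiment orchestration: the synthetic learning-curve study comparing
horizontal and vertical stacking, and the integrated multi-source stacking
study on the pharmacogenomic simulator.

The learning-curve study repeats, over many independently generated
replicates, the cycle: generate data, partition samples, build the
horizontal/vertical layout with a stratified feature split, fit the four
component forests and the two stacks, score test MSE and bias angle, then
grow each training group by ``increment`` samples and refit.  Averages over
replicates trace out the learning curves.

The integrated study mimics a multi-source drug screen: per-drug mean,
forest on cell-line expression, forest on drug descriptors (fitted to
mean-centered residuals), and residual KNN on binary drug-target profiles
are fitted on 60% of the cell x drug pairs, all pairwise and full linear
stacks are estimated on 20%, and everything is scored on the remaining 20%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bias_diagnostics import bias_angle
from .datasets import (
    LabeledDataset,
    PharmacoSimConfig,
    SplitSpec,
    SyntheticConfig,
    generate_pharmaco_dataset,
    generate_synthetic_dataset,
    split_replicate,
)
from .predictors import ForestConfig, KnnConfig, fit_forest, fit_knn_residual, fit_mean
from .stacking import build_layout, fit_linear_stack, predict_stack, run_stacked_pair

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "LearningCurveResult",
    "IntegratedStudyResult",
    "compute_metrics",
    "stratified_feature_split",
    "run_learning_curve",
    "run_integrated_study",
]

MODELS = ("H1", "H2", "V1", "V2", "Hc", "Vc")


@dataclass(frozen=True)
class MetricReport:
    """Pearson correlation, MSE and MSE normalized by the mean predictor."""

    pearson: float
    mse: float
    nmse: float


def compute_metrics(
    observed: np.ndarray, predicted: np.ndarray, baseline_predicted: np.ndarray
) -> MetricReport:
    """Score predictions against observations.

    ``baseline_predicted`` is the mean predictor's output on the same
    samples; NMSE is the ratio of the two MSEs, so the baseline itself
    scores NMSE = 1.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    baseline = np.asarray(baseline_predicted, dtype=float)
    if not (observed.shape == predicted.shape == baseline.shape) or observed.ndim != 1:
        raise ValueError("observed, predicted and baseline must be aligned 1-D vectors")
    if np.ptp(observed) == 0:
        raise ValueError("constant observed values: correlation undefined")
    mse = float(np.mean((observed - predicted) ** 2))
    baseline_mse = float(np.mean((observed - baseline) ** 2))
    if mse == 0.0:
        pearson = 1.0  # predicted == observed exactly
    elif np.ptp(predicted) == 0:
        pearson = float("nan")  # constant prediction: correlation undefined
    else:
        pearson = float(stats.pearsonr(observed, predicted)[0])
    return MetricReport(pearson=pearson, mse=mse, nmse=mse / baseline_mse)


def stratified_feature_split(
    weak_idx: set[int], strong_idx: set[int], seed: int
) -> tuple[set[int], set[int]]:
    """Split features into two halves, each holding half the weak and half
    the strong predictors.

    With the default 50 weak / 50 strong features this guarantees at least
    25 of each kind per side, so neither stacking group is starved of
    signal.
    """
    rng = np.random.default_rng(seed)
    p1: set[int] = set()
    p2: set[int] = set()
    for group in (sorted(weak_idx), sorted(strong_idx)):
        perm = rng.permutation(len(group))
        half = len(group) // 2
        p1.update(group[i] for i in perm[:half])
        p2.update(group[i] for i in perm[half:])
    return p1, p2


@dataclass
class LearningCurveResult:
    """Replicate-averaged learning curves for the six models.

    ``mse`` and ``theta`` are (training size x model) tables of averages;
    the ``*_replicates`` arrays keep the per-replicate values with shape
    (n_sizes, n_models, n_replicates), model order as in ``models``.
    ``val_mse`` holds stacking-fit-set MSEs for the exact stacked-dominance
    property.
    """

    training_sizes: list[int]
    models: tuple[str, ...]
    mse: pd.DataFrame
    theta: pd.DataFrame
    val_mse: pd.DataFrame
    mse_replicates: np.ndarray = field(repr=False)
    theta_replicates: np.ndarray = field(repr=False)
    val_mse_replicates: np.ndarray = field(repr=False)
    n_replicates: int = 0


def run_learning_curve(
    synth_config: SyntheticConfig,
    split_spec: SplitSpec,
    forest_config: ForestConfig,
    n_replicates: int = 20,
    base_seed: int = 0,
    n_sizes: int = 3,
) -> LearningCurveResult:
    """Run the horizontal-vs-vertical learning-curve study.

    Per replicate ``r`` (seeded from ``base_seed + r``): generate a fresh
    synthetic dataset, partition into train/validation/test/reserve, split
    the initial training set 50:50 into the two sample groups, stratify the
    features into two halves, and for each of ``n_sizes`` training sizes
    (each step moves ``increment`` reserve samples into *each* group) fit
    the four component forests and the two stacks and record test MSE and
    bias angle.

    Stops early with a warning when the reserve pool cannot supply a
    further increment.
    """
    if n_replicates < 1 or n_sizes < 1:
        raise ValueError("n_replicates and n_sizes must be >= 1")

    n_models = len(MODELS)
    mse_rep = np.full((n_sizes, n_models, n_replicates), np.nan)
    theta_rep = np.full((n_sizes, n_models, n_replicates), np.nan)
    val_rep = np.full((n_sizes, n_models, n_replicates), np.nan)
    sizes: list[int] = []

    for r in range(n_replicates):
        gen_seed, split_seed, feat_seed, forest_seed = (
            int(s) for s in np.random.SeedSequence(base_seed + r).generate_state(4) >> 1
        )
        cfg = SyntheticConfig(
            n_samples=synth_config.n_samples,
            n_features=synth_config.n_features,
            weak_low=synth_config.weak_low,
            weak_high=synth_config.weak_high,
            strong_low=synth_config.strong_low,
            strong_high=synth_config.strong_high,
            noise_fraction=synth_config.noise_fraction,
            intercept=synth_config.intercept,
            seed=gen_seed,
        )
        ds, weak_idx, strong_idx = generate_synthetic_dataset(cfg)
        train, validation, test, reserve = split_replicate(ds, split_spec, split_seed)
        p1, p2 = stratified_feature_split(weak_idx, strong_idx, feat_seed)

        # 50:50 split of the initial training pool into the two sample groups
        half = train.n_samples // 2
        group1_idx = list(range(half))
        group2_idx = list(range(half, train.n_samples))
        group1 = train.subset_samples(group1_idx)
        group2 = train.subset_samples(group2_idx)
        reserve_pos = 0

        for s in range(n_sizes):
            if s > 0:
                need = 2 * split_spec.increment
                if reserve_pos + need > reserve.n_samples:
                    warnings.warn(
                        f"reserve exhausted after {s} training sizes", RuntimeWarning
                    )
                    break
                add1 = reserve.subset_samples(
                    range(reserve_pos, reserve_pos + split_spec.increment)
                )
                add2 = reserve.subset_samples(
                    range(
                        reserve_pos + split_spec.increment,
                        reserve_pos + 2 * split_spec.increment,
                    )
                )
                reserve_pos += need
                group1 = LabeledDataset.concat(group1, add1)
                group2 = LabeledDataset.concat(group2, add2)

            total = group1.n_samples + group2.n_samples
            if r == 0 and len(sizes) <= s:
                sizes.append(total)

            D_M = group1.subset_features(sorted(p1))
            layout = build_layout(D_M, group2, (p1, p2))
            result = run_stacked_pair(
                layout,
                validation,
                test,
                ForestConfig(
                    n_trees=forest_config.n_trees,
                    feature_fraction=forest_config.feature_fraction,
                    min_node_size=forest_config.min_node_size,
                    seed=forest_seed + s,
                ),
            )

            test_preds = dict(result.components)
            test_preds["Hc"] = result.Hc
            test_preds["Vc"] = result.Vc
            val_preds = dict(result.validation_components)
            for stack_name, parts in (("Hc", ("H1", "H2")), ("Vc", ("V1", "V2"))):
                P = np.column_stack([val_preds[p] for p in parts])
                val_preds[stack_name] = predict_stack(result.stacks[stack_name], P)

            for m_i, name in enumerate(MODELS):
                mse_rep[s, m_i, r] = np.mean((test.Y - test_preds[name]) ** 2)
                theta_rep[s, m_i, r] = bias_angle(test.Y, test_preds[name]).theta_deg
                val_rep[s, m_i, r] = np.mean((validation.Y - val_preds[name]) ** 2)
        logger.info("learning-curve replicate %d/%d done", r + 1, n_replicates)

    n_sizes_done = len(sizes)
    mse_rep = mse_rep[:n_sizes_done]
    theta_rep = theta_rep[:n_sizes_done]
    val_rep = val_rep[:n_sizes_done]

    def _table(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            np.nanmean(arr, axis=2), index=sizes, columns=list(MODELS)
        ).rename_axis("training_size")

    return LearningCurveResult(
        training_sizes=sizes,
        models=MODELS,
        mse=_table(mse_rep),
        theta=_table(theta_rep),
        val_mse=_table(val_rep),
        mse_replicates=mse_rep,
        theta_replicates=theta_rep,
        val_mse_replicates=val_rep,
        n_replicates=n_replicates,
    )


@dataclass
class IntegratedStudyResult:
    """Metric tables of the multi-source stacking study.

    ``singles`` and ``pairs`` are indexed by model / "a+b" stack names;
    ``ensemble`` is the full linear stack of all single models.
    ``stack_set_mse`` records fit-set MSEs of every stack and of the single
    models on the stacking partition (where OLS dominance holds exactly).
    """

    singles: pd.DataFrame
    pairs: pd.DataFrame
    ensemble: MetricReport
    stack_set_mse: dict
    n_train: int = 0
    n_stack: int = 0
    n_test: int = 0


def run_integrated_study(
    pharmaco_config: PharmacoSimConfig,
    seed: int = 0,
    forest_config: ForestConfig | None = None,
    knn_config: KnnConfig = KnnConfig(),
) -> IntegratedStudyResult:
    """Fit single predictors, all pairwise stacks and the full ensemble on
    the pharmacogenomic simulator.

    Cell x drug pairs are split 60/20/20 into training (individual
    predictors), stacking (stack weights) and test partitions.  Single
    models: per-drug mean; forest on cell-line expression (raw response);
    forest on drug descriptors fitted to mean-centered residuals; taxicab
    KNN on binary drug-target profiles fitted to residuals.  NMSE is
    relative to the per-drug mean predictor on the test partition.
    """
    if forest_config is None:
        forest_config = ForestConfig(n_trees=50, seed=seed)
    data = generate_pharmaco_dataset(pharmaco_config)

    long = (
        data.auc.stack()
        .rename("auc")
        .reset_index()
        .rename(columns={"level_0": "cell_id", "level_1": "drug_id"})
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(long))
    n = len(long)
    n_train = int(round(0.6 * n))
    n_stack = int(round(0.2 * n))
    idx_train = perm[:n_train]
    idx_stack = perm[n_train : n_train + n_stack]
    idx_test = perm[n_train + n_stack :]

    parts = {
        "train": long.iloc[idx_train].reset_index(drop=True),
        "stack": long.iloc[idx_stack].reset_index(drop=True),
        "test": long.iloc[idx_test].reset_index(drop=True),
    }

    mean_model = fit_mean(parts["train"])
    drug_means = mean_model.drug_means

    def expr_X(df: pd.DataFrame) -> np.ndarray:
        return data.expression.loc[df["cell_id"]].to_numpy(dtype=float)

    def desc_X(df: pd.DataFrame) -> np.ndarray:
        return data.descriptors.loc[df["drug_id"]].to_numpy(dtype=float)

    def target_X(df: pd.DataFrame) -> np.ndarray:
        return data.targets.loc[df["drug_id"]].to_numpy(dtype=float)

    train = parts["train"]
    rf_ge = fit_forest(
        LabeledDataset(
            sample_ids=tuple(f"p{i}" for i in range(len(train))),
            X=expr_X(train),
            Y=train["auc"].to_numpy(),
            feature_ids=tuple(data.expression.columns),
        ),
        forest_config,
    )
    train_resid = train["auc"].to_numpy() - drug_means.loc[train["drug_id"]].to_numpy()
    rf_phys = fit_forest(
        LabeledDataset(
            sample_ids=tuple(f"p{i}" for i in range(len(train))),
            X=desc_X(train),
            Y=train_resid,
            feature_ids=tuple(data.descriptors.columns),
        ),
        ForestConfig(
            n_trees=forest_config.n_trees,
            feature_fraction=forest_config.feature_fraction,
            min_node_size=forest_config.min_node_size,
            seed=forest_config.seed + 1,
        ),
    )
    knn_res = fit_knn_residual(
        target_X(train),
        train["auc"].to_numpy(),
        list(train["drug_id"]),
        drug_means,
        knn_config,
    )

    def predict_all(df: pd.DataFrame) -> dict[str, np.ndarray]:
        dm = drug_means.loc[df["drug_id"]].to_numpy()
        return {
            "mean": mean_model.predict(list(df["drug_id"])),
            "rf_ge": rf_ge.predict(expr_X(df)),
            "rf_phys_residual": rf_phys.predict(desc_X(df)) + dm,
            "knn_residual": knn_res.predict(target_X(df), list(df["drug_id"])),
        }

    preds = {name: predict_all(parts[name]) for name in ("stack", "test")}
    y_stack = parts["stack"]["auc"].to_numpy()
    y_test = parts["test"]["auc"].to_numpy()
    baseline_test = preds["test"]["mean"]

    single_names = ("mean", "rf_ge", "rf_phys_residual", "knn_residual")
    singles = pd.DataFrame(
        {
            name: compute_metrics(y_test, preds["test"][name], baseline_test).__dict__
            for name in single_names
        }
    ).T

    stack_set_mse: dict[str, float] = {
        name: float(np.mean((y_stack - preds["stack"][name]) ** 2))
        for name in single_names
    }

    def fit_and_score(members: tuple[str, ...]) -> tuple[MetricReport, float]:
        P_stack = np.column_stack([preds["stack"][m] for m in members])
        stack = fit_linear_stack(P_stack, y_stack, members)
        fit_mse = float(np.mean((y_stack - predict_stack(stack, P_stack)) ** 2))
        P_test = np.column_stack([preds["test"][m] for m in members])
        report = compute_metrics(y_test, predict_stack(stack, P_test), baseline_test)
        return report, fit_mse

    pair_rows = {}
    for i in range(len(single_names)):
        for j in range(i + 1, len(single_names)):
            members = (single_names[i], single_names[j])
            report, fit_mse = fit_and_score(members)
            key = "+".join(members)
            pair_rows[key] = report.__dict__
            stack_set_mse[key] = fit_mse
    pairs = pd.DataFrame(pair_rows).T

    ensemble, ens_fit_mse = fit_and_score(single_names)
    stack_set_mse["ensemble"] = ens_fit_mse

    return IntegratedStudyResult(
        singles=singles,
        pairs=pairs,
        ensemble=ensemble,
        stack_set_mse=stack_set_mse,
        n_train=n_train,
        n_stack=n_stack,
        n_test=n - n_train - n_stack,
    )
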