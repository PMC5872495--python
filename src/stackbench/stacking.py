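"""Linear stacking of component predictions and the horizontal/vertical
stacking layouts.

A linear stack is an affine combination ``y_f = P w + b`` of component
predictions ``P`` fitted by least squares on a held-out validation set.
Because ordinary least squares with an intercept nests every single
component (weight 1 on it, 0 elsewhere), the stacked fit-set MSE can never
exceed that of any component.

The layout machinery formalizes two ways of pooling a small full-feature
dataset ``D_F`` (n2 samples, p1+p2 features) with a larger reduced-feature
dataset ``D_M`` (n1 samples, p1 features):

* horizontal: stack a forest on the pooled samples restricted to the shared
  features (H1, (n1+n2) x p1) with a forest on the extra features
  (H2, n2 x p2);
* vertical: stack a forest on D_M (V1, n1 x p1) with a forest on D_F
  (V2, n2 x (p1+p2)).

With the number of terminal nodes k held fixed, the component variances
scale like k/(samples); horizontal stacking keeps the first component's
variance (~k/(n1+n2)) well below the second's (~k/n2), the condition under
which the stack acts as a debiasing device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset
from .predictors import ForestConfig, fit_forest

__all__ = [
    "LinearStack",
    "StackLayout",
    "fit_linear_stack",
    "predict_stack",
    "build_layout",
    "run_stacked_pair",
    "StackedPairResult",
]


@dataclass(frozen=True)
class LinearStack:
    """Fitted stacking weights ``w`` and intercept ``b`` over named
    component model outputs."""

    component_names: tuple[str, ...]
    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or w.shape[0] != len(self.component_names) or w.shape[0] < 1:
            raise ValueError("w must be 1-D with one weight per component")


def fit_linear_stack(
    component_preds: np.ndarray,
    y_val: np.ndarray,
    component_names: tuple[str, ...] | None = None,
) -> LinearStack:
    """Least-squares fit of stacking weights on validation predictions.

    Solves ``min_{w,b} || P w + b - y ||^2``.  A rank-deficient design
    (e.g. duplicated components) is resolved by the minimum-norm solution,
    with a warning.
    """
    P = np.asarray(component_preds, dtype=float)
    y = np.asarray(y_val, dtype=float)
    if P.ndim != 2:
        raise ValueError("component_preds must be 2-D (n_val x n_models)")
    n, n_m = P.shape
    if y.shape != (n,):
        raise ValueError("y_val must align with component_preds rows")
    if n <= n_m + 1:
        raise ValueError(
            f"need more than n_models+1={n_m + 1} validation samples, got {n}"
        )
    if component_names is None:
        component_names = tuple(f"m{i}" for i in range(n_m))
    if len(component_names) != n_m:
        raise ValueError("one name per component is required")

    A = np.column_stack([P, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < n_m + 1:
        warnings.warn(
            "rank-deficient stacking design; using the minimum-norm "
            "least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return LinearStack(tuple(component_names), coef[:-1], float(coef[-1]))


def predict_stack(stack: LinearStack, component_preds: np.ndarray) -> np.ndarray:
    """Apply a fitted stack row-wise: ``P w + b``."""
    P = np.asarray(component_preds, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[1] != len(stack.component_names):
        raise ValueError(
            f"expected {len(stack.component_names)} component columns, got {P.shape[1]}"
        )
    return P @ stack.w + stack.b


@dataclass(frozen=True)
class StackLayout:
    """The four training roles of the horizontal/vertical comparison.

    ``p1_features`` are shared between both source datasets; ``p2_features``
    exist only in the full-feature dataset D_F.
    """

    p1_features: tuple[int, ...]
    p2_features: tuple[int, ...]
    H1: LabeledDataset  # (n1+n2) x p1
    H2: LabeledDataset  # n2 x p2
    V1: LabeledDataset  # n1 x p1
    V2: LabeledDataset  # n2 x (p1+p2)


def build_layout(
    D_M: LabeledDataset,
    D_F: LabeledDataset,
    feature_split: tuple[set[int], set[int]],
) -> StackLayout:
    """Assemble the horizontal and vertical training sets.

    ``D_M`` carries only the shared features p1; ``D_F`` carries p1 and p2.
    Feature indices in ``feature_split`` refer to columns of ``D_F``.
    H1 row order is D_M first, then D_F; sample ids are preserved.
    """
    p1_set, p2_set = (set(feature_split[0]), set(feature_split[1]))
    n_f = D_F.n_features
    if not p1_set or not p2_set:
        raise ValueError("both p1 and p2 feature sets must be nonempty")
    if p1_set & p2_set:
        raise ValueError("p1 and p2 feature sets must be disjoint")
    if p1_set | p2_set != set(range(n_f)):
        raise ValueError("p1 and p2 must partition the features of D_F")
    p1 = sorted(p1_set)
    p2 = sorted(p2_set)

    p1_ids = tuple(D_F.feature_ids[j] for j in p1)
    if D_M.feature_ids != p1_ids:
        raise ValueError("D_M's features must equal D_F's p1 feature set (in order)")

    D_F_p1 = D_F.subset_features(p1)
    H1 = LabeledDataset.concat(D_M, D_F_p1)
    H2 = D_F.subset_features(p2)
    return StackLayout(
        p1_features=tuple(p1),
        p2_features=tuple(p2),
        H1=H1,
        H2=H2,
        V1=D_M,
        V2=D_F,
    )


@dataclass
class StackedPairResult:
    """Test predictions of the two stacks and their four components."""

    Hc: np.ndarray
    Vc: np.ndarray
    components: dict  # name -> test predictions
    stacks: dict  # name -> LinearStack
    validation_components: dict  # name -> validation predictions


def run_stacked_pair(
    layout: StackLayout,
    validation: LabeledDataset,
    test: LabeledDataset,
    forest_config: ForestConfig,
) -> StackedPairResult:
    """Fit the four component forests and both stacks; predict on test.

    Each component model sees only its own feature subset at predict time.
    The two stacks (Hc from H1+H2, Vc from V1+V2) are fitted on the
    validation predictions and applied to the test predictions.
    """
    p1 = list(layout.p1_features)
    p2 = list(layout.p2_features)

    roles = {
        "H1": (layout.H1, p1),
        "H2": (layout.H2, p2),
        "V1": (layout.V1, p1),
        "V2": (layout.V2, None),  # all features
    }
    val_preds: dict[str, np.ndarray] = {}
    test_preds: dict[str, np.ndarray] = {}
    for i, (name, (train_ds, cols)) in enumerate(roles.items()):
        cfg = ForestConfig(
            n_trees=forest_config.n_trees,
            feature_fraction=forest_config.feature_fraction,
            min_node_size=forest_config.min_node_size,
            seed=forest_config.seed + i,
        )
        model = fit_forest(train_ds, cfg)
        if cols is None:
            val_X, test_X = validation.X, test.X
        else:
            val_X, test_X = validation.X[:, cols], test.X[:, cols]
        val_preds[name] = model.predict(val_X)
        test_preds[name] = model.predict(test_X)

    stacks = {}
    out = {}
    for stack_name, parts in (("Hc", ("H1", "H2")), ("Vc", ("V1", "V2"))):
        P_val = np.column_stack([val_preds[p] for p in parts])
        stack = fit_linear_stack(P_val, validation.Y, parts)
        stacks[stack_name] = stack
        P_test = np.column_stack([test_preds[p] for p in parts])
        out[stack_name] = predict_stack(stack, P_test)

    return StackedPairResult(
        Hc=out["Hc"],
        Vc=out["Vc"],
        components=test_preds,
        stacks=stacks,
        validation_components=val_preds,
    )
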