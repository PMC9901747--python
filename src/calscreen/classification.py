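"""The classical-classifier panel benchmarked on augmented feature vectors.

Twenty presets spanning SVMs, k-NN variants, tree ensembles and single
decision trees are compared by 5-fold cross-validated training accuracy and
held-out test accuracy, per projection method.  The preset map mirrors the
familiar "fine / medium / coarse" granularity naming:

* Gaussian SVM kernel scales: sqrt(P)/4, sqrt(P), 4*sqrt(P) with P features
  (``gamma = 1 / scale**2``);
* k-NN neighbour counts: 1 (fine), 10 (medium), 100 (coarse); cosine, cubic
  (Minkowski p=3) and distance-weighted variants use k = 10;
* trees: at most 100 / 20 / 4 splits for fine / medium / coarse;
* ensembles: 30 learners each — AdaBoosted medium trees, bagged trees
  (random forest), random-subspace LDA, random-subspace 1-NN, and AdaBoosted
  class-weight-balanced trees as the imbalance-aware boosting preset.

Distance-based models (SVMs, k-NN, subspace learners) are standardised with
statistics fit on the training split only; trees consume raw features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: panel order; ties in the benchmark are broken by this order
CLASSIFIER_NAMES = (
    "Linear SVM",
    "Quadratic SVM",
    "Cubic SVM",
    "Fine Gaussian SVM",
    "Medium Gaussian SVM",
    "Coarse Gaussian SVM",
    "Fine k-NN",
    "Medium k-NN",
    "Coarse k-NN",
    "Cosine k-NN",
    "Cubic k-NN",
    "Weighted k-NN",
    "Boosted Trees",
    "Bagged Trees",
    "Subspace Discriminant",
    "Subspace k-NN",
    "RUSBoosted Trees",
    "Fine Tree",
    "Medium Tree",
    "Coarse Tree",
)

_N_ENSEMBLE = 30


def _knn(k: int, n_fit: int, **kw) -> KNeighborsClassifier:
    # k cannot exceed the number of fitting samples (smallest CV fold)
    return KNeighborsClassifier(n_neighbors=max(1, min(k, n_fit)), **kw)


def _medium_tree(seed):
    return DecisionTreeClassifier(max_leaf_nodes=21, random_state=seed)


def build_classifier(name: str, n_features: int, n_fit: int, seed: int = 0):
    """Instantiate one named preset sized for ``n_features`` inputs.

    ``n_fit`` is the smallest number of samples any fit will see (the
    smallest cross-validation fold); it caps k-NN neighbour counts.
    """
    sqrt_p = float(np.sqrt(n_features))
    scaled = True
    if name == "Linear SVM":
        est = SVC(kernel="linear", C=1.0)
    elif name == "Quadratic SVM":
        est = SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, C=1.0)
    elif name == "Cubic SVM":
        est = SVC(kernel="poly", degree=3, gamma="scale", coef0=1.0, C=1.0)
    elif name == "Fine Gaussian SVM":
        est = SVC(kernel="rbf", gamma=1.0 / (sqrt_p / 4) ** 2, C=1.0)
    elif name == "Medium Gaussian SVM":
        est = SVC(kernel="rbf", gamma=1.0 / sqrt_p**2, C=1.0)
    elif name == "Coarse Gaussian SVM":
        est = SVC(kernel="rbf", gamma=1.0 / (4 * sqrt_p) ** 2, C=1.0)
    elif name == "Fine k-NN":
        est = _knn(1, n_fit)
    elif name == "Medium k-NN":
        est = _knn(10, n_fit)
    elif name == "Coarse k-NN":
        est = _knn(100, n_fit)
    elif name == "Cosine k-NN":
        est = _knn(10, n_fit, metric="cosine")
    elif name == "Cubic k-NN":
        est = _knn(10, n_fit, metric="minkowski", p=3)
    elif name == "Weighted k-NN":
        est = _knn(10, n_fit, weights="distance")
    elif name == "Boosted Trees":
        scaled = False
        est = AdaBoostClassifier(
            estimator=_medium_tree(seed), n_estimators=_N_ENSEMBLE, random_state=seed
        )
    elif name == "Bagged Trees":
        scaled = False
        est = RandomForestClassifier(n_estimators=_N_ENSEMBLE, random_state=seed)
    elif name == "Subspace Discriminant":
        est = BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=_N_ENSEMBLE,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    elif name == "Subspace k-NN":
        est = BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=_N_ENSEMBLE,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    elif name == "RUSBoosted Trees":
        scaled = False
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_leaf_nodes=21, class_weight="balanced", random_state=seed
            ),
            n_estimators=_N_ENSEMBLE,
            random_state=seed,
        )
    elif name == "Fine Tree":
        scaled = False
        est = DecisionTreeClassifier(max_leaf_nodes=101, random_state=seed)
    elif name == "Medium Tree":
        scaled = False
        est = _medium_tree(seed)
    elif name == "Coarse Tree":
        scaled = False
        est = DecisionTreeClassifier(max_leaf_nodes=5, random_state=seed)
    else:
        raise ValueError(f"unknown classifier preset {name!r}")
    if scaled:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def train_and_score(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cv_folds: int | None = 5,
    seed: int = 0,
) -> dict:
    """Fit one preset; report CV, resubstitution and test accuracy (percent)."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if len(X_test) == 0:
        raise ValueError("test set is empty")
    n_fit = len(X_train)
    if cv_folds:
        n_fit = n_fit - int(np.ceil(n_fit / cv_folds))
    est = build_classifier(name, X_train.shape[1], n_fit, seed=seed)

    cv_acc = float("nan")
    if cv_folds:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_acc = 100.0 * float(
            cross_val_score(clone(est), X_train, y_train, cv=skf, scoring="accuracy").mean()
        )
    est.fit(X_train, y_train)
    resub_acc = 100.0 * float(np.mean(est.predict(X_train) == y_train))
    test_acc = 100.0 * float(np.mean(est.predict(X_test) == y_test))
    return {
        "classifier": name,
        "cv_accuracy": cv_acc,
        "resub_accuracy": resub_acc,
        "test_accuracy": test_acc,
    }


def benchmark(
    names,
    datasets: dict,
    cv_folds: int | None = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Score every preset on every projection method's train/test split.

    ``datasets`` maps projection-method name -> (X_train, y_train, X_test,
    y_test).  Returns the full grid and the best row (highest test accuracy;
    ties broken by panel order, then method order).
    """
    names = list(names) if names else list(CLASSIFIER_NAMES)
    unknown = [n for n in names if n not in CLASSIFIER_NAMES]
    if unknown:
        raise ValueError(f"unknown classifier presets: {unknown}")
    rows = []
    for method, (Xtr, ytr, Xte, yte) in datasets.items():
        for name in names:
            row = train_and_score(name, Xtr, ytr, Xte, yte, cv_folds=cv_folds, seed=seed)
            row["projection_method"] = method
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["projection_method", "classifier", "cv_accuracy", "resub_accuracy", "test_accuracy"],
    )
    order = {n: i for i, n in enumerate(CLASSIFIER_NAMES)}
    morder = {m: i for i, m in enumerate(datasets)}
    best_row = min(
        rows,
        key=lambda r: (-r["test_accuracy"], order[r["classifier"]], morder[r["projection_method"]]),
    )
    best = {
        "classifier": best_row["classifier"],
        "projection_method": best_row["projection_method"],
        "test_accuracy": best_row["test_accuracy"],
    }
    return table, best
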