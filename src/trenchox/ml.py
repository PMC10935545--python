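"""Random-forest prediction of mother-cell response peaks from the
126-feature matrix, grouped feature importance, and a concentration
classifier.

The regressor predicts each mother cell's reporter response peak from its
own morphology/growth features and those of its barrier cells; accuracy is
the mean-relative-error metric A = 1 - mean(|pred - obs| / obs), reported on
a held-out 20% of mother cells.  Feature importance uses mean decrease in
impurity, normalised to sum to one, and is aggregated into mother-cell and
barrier-cell group shares via the feature manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .metrics import FEATURE_COLUMNS, LABEL, feature_manifest

N_TREES = 100
MAX_DEPTH = 3000  # an effectively unconstrained depth cap
TEST_FRACTION = 0.2


def split_train_test(matrix: pd.DataFrame, fraction: float = TEST_FRACTION,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffled, seed-reproducible split by mother cell (row), 80:20 default.

    Requires at least 50 mothers; the two parts are disjoint and their union
    is the input.
    """
    if len(matrix) < 50:
        raise ValueError(f"need >= 50 mothers to split, got {len(matrix)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(matrix))
    n_test = int(round(fraction * len(matrix)))
    test_idx = order[:n_test]
    train_idx = order[n_test:]
    return (matrix.iloc[train_idx].reset_index(drop=True),
            matrix.iloc[test_idx].reset_index(drop=True))


def _check_features(matrix: pd.DataFrame, columns) -> np.ndarray:
    missing = [c for c in columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix lacks columns: {missing[:5]}")
    X = matrix[list(columns)].to_numpy(dtype=float)
    bad = [c for c, isnan in zip(columns, np.isnan(X).any(axis=0)) if isnan]
    if bad:
        raise ValueError(f"missing values in feature columns: {bad[:5]}")
    return X


def train_regressor(train: pd.DataFrame, n_trees: int = N_TREES,
                    max_depth: int = MAX_DEPTH, seed: int = 0,
                    columns=FEATURE_COLUMNS) -> RandomForestRegressor:
    """Fit the bootstrap forest of regression trees on the training mothers."""
    X = _check_features(train, columns)
    y = train[LABEL].to_numpy(dtype=float)
    model = RandomForestRegressor(n_estimators=n_trees, max_depth=max_depth,
                                  random_state=seed, n_jobs=1)
    model.fit(X, y)
    model.feature_names_ = list(columns)
    return model


def accuracy(pred, obs) -> float:
    """Mean-relative-error accuracy A = 1 - mean(|pred - obs| / obs).

    Observations must be strictly positive; A can be negative for very poor
    predictions and is reported as-is.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("pred and obs must have the same shape")
    if np.any(o <= 0):
        raise ValueError("observations must be positive for the relative metric")
    return float(1.0 - np.mean(np.abs(p - o) / o))


@dataclass
class ImportanceReport:
    per_feature: pd.Series
    mother_share: float
    barrier_share: float
    top2_share: float
    top_features: list

    def to_dict(self) -> dict:
        return {"mother_share": self.mother_share,
                "barrier_share": self.barrier_share,
                "top2_share": self.top2_share,
                "top_features": self.top_features,
                "per_feature": self.per_feature.to_dict()}


def importances(model, manifest: dict | None = None) -> ImportanceReport:
    """Mean-decrease-impurity importances, normalised, with group shares.

    Groups come from the manifest's ``mother``/``barrier`` tags; the two
    shares sum to one.  Also reports the cumulative share of the two
    top-ranked features.
    """
    manifest = manifest or feature_manifest()
    names = getattr(model, "feature_names_", None)
    if names is None or any(n not in manifest for n in names):
        unknown = [n for n in (names or []) if n not in manifest]
        raise ValueError(f"model features not in manifest: {unknown[:5] or 'none recorded'}")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        raise ValueError("degenerate model: zero total importance")
    imp = imp / total
    per = pd.Series(imp, index=names).sort_values(ascending=False)
    barrier = sum(v for n, v in per.items() if manifest[n]["group"] == "barrier")
    top2 = float(per.iloc[:2].sum())
    return ImportanceReport(per_feature=per, mother_share=float(1.0 - barrier),
                            barrier_share=float(barrier), top2_share=top2,
                            top_features=list(per.index[:5]))


def barrier_feature_columns(manifest: dict | None = None) -> list:
    manifest = manifest or feature_manifest()
    return [n for n, m in manifest.items() if m["group"] == "barrier"]


@dataclass
class ModelReport:
    """Everything the prediction stage reports for one (matrix, seed)."""

    accuracy: float
    n_train: int
    n_test: int
    seed: int
    predictions: pd.DataFrame
    importance: ImportanceReport
    barrier_only_accuracy: float | None = None
    barrier_only_n_features: int | None = None
    confusion: pd.DataFrame | None = None
    classifier_accuracy: float | None = None

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "n_train": self.n_train,
             "n_test": self.n_test, "seed": self.seed,
             "importance": self.importance.to_dict(),
             "barrier_only_accuracy": self.barrier_only_accuracy,
             "barrier_only_n_features": self.barrier_only_n_features,
             "classifier_accuracy": self.classifier_accuracy}
        if self.confusion is not None:
            d["confusion"] = {"classes": list(self.confusion.columns),
                              "rows": self.confusion.to_numpy().tolist()}
        return d


def evaluate_regressor(matrix: pd.DataFrame, seed: int = 0,
                       columns=FEATURE_COLUMNS, n_trees: int = N_TREES):
    """Train on a seeded 80:20 split and report test accuracy + predictions."""
    train, test = split_train_test(matrix, seed=seed)
    model = train_regressor(train, seed=seed, columns=columns, n_trees=n_trees)
    pred = model.predict(_check_features(test, columns))
    obs = test[LABEL].to_numpy(dtype=float)
    acc = accuracy(pred, obs)
    out = test[["trench_id", LABEL]].copy()
    out["predicted"] = pred
    return acc, out, model


def barrier_only_model(matrix: pd.DataFrame, seed: int = 0) -> tuple[float, int]:
    """Regression restricted to the barrier-cell feature columns
    (7 stats x 4 series x 2 epochs = 56 features)."""
    cols = barrier_feature_columns()
    acc, _, _ = evaluate_regressor(matrix, seed=seed, columns=tuple(cols))
    return acc, len(cols)


def train_classifier(matrix: pd.DataFrame, seed: int = 0,
                     min_per_class: int = 25, n_trees: int = N_TREES,
                     max_depth: int = MAX_DEPTH):
    """Random-forest classification of the external H2O2 concentration.

    Each distinct external concentration is a class; requires at least two
    classes with ``min_per_class`` mothers each.  Returns the row-normalised
    confusion matrix on the held-out split and the overall test accuracy.
    """
    classes = matrix["external_c0_uM"].round(3)
    counts = classes.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 concentration classes")
    low = counts[counts < min_per_class]
    if len(low):
        raise ValueError(f"classes below minimum size {min_per_class}: "
                         f"{dict(low)}")
    train, test = split_train_test(matrix, seed=seed)
    X = _check_features(train, FEATURE_COLUMNS)
    y = train["external_c0_uM"].round(3).astype(str).to_numpy()
    model = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                   random_state=seed, n_jobs=1)
    model.fit(X, y)
    pred = model.predict(_check_features(test, FEATURE_COLUMNS))
    obs = test["external_c0_uM"].round(3).astype(str).to_numpy()
    labels = sorted(counts.index.astype(str), key=float)
    cm = np.zeros((len(labels), len(labels)))
    pos = {c: i for i, c in enumerate(labels)}
    for o, p in zip(obs, pred):
        cm[pos[o], pos[p]] += 1
    rowsum = cm.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    cm = cm / rowsum
    conf = pd.DataFrame(cm, index=labels, columns=labels)
    cls_acc = float(np.mean(obs == pred))
    return conf, cls_acc


def full_report(matrix: pd.DataFrame, seed: int = 0,
                with_classifier: bool | None = None) -> ModelReport:
    """Regression + importance analysis (+ classifier when the matrix holds
    several concentration classes) in one report."""
    acc, preds, model = evaluate_regressor(matrix, seed=seed)
    imp = importances(model)
    b_acc, b_n = barrier_only_model(matrix, seed=seed)
    n_classes = matrix["external_c0_uM"].round(3).nunique()
    if with_classifier is None:
        with_classifier = n_classes >= 2
    conf = cls_acc = None
    if with_classifier:
        conf, cls_acc = train_classifier(matrix, seed=seed)
    n_test = len(preds)
    return ModelReport(accuracy=acc, n_train=len(matrix) - n_test,
                       n_test=n_test, seed=seed, predictions=preds,
                       importance=imp, barrier_only_accuracy=b_acc,
                       barrier_only_n_features=b_n, confusion=conf,
                       classifier_accuracy=cls_acc)
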