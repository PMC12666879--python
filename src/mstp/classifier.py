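"""Random-forest assignment of disability-worsening phenotypes from baseline
features, with permutation importance and label transfer to treated patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .matching import NUMERIC_COVARIATES, encode_baseline

DEFAULT_HYPERPARAMS = dict(
    n_estimators=500,
    max_features="sqrt",
    max_depth=None,
    class_weight="balanced_subsample",
)


@dataclass
class ClassifierReport:
    accuracy: float
    per_class: pd.DataFrame        # class, precision, recall, support
    importance: pd.DataFrame       # feature, accuracy_drop_pct, share
    split_seed: int
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="records"),
            "importance": self.importance.to_dict(orient="records"),
            "split_seed": self.split_seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def _features(baseline: pd.DataFrame) -> pd.DataFrame:
    return encode_baseline(baseline).set_index("patient_id")[NUMERIC_COVARIATES]


def permutation_importance(clf, X_test: pd.DataFrame, y_test, n_repeats: int = 20,
                           seed: Optional[int] = None) -> pd.DataFrame:
    """Held-out permutation importance as percentage accuracy drop and share."""
    result = _sk_permutation_importance(
        clf, X_test, y_test, scoring="accuracy", n_repeats=n_repeats,
        random_state=seed)
    drop = result.importances_mean * 100.0
    positive = np.clip(drop, 0.0, None)
    total = positive.sum()
    share = positive / total if total > 0 else np.zeros_like(positive)
    return pd.DataFrame({
        "feature": list(X_test.columns),
        "accuracy_drop_pct": drop,
        "share": share,
    }).sort_values("accuracy_drop_pct", ascending=False, ignore_index=True)


def train_classifier(baseline: pd.DataFrame, labels: pd.Series, split: float = 0.7,
                     seed: int = 0, hyperparams: Optional[dict] = None,
                     importance_repeats: int = 20):
    """Train on a stratified 70/30 patient split; report on the held-out 30%.

    ``labels`` must be indexed by patient_id (modal posterior assignments on
    the untreated cohort). Returns (fitted forest, ClassifierReport).
    """
    X = _features(baseline)
    y = labels.reindex(X.index)
    if y.isna().any():
        raise ValueError("every patient in the baseline table needs a label")
    if y.nunique() < 2:
        raise ValueError("at least two phenotype classes are required")
    counts = y.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"stratified splitting impossible: classes with <2 members: "
            f"{counts[counts < 2].index.tolist()}")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed)
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    clf = RandomForestClassifier(random_state=seed, **params)
    clf.fit(X_train, y_train)
    pred = clf.predict(X_test)
    acc = float(accuracy_score(y_test, pred))
    classes = sorted(y.unique())
    prec, rec, _, supp = precision_recall_fscore_support(
        y_test, pred, labels=classes, zero_division=0)
    per_class = pd.DataFrame({"class": classes, "precision": prec,
                              "recall": rec, "support": supp})
    importance = permutation_importance(clf, X_test, y_test,
                                        n_repeats=importance_repeats, seed=seed)
    report = ClassifierReport(accuracy=acc, per_class=per_class,
                              importance=importance, split_seed=seed,
                              n_train=len(X_train), n_test=len(X_test))
    return clf, report


def assign_phenotypes(clf, baseline: pd.DataFrame) -> pd.DataFrame:
    """Predict phenotype labels and probability vectors for new patients."""
    X = _features(baseline)
    expected = list(getattr(clf, "feature_names_in_", X.columns))
    missing = [f for f in expected if f not in X.columns]
    extra = [f for f in X.columns if f not in expected]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing}, extra={extra}")
    X = X[expected]
    probs = clf.predict_proba(X)
    labels = clf.classes_[np.argmax(probs, axis=1)]
    out = pd.DataFrame({"patient_id": X.index, "label": labels})
    for j, cls in enumerate(clf.classes_):
        out[f"p_{cls}"] = probs[:, j]
    return out
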