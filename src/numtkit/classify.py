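"""Random-forest classification of NUMTs vs matched random sequences.

Random-search hyperparameter tuning scored by stratified 10-fold
cross-validated AUROC, evaluation on a held-out stratified test split,
and impurity feature importances summed per descriptor family.  The
forest itself is scikit-learn's; this module fixes its configuration
surface and the evaluation protocol.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import ClassifierReport, TuningSpace


def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain two classes")


def _forest(params: Dict, seed: int, n_features: int) -> RandomForestClassifier:
    mf = params.get("max_features")
    if mf is not None:
        mf = min(int(mf), n_features)
    return RandomForestClassifier(
        n_estimators=int(params["n_estimators"]),
        max_depth=int(params["max_depth"]),
        max_features=mf,
        random_state=seed,
        n_jobs=1,
    )


def cv_auroc(
    X: np.ndarray, y: np.ndarray, params: Dict, k: int = 10, seed: int = 0
) -> np.ndarray:
    """Per-fold AUROC under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = _forest(params, seed + fold, X.shape[1])
        clf.fit(X[tr], y[tr])
        prob = clf.predict_proba(X[te])[:, 1]
        scores.append(roc_auc_score(y[te], prob))
    return np.array(scores)


def tune(
    features: pd.DataFrame,
    labels: Sequence[int],
    space: Optional[TuningSpace] = None,
    k: int = 10,
) -> Tuple[Dict, pd.DataFrame]:
    """Random-search the forest hyperparameters by stratified CV AUROC.

    Returns (best parameter dict, full per-draw trace); the trace carries
    every sampled tuple and its mean AUROC (the parallel-coordinates
    view of the search).
    """
    if space is None:
        space = TuningSpace()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    rng = np.random.default_rng(space.seed)
    n_feat = X.shape[1]
    mf_hi = space.max_features[1] if space.max_features[1] is not None else n_feat
    mf_hi = min(mf_hi, n_feat)
    rows = []
    for draw in range(space.n_draws):
        params = {
            "n_estimators": int(rng.integers(space.n_trees[0], space.n_trees[1] + 1)),
            "max_depth": int(rng.integers(space.max_depth[0], space.max_depth[1] + 1)),
            "max_features": int(rng.integers(space.max_features[0], mf_hi + 1)),
        }
        scores = cv_auroc(X, y, params, k=k, seed=space.seed)
        rows.append({**params, "mean_auroc": scores.mean(), "draw": draw})
    trace = pd.DataFrame(rows)
    best = trace.loc[trace["mean_auroc"].idxmax()]
    best_params = {
        "n_estimators": int(best["n_estimators"]),
        "max_depth": int(best["max_depth"]),
        "max_features": int(best["max_features"]),
    }
    return best_params, trace


def grouped_importances(
    importances: np.ndarray, columns: Sequence[str], groups: Dict[str, str]
) -> Dict[str, float]:
    """Sum impurity importances within descriptor families.

    Families absent from the model's splits get 0; the sums inherit the
    forest's normalization (total 1 when any split happened).
    """
    out: Dict[str, float] = {g: 0.0 for g in dict.fromkeys(groups.values())}
    for col, imp in zip(columns, importances):
        out[groups[col]] += float(imp)
    return out


def evaluate(
    features: pd.DataFrame,
    labels: Sequence[int],
    params: Dict,
    groups: Optional[Dict[str, str]] = None,
    k: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> ClassifierReport:
    """Train/evaluate at fixed hyperparameters.

    Stratified ``test_fraction`` hold-out; k-fold CV AUROC on the training
    portion; final fit on the training portion scored on the hold-out
    (accuracy, per-class confusion counts and recalls at the 0.5 vote
    threshold); feature importances summed per descriptor group.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    fold_scores = cv_auroc(Xtr, ytr, params, k=k, seed=seed)
    clf = _forest(params, seed, X.shape[1])
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = float((pred == yte).mean())
    confusion: Dict[str, Dict[str, int]] = {}
    recall: Dict[str, float] = {}
    for cls in np.unique(y):
        mask = yte == cls
        correct = int((pred[mask] == cls).sum())
        confusion[str(cls)] = {
            "correct": correct,
            "incorrect": int(mask.sum()) - correct,
        }
        recall[str(cls)] = correct / int(mask.sum())
    if groups is None:
        groups = {c: "all" for c in features.columns}
    gimp = grouped_importances(
        clf.feature_importances_, list(features.columns), groups
    )
    return ClassifierReport(
        best_params=dict(params),
        per_fold_auroc=[float(s) for s in fold_scores],
        mean_auroc=float(fold_scores.mean()),
        sd_auroc=float(fold_scores.std()),
        test_accuracy=acc,
        confusion=confusion,
        per_class_recall=recall,
        grouped_importances=gimp,
    )
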