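"""Classification trees linking stimulus kinematics to observers' responses.

CART trees (Gini impurity, cost-complexity pruning with the pruning level
chosen by cross-validation on the training split) are trained on 80% of the
trials and tested on the held-out 20%.  Variable importance is the
normalized Gini improvement attributable to each feature; test accuracy is
assessed against chance with an exact two-sided binomial test.  The engine
is scikit-learn's DecisionTreeClassifier behind the TreeModel contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateOutcomeError, InsufficientDataError, InvalidInputError

POS_LABEL = "PASS"


@dataclass(frozen=True)
class TreeModel:
    """A fitted, pruned CART tree plus its split metadata."""

    estimator: DecisionTreeClassifier
    feature_names: tuple[str, ...]
    importance: dict[str, float]  # normalized to sum 1 (or all 0 for a stump)
    root_feature: str | None
    root_threshold: float | None
    ccp_alpha: float
    train_index: np.ndarray
    test_index: np.ndarray
    pos_label: str
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[list(self.feature_names)].to_numpy(float))


def _select_ccp_alpha(
    X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 5
) -> float:
    """Cost-complexity level maximising cross-validated accuracy."""
    base = DecisionTreeClassifier(criterion="gini", random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if alphas.size <= 1:
        return float(alphas[0]) if alphas.size else 0.0
    alphas = alphas[:-1]  # the largest alpha collapses the tree to a stump
    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(n_folds, counts.min()))
    if n_folds < 2:
        return 0.0
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(alphas.size)
    for tr, va in cv.split(X, y):
        for i, a in enumerate(alphas):
            clf = DecisionTreeClassifier(criterion="gini", random_state=seed, ccp_alpha=a)
            clf.fit(X[tr], y[tr])
            scores[i] += (clf.predict(X[va]) == y[va]).mean()
    return float(alphas[int(np.argmax(scores))])


def train_tree(
    features: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    feature_names: list[str] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    pos_label: str = POS_LABEL,
) -> TreeModel:
    """Train a pruned CART tree on a stratified 80/20 split.

    ``outcome`` is binary (e.g. the observer's PASS/PLACE choice, or
    correct/incorrect).  Deterministic given the seed.
    """
    y = np.asarray(outcome)
    if feature_names is None:
        feature_names = [
            c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])
        ]
    X = features[feature_names].to_numpy(float)
    if X.shape[0] < 20:
        raise InsufficientDataError("need at least 20 rows to train and test")
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("outcome has a single level")
    idx = np.arange(X.shape[0])
    tr, te = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=y
    )
    if np.unique(y[tr]).size < 2:
        raise DegenerateOutcomeError("training split has a single outcome level")

    alpha = _select_ccp_alpha(X[tr], y[tr], seed)
    clf = DecisionTreeClassifier(criterion="gini", random_state=seed, ccp_alpha=alpha)
    clf.fit(X[tr], y[tr])

    imp = clf.feature_importances_
    total = imp.sum()
    importance = {
        name: float(v / total) if total > 0 else 0.0
        for name, v in zip(feature_names, imp)
    }
    if clf.tree_.node_count > 1:
        root_feature = feature_names[int(clf.tree_.feature[0])]
        root_threshold = float(clf.tree_.threshold[0])
    else:
        root_feature, root_threshold = None, None
    return TreeModel(
        estimator=clf,
        feature_names=tuple(feature_names),
        importance=importance,
        root_feature=root_feature,
        root_threshold=root_threshold,
        ccp_alpha=alpha,
        train_index=tr,
        test_index=te,
        pos_label=pos_label,
        seed=seed,
    )


@dataclass(frozen=True)
class TreeEvaluation:
    accuracy: float
    sensitivity: float
    specificity: float
    p_binomial: float
    n_test: int


def evaluate_tree(
    model: TreeModel, features: pd.DataFrame, outcome: np.ndarray | pd.Series
) -> TreeEvaluation:
    """Held-out accuracy/sensitivity/specificity and an exact two-sided
    binomial test of #correct against chance (p = 0.5)."""
    y = np.asarray(outcome)
    if len(features) == 0:
        raise InvalidInputError("test set is empty")
    pred = model.predict(features)
    correct = pred == y
    acc = float(correct.mean())
    pos = y == model.pos_label
    sens = float((pred[pos] == y[pos]).mean()) if pos.any() else np.nan
    neg = ~pos
    spec = float((pred[neg] == y[neg]).mean()) if neg.any() else np.nan
    p = sps.binomtest(int(correct.sum()), len(y), 0.5, alternative="two-sided").pvalue
    return TreeEvaluation(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        p_binomial=float(p),
        n_test=len(y),
    )


def train_and_evaluate(
    features: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    feature_names: list[str] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    pos_label: str = POS_LABEL,
) -> tuple[TreeModel, TreeEvaluation]:
    """Train on the 80% split and evaluate on the held-out 20%."""
    model = train_tree(features, outcome, feature_names, train_fraction, seed, pos_label)
    y = np.asarray(outcome)
    ev = evaluate_tree(model, features.iloc[model.test_index], y[model.test_index])
    return model, ev


def subgroup_analysis(
    data: pd.DataFrame,
    outcome_col: str,
    subgroup_col: str,
    feature_names: list[str],
    min_size: int = 20,
    seed: int = 0,
    pos_label: str = POS_LABEL,
) -> dict[str, dict]:
    """Per-subgroup tree analysis with the shared train/test protocol.

    Subgroups below ``min_size`` rows (or with a single outcome level) are
    skipped with a recorded reason rather than failing the whole report.
    Returns, per subgroup, the model, its evaluation and the importance
    ranking for cross-group contrasts.
    """
    out: dict[str, dict] = {}
    for name, grp in data.groupby(subgroup_col, sort=True):
        if len(grp) < min_size:
            out[str(name)] = {"skipped": f"only {len(grp)} rows (min {min_size})"}
            continue
        y = grp[outcome_col].to_numpy()
        if np.unique(y).size < 2:
            out[str(name)] = {"skipped": "single outcome level"}
            continue
        model, ev = train_and_evaluate(
            grp.reset_index(drop=True), y, feature_names, seed=seed, pos_label=pos_label
        )
        ranking = sorted(model.importance, key=model.importance.get, reverse=True)
        out[str(name)] = {"model": model, "evaluation": ev, "importance_rank": ranking}
    return out
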