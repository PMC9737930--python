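"""Diagnosis classification and BARS-severity regression under LOSO CV.

Disease-status classification uses a balanced random forest: 200 trees,
each grown on a bootstrap in which every class is sampled (with
replacement) down to the minority-class size, compensating for the
class imbalance typical of clinical cohorts.  Severity regression uses a
200-tree random forest with maximum depth 10 and a mean-absolute-error
split criterion, trained on control (score 0) and ataxia sessions only.

All metrics are computed under leave-one-subject-out cross-validation:
every session of one subject is held out per fold, so no subject's data
can leak between train and test.  Classification metrics (AUROC,
sensitivity/specificity at probability 0.5) are computed on the pooled
out-of-fold scores; regression reports pooled Pearson r, r^2 and MAE.
Test-retest reliability is the Pearson correlation of first- vs
second-session out-of-fold scores across subjects with repeat visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidDesignError, InvalidTargetError

N_TREES = 200
CLASSIFICATION_THRESHOLD = 0.5

META_COLUMNS = [
    "subject_id",
    "session_id",
    "diagnosis",
    "severity",
    "bars_total",
    "bars_right_arm",
    "bars_arm_leg",
]


@dataclass
class EvaluationReport:
    task: str  # "classification" | "regression"
    auroc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    confusion: np.ndarray | None = None
    class_order: list[str] | None = None
    pearson_r: float | None = None
    r_squared: float | None = None
    mae: float | None = None
    test_retest_corr: float | None = None
    per_session_scores: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "auroc": self.auroc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "mae": self.mae,
            "test_retest_corr": self.test_retest_corr,
            "notes": self.notes,
            "seed": self.seed,
        }
        if self.confusion is not None:
            d["confusion"] = np.asarray(self.confusion).tolist()
            d["class_order"] = self.class_order
        return d


class BalancedRandomForestClassifier:
    """Random forest whose per-tree bootstraps undersample to the minority class.

    For each of ``n_estimators`` trees, every class contributes a bootstrap
    (with replacement) of size equal to the smallest training-class count,
    so each tree sees an exactly balanced sample.  Probabilities are the
    average of per-tree leaf class frequencies.  ``sampled_indices_`` keeps
    each tree's bootstrap for balance auditing.
    """

    def __init__(self, n_estimators: int = N_TREES, max_features: str = "sqrt",
                 random_state: int | np.random.Generator | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        class_idx = [np.nonzero(y_enc == c)[0] for c in range(len(self.classes_))]
        m = min(len(ix) for ix in class_idx)
        if m == 0:
            raise InvalidDesignError("every class needs at least one training sample")
        self.estimators_ = []
        self.sampled_indices_ = []
        for _ in range(self.n_estimators):
            idx = np.concatenate([rng.choice(ix, size=m, replace=True) for ix in class_idx])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_enc[idx])
            self.estimators_.append(tree)
            self.sampled_indices_.append(idx)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            proba[:, tree.classes_] += p
        return proba / len(self.estimators_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = np.mean([t.feature_importances_ for t in self.estimators_], axis=0)
        s = imp.sum()
        return imp / s if s > 0 else imp


# ---------------------------------------------------------------------------
# feature-table helpers


def feature_columns(table: pd.DataFrame, subset: str = "all") -> list[str]:
    """Select feature columns by origin: 'all', 'tf_only' or 'arhmm_only'.

    Time-frequency column names carry a modality segment
    ({task}_{side}_{accel|gyro}_...); AR-HMM names do not.
    """
    feats = [c for c in table.columns if c not in META_COLUMNS]
    if subset == "all":
        return feats
    is_tf = [c.split("_")[2] in ("accel", "gyro") if len(c.split("_")) > 2 else False for c in feats]
    if subset == "tf_only":
        return [c for c, t in zip(feats, is_tf) if t]
    if subset == "arhmm_only":
        return [c for c, t in zip(feats, is_tf) if not t]
    raise InvalidDesignError(f"unknown feature subset {subset!r}")


def impute_sentinels(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN sentinels with the training-fold finite column maximum.

    Fold-local imputation avoids leaking test-fold statistics; an all-NaN
    training column imputes to 0.
    """
    train = train.copy()
    test = test.copy()
    with np.errstate(all="ignore"):
        col_max = np.nanmax(np.where(np.isfinite(train), train, np.nan), axis=0)
    col_max = np.where(np.isfinite(col_max), col_max, 0.0)
    for X in (train, test):
        bad = ~np.isfinite(X)
        X[bad] = np.broadcast_to(col_max, X.shape)[bad]
    return train, test


def loso_splits(table: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out splits: one fold per subject, all their sessions held out."""
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise InvalidDesignError("LOSO needs at least 2 subjects")
    splits = []
    for subject in subjects:
        test = np.nonzero((table["subject_id"] == subject).to_numpy())[0]
        train = np.nonzero((table["subject_id"] != subject).to_numpy())[0]
        splits.append((train, test))
    return splits


# ---------------------------------------------------------------------------
# evaluation


def classify_loso(
    table: pd.DataFrame,
    classes: tuple[str, ...] = ("ataxia", "control"),
    feature_subset: str = "all",
    seed: int = 0,
) -> EvaluationReport:
    """LOSO balanced-random-forest classification of diagnosis.

    For two classes, ``classes[0]`` is the positive class; AUROC,
    sensitivity and specificity come from pooled out-of-fold positive-class
    probabilities thresholded at 0.5.  For three classes the report carries
    accuracy and a confusion matrix instead.
    """
    sub = table[table["diagnosis"].isin(classes)].reset_index(drop=True)
    present = sub["diagnosis"].unique()
    if len(present) < 2:
        raise InvalidDesignError("need at least 2 classes present")
    feats = feature_columns(sub, feature_subset)
    X = sub[feats].to_numpy(dtype=float)
    y = sub["diagnosis"].to_numpy()
    rng = np.random.default_rng(seed)

    scores = np.full((len(sub), len(classes)), np.nan)
    notes = []
    for train, test in loso_splits(sub):
        if len(np.unique(y[train])) < len(classes):
            notes.append(
                f"fold for subject {sub.loc[test[0], 'subject_id']} skipped: "
                "a class is absent from its training fold"
            )
            continue
        Xtr, Xte = impute_sentinels(X[train], X[test])
        clf = BalancedRandomForestClassifier(random_state=rng).fit(Xtr, y[train])
        proba = clf.predict_proba(Xte)
        order = [list(clf.classes_).index(c) for c in classes]
        scores[test] = proba[:, order]

    evaluated = np.all(np.isfinite(scores), axis=1)
    report = EvaluationReport(task="classification", notes=notes, seed=seed)
    report.class_order = list(classes)
    pos_scores = scores[evaluated, 0]
    y_eval = y[evaluated]
    report.per_session_scores = pd.DataFrame(
        {
            "subject_id": sub.loc[evaluated, "subject_id"].to_numpy(),
            "session_id": sub.loc[evaluated, "session_id"].to_numpy(),
            "true": y_eval,
            "score": pos_scores,
        }
    )
    if len(classes) == 2:
        y_bin = (y_eval == classes[0]).astype(int)
        report.auroc = float(roc_auc_score(y_bin, pos_scores))
        pred = (pos_scores > CLASSIFICATION_THRESHOLD).astype(int)
        cm = confusion_matrix(y_bin, pred, labels=[1, 0])
        tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
        report.sensitivity = float(tp / (tp + fn)) if tp + fn else None
        report.specificity = float(tn / (tn + fp)) if tn + fp else None
        report.confusion = cm
        report.accuracy = float((tp + tn) / cm.sum())
    else:
        pred_labels = np.array(classes)[np.nanargmax(scores[evaluated], axis=1)]
        report.accuracy = float((pred_labels == y_eval).mean())
        report.confusion = confusion_matrix(y_eval, pred_labels, labels=list(classes))
    report.test_retest_corr = test_retest(report.per_session_scores)
    return report


def regress_loso(
    table: pd.DataFrame,
    target: str = "bars_total",
    seed: int = 0,
    feature_subset: str = "all",
) -> EvaluationReport:
    """LOSO random-forest regression of a BARS score (ataxia + control rows).

    Sessions with a missing target are dropped (per-score session counts
    differ in practice).  Reports pooled out-of-fold Pearson r, r^2 and MAE.
    """
    if target not in ("bars_total", "bars_right_arm", "bars_arm_leg"):
        raise InvalidTargetError(f"unknown target {target!r}")
    sub = table[table["diagnosis"].isin(["ataxia", "control"])]
    sub = sub[np.isfinite(sub[target].astype(float))].reset_index(drop=True)
    if sub.empty or sub["subject_id"].nunique() < 2:
        raise InvalidTargetError(f"target {target} present for fewer than 2 subjects")
    feats = feature_columns(sub, feature_subset)
    X = sub[feats].to_numpy(dtype=float)
    y = sub[target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    preds = np.full(len(sub), np.nan)
    for train, test in loso_splits(sub):
        Xtr, Xte = impute_sentinels(X[train], X[test])
        model = RandomForestRegressor(
            n_estimators=N_TREES,
            max_depth=10,
            criterion="absolute_error",
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(Xtr, y[train])
        preds[test] = model.predict(Xte)

    report = EvaluationReport(task="regression", seed=seed)
    report.per_session_scores = pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "session_id": sub["session_id"],
            "true": y,
            "score": preds,
        }
    )
    report.mae = float(np.abs(preds - y).mean())
    if np.std(y) == 0 or np.std(preds) == 0:
        report.notes.append("correlation undefined: constant target or predictions")
    else:
        r = float(stats.pearsonr(y, preds).statistic)
        report.pearson_r = r
        report.r_squared = r * r
    report.test_retest_corr = test_retest(report.per_session_scores)
    return report


def test_retest(per_session_scores: pd.DataFrame) -> float | None:
    """Pearson correlation of first- vs second-session scores across repeat subjects.

    Sessions beyond the second are ignored.  Returns None with fewer than
    2 repeat subjects or degenerate score variance.
    """
    df = per_session_scores.sort_values(["subject_id", "session_id"])
    firsts, seconds = [], []
    for _, grp in df.groupby("subject_id"):
        if len(grp) >= 2:
            firsts.append(grp["score"].iloc[0])
            seconds.append(grp["score"].iloc[1])
    if len(firsts) < 2 or np.std(firsts) == 0 or np.std(seconds) == 0:
        return None
    return float(stats.pearsonr(firsts, seconds).statistic)


def permutation_pvalue(
    y_true: np.ndarray, y_pred: np.ndarray, n_perm: int = 200, seed: int = 0
) -> float:
    """One-sided permutation p-value for Pearson r > 0 (targets permuted)."""
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    r_obs = stats.pearsonr(y_true, y_pred).statistic
    count = 0
    for _ in range(n_perm):
        r = stats.pearsonr(rng.permutation(y_true), y_pred).statistic
        if r >= r_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def feature_importance(
    table: pd.DataFrame,
    classes: tuple[str, ...] = ("ataxia", "control"),
    seed: int = 0,
) -> pd.DataFrame:
    """Impurity-based importances of a balanced RF fit on all sessions.

    Returns a DataFrame sorted by descending importance with ``origin``
    (tf / arhmm) and ``task`` columns for top-k audits.
    """
    sub = table[table["diagnosis"].isin(classes)].reset_index(drop=True)
    feats = feature_columns(sub, "all")
    X = sub[feats].to_numpy(dtype=float)
    X, _ = impute_sentinels(X, X[:0])
    y = sub["diagnosis"].to_numpy()
    clf = BalancedRandomForestClassifier(random_state=np.random.default_rng(seed)).fit(X, y)
    tf_set = set(feature_columns(sub, "tf_only"))
    out = pd.DataFrame(
        {
            "feature": feats,
            "importance": clf.feature_importances_,
            "origin": ["tf" if f in tf_set else "arhmm" for f in feats],
            "task": [f.split("_")[0] for f in feats],
        }
    )
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
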