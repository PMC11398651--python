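"""Grade-classification stage: rank-sum group tests, stratified splitting,
SMOTE balancing, treebag recursive feature elimination and a boosted-tree
model with test-set evaluation.

Grade groups: 0 = well / well-to-moderately differentiated, 1 = moderately /
moderately-to-poorly / poorly differentiated (the positive class for
sensitivity, specificity, PPV and NPV at the 0.5 probability threshold).
Balancing and feature selection operate strictly on the training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

XGB_PARAMS = dict(n_estimators=300, max_depth=3, learning_rate=0.1)


def _rank_sum(values: np.ndarray, idx: np.ndarray, ranks: np.ndarray) -> float:
    return float(ranks[idx].sum())


def wilcoxon_grade_test(values, groups) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a feature across two groups.

    Midranks for ties; exact enumeration of all group assignments when
    n1 + n2 <= 10, normal approximation with continuity and tie correction
    otherwise.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    if labs.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labs.size}")
    g1 = values[groups == labs[0]]
    g2 = values[groups == labs[1]]
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need >= 2 observations")
    n1, n = g1.size, values.size
    if n <= 10:
        ranks = stats.rankdata(values)  # midranks
        w_obs = ranks[groups == labs[0]].sum()
        ws = np.array([ranks[list(c)].sum() for c in combinations(range(n), n1)])
        lo = (ws <= w_obs + 1e-12).mean()
        hi = (ws >= w_obs - 1e-12).mean()
        return float(min(1.0, 2.0 * min(lo, hi)))
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def split_train_test(features: pd.DataFrame, groups: pd.Series,
                     train_n: int = 29, test_n: int = 10, seed: int = 0):
    """Stratified, disjoint train/test split of exactly (train_n, test_n)."""
    if len(features) != train_n + test_n:
        raise ValueError(f"cohort size {len(features)} != {train_n} + {test_n}")
    groups = groups.loc[features.index]
    rng = np.random.default_rng(seed)
    test_idx: list = []
    for lab, members in groups.groupby(groups):
        ids = list(members.index)
        rng.shuffle(ids)
        k = int(round(test_n * len(ids) / len(features)))
        k = min(max(k, 1), len(ids) - 1)  # keep both groups on both sides
        test_idx.extend(ids[:k])
    # largest-remainder adjustment to hit test_n exactly
    while len(test_idx) > test_n:
        big = groups.loc[test_idx].value_counts().idxmax()
        test_idx.remove(next(i for i in reversed(test_idx) if groups[i] == big))
    remaining = [i for i in features.index if i not in test_idx]
    while len(test_idx) < test_n:
        big = groups.loc[remaining].value_counts().idxmax()
        pick = next(i for i in remaining if groups[i] == big)
        remaining.remove(pick)
        test_idx.append(pick)
    train_idx = [i for i in features.index if i not in test_idx]
    for side, idx in (("train", train_idx), ("test", test_idx)):
        if groups.loc[idx].nunique() < 2:
            raise ValueError(f"stratification failed: {side} split lacks a group")
    return (features.loc[train_idx], groups.loc[train_idx],
            features.loc[test_idx], groups.loc[test_idx])


def smote_oversample(features: pd.DataFrame, labels: pd.Series, seed: int = 0,
                     k_neighbors: int = 5):
    """Synthetic minority oversampling: convex combinations of minority
    neighbors until the class counts are equal. Originals are preserved."""
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    if counts.min() == counts.max():
        return features.copy(), labels.copy()
    minority = counts.idxmin()
    if counts[minority] < 2:
        raise ValueError("minority class needs >= 2 samples for SMOTE")
    x_min = features[labels == minority].values
    n_new = int(counts.max() - counts.min())
    k = min(k_neighbors, len(x_min) - 1)

    d = np.linalg.norm(x_min[:, None, :] - x_min[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k]

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_new):
        a = i % len(x_min)
        b = nn[a, rng.integers(k)]
        lam = rng.uniform()
        rows.append(x_min[a] + lam * (x_min[b] - x_min[a]))
    synth = pd.DataFrame(rows, columns=features.columns,
                         index=[f"synth{i}" for i in range(n_new)])
    out_x = pd.concat([features, synth])
    out_y = pd.concat([labels, pd.Series([minority] * n_new, index=synth.index)])
    return out_x, out_y


def _treebag(seed: int) -> RandomForestClassifier:
    # bagged decision trees = random forest with all features per split
    return RandomForestClassifier(n_estimators=100, max_features=None,
                                  random_state=seed)


def rfe_select_features(features: pd.DataFrame, labels: pd.Series,
                        max_k: int = 3, folds: int = 5, seed: int = 0) -> list[str]:
    """Recursive feature elimination with bagged-tree importance.

    Fewer than or exactly ``max_k`` candidates -> all are used. Otherwise
    features are eliminated one at a time by lowest bagged-tree importance
    down to ``max_k``; candidate subset sizes 1..max_k along the elimination
    path are scored by stratified ``folds``-fold cross-validated accuracy and
    the best size wins (ties go to the larger subset).
    """
    labels = labels.loc[features.index]
    if labels.nunique() < 2:
        raise ValueError("labels are degenerate (single class)")
    cols = list(features.columns)
    if len(cols) <= max_k:
        return cols
    x = features.copy()
    while len(cols) > max_k:
        est = _treebag(seed).fit(x[cols].values, labels.values)
        worst = cols[int(np.argmin(est.feature_importances_))]
        cols.remove(worst)
    # ranking within the final max_k by importance
    est = _treebag(seed).fit(x[cols].values, labels.values)
    order = [cols[i] for i in np.argsort(-est.feature_importances_)]

    n_splits = min(folds, int(labels.value_counts().min()))
    best_k, best_score = max_k, -np.inf
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for k in range(1, max_k + 1):
            score = cross_val_score(_treebag(seed), x[order[:k]].values,
                                    labels.values, cv=cv).mean()
            if score >= best_score:  # ties -> larger subset
                best_k, best_score = k, score
    return order[:best_k]


@dataclass
class ModelReport:
    selected_features: list[str]
    auc: float | None
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    train_size: int
    test_size: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features), "auc": self.auc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "npv": self.npv, "ppv": self.ppv, "train_size": self.train_size,
            "test_size": self.test_size, "seed": self.seed,
        }


def _safe_div(a, b):
    return float(a / b) if b else 0.0


def train_eval_boosted_trees(train_x: pd.DataFrame, train_y: pd.Series,
                             test_x: pd.DataFrame, test_y: pd.Series,
                             selected: list[str], seed: int = 0) -> ModelReport:
    """Fit a gradient-boosted tree classifier on the selected features and
    evaluate on the held-out test set (AUC rank-based; operating point 0.5)."""
    if not selected:
        raise ValueError("no selected features")
    from xgboost import XGBClassifier
    from sklearn.metrics import roc_auc_score

    clf = XGBClassifier(random_state=seed, eval_metric="logloss",
                        use_label_encoder=False, **XGB_PARAMS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train_x[selected].values, train_y.values.astype(int))
    prob = clf.predict_proba(test_x[selected].values)[:, 1]
    y = test_y.values.astype(int)

    if len(np.unique(y)) < 2:
        warnings.warn("single-class test set; AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(y, prob))
    pred = (prob >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ModelReport(
        selected_features=list(selected), auc=auc,
        sensitivity=_safe_div(tp, tp + fn), specificity=_safe_div(tn, tn + fp),
        npv=_safe_div(tn, tn + fn), ppv=_safe_div(tp, tp + fp),
        train_size=len(train_x), test_size=len(test_x), seed=seed,
    )


def run_grading_pipeline(features: pd.DataFrame, groups: pd.Series,
                         train_n: int = 29, test_n: int = 10, max_k: int = 3,
                         seed: int = 0) -> ModelReport:
    """Split -> SMOTE(train) -> RFE(train) -> boosted trees -> test metrics."""
    tr_x, tr_y, te_x, te_y = split_train_test(features, groups, train_n, test_n, seed)
    bal_x, bal_y = smote_oversample(tr_x, tr_y, seed=seed)
    selected = rfe_select_features(bal_x, bal_y, max_k=max_k, seed=seed)
    return train_eval_boosted_trees(bal_x, bal_y, te_x, te_y, selected, seed=seed)


def descriptive_statistics(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature group means/SDs and Wilcoxon rank-sum p (group layout of a
    grade-association table)."""
    groups = groups.loc[features.index]
    testable = (groups.value_counts().min() >= 2) and groups.nunique() == 2
    if not testable:
        warnings.warn("a grade group has fewer than 2 patients; "
                      "rank-sum p-values reported as NaN")
    rows = []
    for f in features.columns:
        v = features[f]
        rows.append({
            "feature": f,
            "group0_mean": v[groups == 0].mean(), "group0_std": v[groups == 0].std(ddof=0),
            "group1_mean": v[groups == 1].mean(), "group1_std": v[groups == 1].std(ddof=0),
            "wilcoxon_p": (wilcoxon_grade_test(v.values, groups.values)
                           if testable else float("nan")),
        })
    return pd.DataFrame(rows)
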