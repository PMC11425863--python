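"""Dual-fluid fusion, feature selection, model search and the three-step
diagnostic cascade.

The cascade mirrors clinical triage: stage 1 separates healthy controls
from renal tumors, stage 2 separates benign (AML) from malignant (RCC)
tumors, stage 3 assigns the RCC subtype (ccRCC / pRCC / chRCC,
one-vs-rest). Serum and urine fingerprints are fused along the feature
axis (same subjects, wider feature space), features are shrunk by an
elastic-net family screen, and the classifier is chosen from a fixed
algorithm zoo by nested cross-validation on the training split only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression, Ridge, RidgeClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .core_io import FeatureMatrix, MALIGNANT_GROUPS, validate_clinical
from .errors import (
    ConfigError,
    ContractError,
    PairingError,
    UndefinedMetricError,
)

# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def concat_fingerprints(smf: FeatureMatrix, umf: FeatureMatrix) -> FeatureMatrix:
    """Fuse serum and urine matrices along the feature axis.

    One row per subject (sample sets must match exactly); columns are the
    serum block followed by the urine block, keeping their S/U prefixes.
    """
    s_ids, u_ids = set(smf.sample_ids), set(umf.sample_ids)
    if s_ids != u_ids:
        raise PairingError(
            f"serum/urine sample mismatch: {sorted(s_ids ^ u_ids)}"
        )
    u_frame = umf.frame.loc[smf.sample_ids]
    return FeatureMatrix(
        pd.concat([smf.frame, u_frame], axis=1), allow_negative=True
    )


# ---------------------------------------------------------------------------
# stratified split with demographic balance
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    ratio: tuple[float, float]
    stratify_on: str
    p_age: float
    p_sex: float
    balanced: bool
    attempts: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ConfigError(f"train/test overlap: {sorted(overlap)}")


def _balance_pvalues(clinical: pd.DataFrame, train_ids, test_ids) -> tuple[float, float]:
    c = clinical.set_index("sample_id")
    age_tr = c.loc[list(train_ids), "age"].to_numpy(dtype=float)
    age_te = c.loc[list(test_ids), "age"].to_numpy(dtype=float)
    p_age = float(stats.ttest_ind(age_tr, age_te, equal_var=False).pvalue)
    if np.isnan(p_age):  # zero variance in both arms
        p_age = 1.0
    sex_tab = pd.crosstab(
        c.loc[list(train_ids) + list(test_ids)].index.isin(train_ids),
        c.loc[list(train_ids) + list(test_ids), "sex"],
    )
    if sex_tab.shape[1] < 2:
        p_sex = 1.0
    else:
        p_sex = float(stats.chi2_contingency(sex_tab)[1])
    return p_age, p_sex


def stratified_split(
    clinical: pd.DataFrame,
    ratio: tuple[float, float] = (7, 3),
    seed: int = 0,
    stratify_on: str = "group",
    max_attempts: int = 200,
    balance_p: float = 0.05,
) -> SplitPlan:
    """Class-stratified train/test split, resampled until age (t-test) and
    sex (chi-square) differ between the splits with p > ``balance_p``.

    If no attempt balances within ``max_attempts``, the best attempt (by
    its smaller balance p-value) is returned flagged ``balanced=False``.
    """
    clinical = validate_clinical(clinical)
    ids = clinical["sample_id"].to_numpy()
    labels = clinical[stratify_on].to_numpy()
    test_size = ratio[1] / (ratio[0] + ratio[1])
    best = None
    for attempt in range(max_attempts):
        tr, te = train_test_split(
            ids,
            test_size=test_size,
            stratify=labels,
            random_state=seed + attempt,
            shuffle=True,
        )
        p_age, p_sex = _balance_pvalues(clinical, tr, te)
        plan = SplitPlan(
            list(tr), list(te), tuple(ratio), stratify_on,
            p_age, p_sex, min(p_age, p_sex) > balance_p, attempt + 1,
        )
        if plan.balanced:
            return plan
        if best is None or min(p_age, p_sex) > min(best.p_age, best.p_sex):
            best = plan
    warnings.warn(
        f"demographic balance not reached in {max_attempts} attempts; "
        "returning best attempt"
    )
    return best


# ---------------------------------------------------------------------------
# elastic-net family feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    selected: list[str]
    candidates: pd.DataFrame          # family, alpha, l1_ratio, val MSE
    best_family: str
    best_params: dict
    coefficients: pd.Series           # winner's coefficients (standardized X)
    fallback: bool


def _encode_binary(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ConfigError("binary encoding requires exactly 2 classes")
    return (y == classes[-1]).astype(float)


def elastic_net_select(
    X,
    y,
    l1_ratios: Sequence[float] = (0.2, 0.5, 0.8),
    alphas: Sequence[float] | None = None,
    coef_threshold: float = 0.05,
    seed: int = 0,
    val_fraction: float = 0.25,
    fallback_k: int = 5,
    feature_names: Sequence[str] | None = None,
) -> SelectionReport:
    """Select predictive features with the lasso/ridge/elastic-net family.

    All three regularizers are fit over their penalty grids on a
    standardized copy of X against a numeric encoding of y; the candidate
    with the lowest held-out MSE wins and features with winner
    |coefficient| > ``coef_threshold`` are retained. If none pass, the
    top ``fallback_k`` by |coefficient| are returned with a warning flag.

    For a multiclass y the screen runs one-vs-rest per class and the
    union of the per-class selections is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    feature_names = list(feature_names)
    classes = np.unique(y)
    # categorical targets with >2 classes go one-vs-rest; a continuous y is
    # regressed directly
    is_categorical = not np.issubdtype(y.dtype, np.floating)
    if is_categorical and classes.size > 2:
        union: list[str] = []
        reports = []
        for c in classes:
            rep = elastic_net_select(
                X, (y == c).astype(int), l1_ratios, alphas, coef_threshold,
                seed, val_fraction, fallback_k, feature_names,
            )
            reports.append(rep)
            union.extend([f for f in rep.selected if f not in union])
        first = reports[0]
        return SelectionReport(union, first.candidates, "one-vs-rest union",
                               {}, first.coefficients, any(r.fallback for r in reports))

    yb = _encode_binary(y) if not np.issubdtype(y.dtype, np.number) else y.astype(float)
    if alphas is None:
        alphas = np.logspace(-3, 0, 7)
    ridge_alphas = np.logspace(-2, 4, 7)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    Xtr, Xval, ytr, yval = train_test_split(
        Xs, yb, test_size=val_fraction, random_state=seed, shuffle=True
    )

    candidates: list[tuple[str, dict, object]] = []
    for a in alphas:
        candidates.append(("lasso", {"alpha": float(a)}, Lasso(alpha=a, max_iter=50_000)))
    for a in ridge_alphas:
        candidates.append(("ridge", {"alpha": float(a)}, Ridge(alpha=a)))
    for a in alphas:
        for l1 in l1_ratios:
            candidates.append(
                ("enet", {"alpha": float(a), "l1_ratio": float(l1)},
                 ElasticNet(alpha=a, l1_ratio=l1, max_iter=50_000))
            )

    rows = []
    best_idx, best_mse = 0, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (family, params, model) in enumerate(candidates):
            model.fit(Xtr, ytr)
            mse = float(np.mean((model.predict(Xval) - yval) ** 2))
            rows.append({"family": family, **params, "val_mse": mse})
            if mse < best_mse - 1e-15:
                best_idx, best_mse = k, mse
        family, params, model = candidates[best_idx]
        refit = clone(model)
        refit.fit(Xs, yb)

    coefs = pd.Series(refit.coef_.ravel(), index=feature_names)
    selected = list(coefs.index[np.abs(coefs.to_numpy()) > coef_threshold])
    fallback = False
    if not selected:
        warnings.warn("no coefficient above threshold; falling back to top-k")
        fallback = True
        selected = list(coefs.abs().sort_values(ascending=False).index[:fallback_k])
    return SelectionReport(
        selected, pd.DataFrame(rows), family, params, coefs, fallback
    )


# ---------------------------------------------------------------------------
# algorithm zoo and nested model search
# ---------------------------------------------------------------------------

def _zoo_entry(name: str, seed: int):
    """Factory + small hyperparameter grid per algorithm."""
    rs = {"random_state": seed}
    table = {
        "LGBM": (
            lambda: _make_lgbm(seed),
            {"num_leaves": [15, 31], "learning_rate": [0.1]},
        ),
        "ET": (lambda: ExtraTreesClassifier(n_estimators=100, **rs),
               {"max_features": ["sqrt", 0.5]}),
        "RF": (lambda: RandomForestClassifier(n_estimators=100, **rs),
               {"max_features": ["sqrt", 0.5]}),
        "AB": (lambda: AdaBoostClassifier(**rs), {"n_estimators": [50, 100]}),
        "GB": (lambda: GradientBoostingClassifier(**rs),
               {"learning_rate": [0.1], "max_depth": [2, 3]}),
        "DT": (lambda: DecisionTreeClassifier(**rs), {"max_depth": [3, 5, None]}),
        "KNN": (lambda: KNeighborsClassifier(), {"n_neighbors": [5, 11]}),
        "LR": (lambda: LogisticRegression(max_iter=5000, **rs),
               {"C": [0.1, 1.0, 10.0]}),
        "LDA": (lambda: LinearDiscriminantAnalysis(), {}),
        "NB": (lambda: GaussianNB(), {}),
        "Ridge": (lambda: RidgeClassifier(**rs), {"alpha": [0.1, 1.0, 10.0]}),
    }
    return table[name]


def _make_lgbm(seed: int):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        n_estimators=100, random_state=seed, verbose=-1, min_child_samples=5
    )


DEFAULT_ZOO = ("LGBM", "ET", "RF", "AB", "GB", "DT", "KNN", "LR", "LDA", "NB", "Ridge")


def _proba(model, X: np.ndarray) -> np.ndarray:
    """Class scores as (n, k) pseudo-probabilities for any zoo member."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    d = np.asarray(model.decision_function(X))
    if d.ndim == 1:
        p1 = expit(d)
        return np.column_stack([1 - p1, p1])
    e = np.exp(d - d.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _grid_iter(grid: Mapping[str, Sequence]) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _cv_auc(model_factory, params, X, y, folds, seed, rebalance_folds) -> float:
    """Mean stratified-CV ROC AUC; folds are clamped to the smallest class
    and degenerate single-class test folds are skipped (0.5 if none score)."""
    counts_min = int(np.unique(y, return_counts=True)[1].min())
    folds = min(folds, counts_min)
    if folds < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            continue
        Xtr, ytr = X[tr], y[tr]
        if rebalance_folds:
            Xtr, ytr = rebalance(Xtr, ytr, seed=seed + k)
        model = model_factory()
        model.set_params(**params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        aucs.append(_auc_any(y[te], _proba(model, X[te]), np.unique(y)))
    return float(np.mean(aucs)) if aucs else 0.5


def _auc_any(y_true, proba, classes) -> float:
    """ROC AUC: binary, or macro one-vs-rest for multiclass."""
    if len(classes) == 2:
        return roc_auc((y_true == classes[1]).astype(int), proba[:, 1])
    per_class = []
    for j, c in enumerate(classes):
        yt = (y_true == c).astype(int)
        if 0 < yt.sum() < yt.size:
            per_class.append(roc_auc(yt, proba[:, j]))
    return float(np.mean(per_class)) if per_class else np.nan


@dataclass
class SearchResult:
    algorithm: str
    hyperparameters: dict
    outer_fold_auc: list[float]
    model: object
    classes: np.ndarray
    leaderboard: pd.DataFrame


def model_search(
    X_train,
    y_train,
    zoo: Sequence[str] = DEFAULT_ZOO,
    folds: int = 10,
    inner_folds: int = 3,
    seed: int = 0,
    rebalance_folds: bool = False,
) -> SearchResult:
    """Nested cross-validation over the algorithm zoo.

    Outer stratified folds estimate generalization; an inner grid search
    tunes each algorithm's (small) hyperparameter grid by inner-CV ROC
    AUC. The winner is the algorithm with the highest mean outer-fold
    AUC (ties: fewer grid combinations, then zoo order); it is re-tuned
    and refit on the full training set.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ConfigError(
            f"need >= {folds} samples per class for {folds}-fold CV; "
            f"smallest class has {counts.min()}"
        )

    def inner_select(Xs, ys, factory, grid, sd):
        best_params, best_auc = {}, -np.inf
        for params in _grid_iter(grid):
            auc = _cv_auc(factory, params, Xs, ys, inner_folds, sd, rebalance_folds)
            if auc > best_auc + 1e-12:
                best_params, best_auc = params, auc
        return best_params

    rows = []
    results = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for zi, name in enumerate(zoo):
        factory, grid = _zoo_entry(name, seed)
        outer_aucs = []
        for k, (tr, te) in enumerate(splits):
            params = inner_select(X[tr], y[tr], factory, grid, seed + 1000 + k)
            Xtr, ytr = X[tr], y[tr]
            if rebalance_folds:
                Xtr, ytr = rebalance(Xtr, ytr, seed=seed + k)
            model = factory()
            model.set_params(**params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, ytr)
            outer_aucs.append(_auc_any(y[te], _proba(model, X[te]), classes))
        mean_auc = float(np.mean(outer_aucs))
        n_combos = len(_grid_iter(grid))
        rows.append({"algorithm": name, "mean_outer_auc": mean_auc,
                     "n_grid": n_combos, "zoo_order": zi})
        results.append((mean_auc, -n_combos, -zi, name, factory, grid, outer_aucs))

    results.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    _, _, _, best_name, factory, grid, outer_aucs = results[0]
    final_params = inner_select(X, y, factory, grid, seed + 2000)
    Xf, yf = (X, y)
    if rebalance_folds:
        Xf, yf = rebalance(X, y, seed=seed + 3000)
    best_model = factory()
    best_model.set_params(**final_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best_model.fit(Xf, yf)
    leaderboard = pd.DataFrame(rows).sort_values(
        "mean_outer_auc", ascending=False
    ).reset_index(drop=True)
    return SearchResult(best_name, final_params, outer_aucs, best_model, classes, leaderboard)


def rebalance(X, y, strategy: str = "oversample", seed: int = 0, role: str = "train"):
    """Random oversampling of minority classes to parity.

    Only ever legal on training data; any ``role`` other than "train"
    raises a contract violation by design.
    """
    if role != "train":
        raise ContractError("rebalancing must only be applied to training data")
    if strategy != "oversample":
        raise ConfigError(f"unknown rebalancing strategy {strategy!r}")
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ConfigError("rebalancing needs at least 2 classes")
    target = counts.max()
    rng = np.random.default_rng(seed)
    idx_all = []
    for c, n in zip(classes, counts):
        idx = np.where(y == c)[0]
        idx_all.append(idx)
        if n < target:
            idx_all.append(rng.choice(idx, size=target - n, replace=True))
    order = np.concatenate(idx_all)
    return X[order], y[order]


def model_feature_scores(model, feature_names: Sequence[str]) -> pd.Series:
    """Per-feature 'model score': feature importance for tree ensembles,
    coefficient magnitude for linear models.

    Both are non-negative so that a strictly-positive score cut keeps
    down-regulated markers in play — their effect direction is reported
    separately by the biomarker statistics table.
    """
    if hasattr(model, "feature_importances_"):
        vals = np.asarray(model.feature_importances_, dtype=float)
    elif hasattr(model, "coef_"):
        coef = np.atleast_2d(np.asarray(model.coef_, dtype=float))
        vals = np.abs(coef).max(axis=0)
    else:
        vals = np.zeros(len(feature_names))
    return pd.Series(vals, index=list(feature_names))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(y_true, scores) -> float:
    """ROC AUC by the rank (Mann-Whitney) statistic, ties as midranks."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(y_true, scores) -> float:
    """Area under the precision-recall curve by step integration
    (average precision; no interpolation)."""
    from sklearn.metrics import average_precision_score

    y_true = np.asarray(y_true)
    if y_true.sum() in (0, y_true.size):
        raise UndefinedMetricError("PR AUC undefined with a single class")
    return float(average_precision_score(y_true, scores))


def bootstrap_auc_ci(
    y_true, scores, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Point ROC AUC plus percentile-bootstrap CI over samples."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    point = roc_auc(y_true, scores)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, y_true.size, y_true.size)
        if 0 < y_true[idx].sum() < idx.size:
            vals.append(roc_auc(y_true[idx], scores[idx]))
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, (float(lo), float(hi))


def _binary_threshold_metrics(y, pred) -> dict[str, float]:
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f1": f1,
        "kappa": cohen_kappa_score(y, pred) if len(np.unique(pred)) > 0 else np.nan,
    }


@dataclass
class ModelReport:
    algorithm: str
    hyperparameters: dict
    cv_fold_auc: list[float]
    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    confusion: pd.DataFrame
    youden_threshold: float | None = None


def evaluate_metrics(
    y_true,
    scores,
    positive_class=1,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, tuple[float, float]], pd.DataFrame]:
    """Binary metric suite with percentile-bootstrap 95% CIs.

    ``scores`` is the probability of ``positive_class``; threshold metrics
    are computed at ``threshold`` (the Youden-optimal point is reported in
    the metrics dict as ``youden_threshold`` alongside).
    Returns (metrics, CIs, confusion matrix).
    """
    y = (np.asarray(y_true) == positive_class).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.sum() in (0, y.size):
        raise UndefinedMetricError("metrics undefined with single-class truth")
    pred = (scores >= threshold).astype(int)

    metrics = {"roc_auc": roc_auc(y, scores), "pr_auc": pr_auc(y, scores)}
    metrics.update(_binary_threshold_metrics(y, pred))
    # Youden-optimal operating point, reported alongside the fixed threshold
    order = np.argsort(-scores, kind="stable")
    tpr = np.cumsum(y[order]) / y.sum()
    fpr = np.cumsum(1 - y[order]) / (y.size - y.sum())
    metrics["youden_threshold"] = float(scores[order][np.argmax(tpr - fpr)])

    rng = np.random.default_rng(seed)
    boots: dict[str, list[float]] = {k: [] for k in metrics if k != "youden_threshold"}
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, y.size)
        yb, sb = y[idx], scores[idx]
        if yb.sum() in (0, yb.size):
            continue
        boots["roc_auc"].append(roc_auc(yb, sb))
        boots["pr_auc"].append(pr_auc(yb, sb))
        for k, v in _binary_threshold_metrics(yb, (sb >= threshold).astype(int)).items():
            boots[k].append(v)
    ci = {
        k: tuple(np.percentile([x for x in v if np.isfinite(x)], [2.5, 97.5]))
        for k, v in boots.items()
        if v
    }
    confusion = pd.DataFrame(
        confusion_matrix(y, pred, labels=[0, 1]),
        index=["true_neg", "true_pos"],
        columns=["pred_neg", "pred_pos"],
    )
    return metrics, ci, confusion


def evaluate_multiclass(y_true, proba: np.ndarray, classes: Sequence) -> dict:
    """Multiclass report: accuracy/kappa on argmax labels plus per-class
    one-vs-rest ROC and PR AUCs."""
    y_true = np.asarray(y_true)
    classes = list(classes)
    pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    out = {
        "accuracy": float(np.mean(pred == y_true)),
        "kappa": float(cohen_kappa_score(y_true, pred)),
        "ovr_roc_auc": {},
        "ovr_pr_auc": {},
    }
    for j, c in enumerate(classes):
        yt = (y_true == c).astype(int)
        if 0 < yt.sum() < yt.size:
            out["ovr_roc_auc"][str(c)] = roc_auc(yt, proba[:, j])
            out["ovr_pr_auc"][str(c)] = pr_auc(yt, proba[:, j])
    out["confusion"] = pd.DataFrame(
        confusion_matrix(y_true, pred, labels=classes), index=classes, columns=classes
    )
    return out


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeStage:
    search: SearchResult
    features: list[str]
    selection: SelectionReport | None


@dataclass
class CascadeModel:
    """Fitted three-step diagnostic cascade plus its split plan."""

    stage1: CascadeStage  # HC vs tumor
    stage2: CascadeStage  # AML vs malignant
    stage3: CascadeStage  # ccRCC / pRCC / chRCC (one-vs-rest)
    split: SplitPlan


def _stage_labels(groups: pd.Series) -> pd.DataFrame:
    lab = pd.DataFrame(index=groups.index)
    lab["tumor"] = (groups != "HC").astype(int)
    lab["malignant"] = groups.isin(MALIGNANT_GROUPS).astype(int)
    lab["subtype"] = groups.where(groups.isin(MALIGNANT_GROUPS))
    return lab


def fit_cascade(
    fused: FeatureMatrix,
    clinical: pd.DataFrame,
    split: SplitPlan,
    zoo: Sequence[str] = DEFAULT_ZOO,
    folds: int = 10,
    seed: int = 0,
    select_features: bool = True,
    coef_threshold: float = 0.05,
) -> CascadeModel:
    """Fit the three-step cascade on the training ids of ``split`` only.

    Feature selection, rebalancing and model search all consume train
    rows exclusively; test rows never enter any fitting path.
    """
    clinical = validate_clinical(clinical)
    groups = clinical.set_index("sample_id")["group"]
    labels = _stage_labels(groups)
    train = fused.subset_samples(split.train_ids)

    def build(stage_ids, y, stage_seed, rebalance_folds):
        Xm = train.subset_samples(stage_ids)
        if select_features:
            rep = elastic_net_select(
                Xm.values, y, coef_threshold=coef_threshold,
                seed=stage_seed, feature_names=Xm.feature_labels,
            )
            feats = rep.selected
        else:
            rep, feats = None, Xm.feature_labels
        # clamp outer folds to the smallest class so minority arms (AML in
        # stage 2) remain cross-validatable
        counts_min = int(pd.Series(y).value_counts().min())
        search = model_search(
            Xm.subset_features(feats).values, y, zoo=zoo,
            folds=max(2, min(folds, counts_min)),
            seed=stage_seed, rebalance_folds=rebalance_folds,
        )
        return CascadeStage(search, feats, rep)

    tr_ids = split.train_ids
    stage1 = build(tr_ids, labels.loc[tr_ids, "tumor"].to_numpy(), seed, False)

    tumor_ids = [i for i in tr_ids if labels.loc[i, "tumor"] == 1]
    stage2 = build(tumor_ids, labels.loc[tumor_ids, "malignant"].to_numpy(),
                   seed + 1, True)

    malig_ids = [i for i in tr_ids if labels.loc[i, "malignant"] == 1]
    stage3 = build(malig_ids, labels.loc[malig_ids, "subtype"].to_numpy(),
                   seed + 2, True)
    return CascadeModel(stage1, stage2, stage3, split)


def cascade_classify(cascade: CascadeModel, fused: FeatureMatrix) -> pd.DataFrame:
    """Route samples through the cascade; returns per-stage probabilities
    and the terminal label. Stages below a routing cut are not evaluated
    (their probabilities stay NaN)."""
    ids = fused.sample_ids
    out = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    p1 = _proba(
        cascade.stage1.search.model,
        fused.subset_features(cascade.stage1.features).values,
    )[:, list(cascade.stage1.search.classes).index(1)]
    out["p_tumor"] = p1
    out["p_malignant"] = np.nan
    subtype_classes = list(cascade.stage3.search.classes)
    for c in subtype_classes:
        out[f"p_{c}"] = np.nan
    out["label"] = "HC"

    tumor_mask = p1 >= 0.5
    if tumor_mask.any():
        sub = fused.subset_samples([i for i, m in zip(ids, tumor_mask) if m])
        p2 = _proba(
            cascade.stage2.search.model,
            sub.subset_features(cascade.stage2.features).values,
        )[:, list(cascade.stage2.search.classes).index(1)]
        out.loc[sub.sample_ids, "p_malignant"] = p2
        out.loc[sub.sample_ids, "label"] = np.where(p2 >= 0.5, "malignant", "AML")

    malig_ids = [i for i in ids if out.loc[i, "label"] == "malignant"]
    if malig_ids:
        sub = fused.subset_samples(malig_ids)
        p3 = _proba(
            cascade.stage3.search.model,
            sub.subset_features(cascade.stage3.features).values,
        )
        for j, c in enumerate(subtype_classes):
            out.loc[malig_ids, f"p_{c}"] = p3[:, j]
        out.loc[malig_ids, "label"] = [
            subtype_classes[j] for j in np.argmax(p3, axis=1)
        ]
    return out
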