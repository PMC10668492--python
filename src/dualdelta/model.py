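"""Feature selection, classifier grid optimization, and model evaluation.

The selector and classifier registries enumerate 45 and 32 named,
functional entries (hyperparameter variants of ~15 selector and ~12
classifier base families), so the full grid has 45 × 32 = 1440
combinations.  Each combination is evaluated with stratified,
replicated cross-validation where normalization and selection are fitted
inside every training fold, and the cell with the highest mean AUC wins.

Also here: LASSO/elastic-net selection at the cross-validated MSE minimum,
a ReliefF implementation, confusion metrics, propensity-score matching on
shape/first-order covariates, t-SNE embedding, and follow-up interval
grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LogisticRegression,
    Ridge,
    enet_path,
)
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .radiomics import FeatureTable

__all__ = [
    "Selector",
    "SelectorRegistry",
    "ClassifierRegistry",
    "GridResult",
    "EvaluationReport",
    "default_selector_registry",
    "default_classifier_registry",
    "enumerate_grid",
    "lasso_select",
    "relieff_rank",
    "run_grid",
    "crossval_auc",
    "confusion_metrics",
    "psm_match",
    "embed_features",
    "group_by_interval",
]


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, FeatureTable) else pd.DataFrame(table)


# ---------------------------------------------------------------------------
# ReliefF

def relieff_rank(table, labels, K: int = 10, n_iterations: int | None = None,
                 seed: int = 0) -> pd.Series:
    """ReliefF feature weights for a binary target.

    For each sampled instance, weights are decreased by the mean
    range-normalized distance to the K nearest hits and increased by the
    class-prior-weighted mean distance to the K nearest misses.  Weights
    lie in [-1, 1]; a feature identical to the label gets the maximal
    weight, pure noise stays near 0.
    """
    X = _as_frame(table)
    y = np.asarray(labels, dtype=int)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt <= K:
            raise ValueError(f"class {cls} has {cnt} samples; K={K} requires more")
    span = Xv.max(axis=0) - Xv.min(axis=0)
    span[span == 0] = 1.0
    Xn = (Xv - Xv.min(axis=0)) / span
    rng = np.random.default_rng(seed)
    m = n if n_iterations is None else min(n_iterations, n)
    sample = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
    priors = {c: (y == c).mean() for c in np.unique(y)}
    w = np.zeros(p)
    for i in sample:
        d = np.abs(Xn - Xn[i]).mean(axis=1)  # Manhattan / p
        d[i] = np.inf
        same = np.where(y == y[i])[0]
        hits = same[np.argsort(d[same], kind="stable")][:K]
        w -= np.abs(Xn[hits] - Xn[i]).mean(axis=0) / m
        for c in np.unique(y):
            if c == y[i]:
                continue
            cand = np.where(y == c)[0]
            order = cand[np.argsort(d[cand], kind="stable")][:K]
            frac = priors[c] / (1.0 - priors[y[i]])
            w += frac * np.abs(Xn[order] - Xn[i]).mean(axis=0) / m
    return pd.Series(w, index=names).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# LASSO / elastic-net selection

@dataclass
class LassoSelection:
    selected: list[str]
    coefficients: pd.Series
    alpha_min: float
    alphas: np.ndarray
    mse_path: np.ndarray  # (n_alphas,) mean CV MSE
    coef_path: np.ndarray  # (n_features, n_alphas)


def lasso_select(table, labels, alpha: float = 0.5, cv_folds: int = 5,
                 seed: int = 0, n_alphas: int = 50) -> LassoSelection:
    """Elastic-net selection at the cross-validated MSE minimum.

    ``alpha`` is the L1/L2 mixing parameter (1.0 = pure LASSO); the
    penalty strength is chosen where the mean cross-validated MSE is
    minimal, and the features with nonzero coefficients there are
    returned together with the full regularization trajectory.
    """
    X = _as_frame(table)
    y = np.asarray(labels, dtype=float)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    alphas, coefs, _ = enet_path(Xv, y, l1_ratio=alpha, alphas=n_alphas)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((cv_folds, len(alphas)))
    for k, (tr, te) in enumerate(cv.split(Xv)):
        _, fold_coefs, _ = enet_path(Xv[tr], y[tr], l1_ratio=alpha, alphas=alphas)
        pred = Xv[te] @ fold_coefs + y[tr].mean()
        mse[k] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))
    coef = pd.Series(coefs[:, best], index=names)
    selected = list(coef.index[coef != 0])
    if not selected:
        raise RuntimeError(
            "elastic-net solution at MSE_min is identically zero; the "
            "features may carry no signal at this penalty range"
        )
    return LassoSelection(selected=selected, coefficients=coef[coef != 0],
                          alpha_min=float(alphas[best]), alphas=alphas,
                          mse_path=mean_mse, coef_path=coefs)


# ---------------------------------------------------------------------------
# registries

@dataclass(frozen=True)
class Selector:
    """A named feature-scoring strategy; higher score = more relevant."""

    name: str
    scorer: "callable"

    def select(self, X: pd.DataFrame, y, n_features: int) -> list[str]:
        scores = self.scorer(X, np.asarray(y, dtype=int))
        scores = pd.Series(scores, index=X.columns).replace([np.inf, -np.inf], 0).fillna(0.0)
        order = scores.sort_values(ascending=False, kind="stable")
        nz = order[order != 0]
        keep = order.index[:n_features] if len(nz) >= n_features else (
            list(nz.index) + [c for c in order.index if c not in nz.index]
        )[:n_features]
        return list(keep)


@dataclass
class SelectorRegistry:
    entries: dict[str, Selector] = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def names(self):
        return list(self.entries)

    def __getitem__(self, name):
        return self.entries[name]


@dataclass
class ClassifierRegistry:
    entries: dict[str, "object"] = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def names(self):
        return list(self.entries)

    def __getitem__(self, name):
        return self.entries[name]


def _abs_model_coef(est):
    def scorer(X, y):
        m = clone(est)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X.to_numpy(dtype=float), y)
        coef = getattr(m, "coef_", None)
        if coef is None:
            return m.feature_importances_
        return np.abs(np.ravel(coef))
    return scorer


def _stat_scorer(fn):
    def scorer(X, y):
        Xv = X.to_numpy(dtype=float)
        return np.array([fn(Xv[:, j], y) for j in range(Xv.shape[1])])
    return scorer


def _safe(fn, default=0.0):
    def inner(x, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = fn(x, y)
            return default if not np.isfinite(v) else v
        except Exception:
            return default
    return inner


def default_selector_registry() -> SelectorRegistry:
    """45 named selector entries built from ~15 base strategies."""
    e: dict[str, Selector] = {}

    def add(name, scorer):
        e[name] = Selector(name, scorer)

    add("anova_f", lambda X, y: np.nan_to_num(f_classif(X.to_numpy(dtype=float), y)[0]))
    for k in (3, 5, 7):
        add(f"mutual_info_k{k}",
            lambda X, y, k=k: mutual_info_classif(
                X.to_numpy(dtype=float), y, n_neighbors=k, random_state=0))
    for K in (5, 10, 20):
        add(f"relieff_K{K}",
            lambda X, y, K=K: relieff_rank(X, y, K=min(K, int(np.bincount(y).min()) - 1)).loc[X.columns].to_numpy())
    add("pearson_r", _stat_scorer(_safe(lambda x, y: abs(stats.pearsonr(x, y)[0]))))
    add("spearman_rho", _stat_scorer(_safe(lambda x, y: abs(stats.spearmanr(x, y)[0]))))
    add("kendall_tau", _stat_scorer(_safe(lambda x, y: abs(stats.kendalltau(x, y)[0]))))
    add("welch_t", _stat_scorer(_safe(lambda x, y: abs(stats.ttest_ind(x[y == 0], x[y == 1], equal_var=False)[0]))))
    add("mannwhitney_u", _stat_scorer(_safe(
        lambda x, y: abs(stats.mannwhitneyu(x[y == 0], x[y == 1])[0] / (max((y == 0).sum() * (y == 1).sum(), 1)) - 0.5))))
    add("univariate_auc", _stat_scorer(_safe(
        lambda x, y: abs(roc_auc_score(y, x) - 0.5) if len(np.unique(y)) > 1 else 0.0)))
    for a in (0.001, 0.01, 0.05, 0.1):
        add(f"lasso_a{a}", _abs_model_coef(Lasso(alpha=a, max_iter=5000)))
    for r in (0.3, 0.5, 0.7):
        add(f"elasticnet_r{r}", _abs_model_coef(ElasticNet(alpha=0.01, l1_ratio=r, max_iter=5000)))
    for a in (0.1, 1.0, 10.0):
        add(f"ridge_a{a}", _abs_model_coef(Ridge(alpha=a)))
    for C in (0.1, 1.0, 10.0):
        add(f"logreg_l1_C{C}", _abs_model_coef(
            LogisticRegression(penalty="l1", C=C, solver="liblinear", max_iter=2000)))
    for C in (0.1, 1.0, 10.0):
        add(f"linsvm_w_C{C}", _abs_model_coef(LinearSVC(C=C, max_iter=5000, dual="auto")))
    for n_est, depth in ((100, None), (200, None), (100, 5), (200, 5)):
        add(f"rf_imp_n{n_est}_d{depth}", _abs_model_coef(
            RandomForestClassifier(n_estimators=n_est, max_depth=depth, random_state=0)))
    for n_est in (100, 200):
        add(f"extratrees_imp_n{n_est}", _abs_model_coef(
            ExtraTreesClassifier(n_estimators=n_est, random_state=0)))
    add("gbm_imp", _abs_model_coef(GradientBoostingClassifier(random_state=0)))
    add("gbm_imp_lr0.05", _abs_model_coef(
        GradientBoostingClassifier(learning_rate=0.05, random_state=0)))
    add("logreg_l2_C1.0", _abs_model_coef(LogisticRegression(max_iter=2000)))
    add("variance", lambda X, y: X.to_numpy(dtype=float).var(axis=0))
    add("mad", lambda X, y: stats.median_abs_deviation(X.to_numpy(dtype=float), axis=0))
    add("iqr", lambda X, y: stats.iqr(X.to_numpy(dtype=float), axis=0))
    for frac in (0.5, 0.25):
        add(f"rfe_logreg_f{frac}", _make_rfe_scorer(
            LogisticRegression(max_iter=2000), frac))
    for frac in (0.5, 0.25):
        add(f"rfe_linsvm_f{frac}", _make_rfe_scorer(
            LinearSVC(max_iter=5000, dual="auto"), frac))
    reg = SelectorRegistry(e)
    assert len(reg) == 45, f"selector registry has {len(reg)} entries, expected 45"
    return reg


def _make_rfe_scorer(est, frac):
    def scorer(X, y):
        from sklearn.feature_selection import RFE

        n_keep = max(1, int(np.ceil(X.shape[1] * frac)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfe = RFE(clone(est), n_features_to_select=n_keep, step=0.2)
            rfe.fit(X.to_numpy(dtype=float), y)
        # higher score for earlier-kept features
        return 1.0 / rfe.ranking_
    return scorer


def default_classifier_registry() -> ClassifierRegistry:
    """32 named classifier entries built from ~12 base families."""
    e: dict[str, object] = {}
    for C in (0.01, 0.1, 1.0, 10.0):
        e[f"logreg_C{C}"] = LogisticRegression(C=C, max_iter=2000, class_weight="balanced")
    for C in (0.01, 0.1, 1.0, 10.0):
        e[f"linsvm_C{C}"] = SVC(kernel="linear", C=C, probability=False,
                                class_weight="balanced")
    for C, gamma in ((1.0, "scale"), (10.0, "scale"), (1.0, 0.01), (10.0, 0.1)):
        e[f"rbfsvm_C{C}_g{gamma}"] = SVC(kernel="rbf", C=C, gamma=gamma,
                                         class_weight="balanced")
    for k in (3, 5, 7, 11):
        e[f"knn_k{k}"] = KNeighborsClassifier(n_neighbors=k)
    for n_est in (100, 200, 500):
        e[f"rf_n{n_est}"] = RandomForestClassifier(
            n_estimators=n_est, random_state=0, class_weight="balanced")
    for n_est in (100, 200):
        e[f"extratrees_n{n_est}"] = ExtraTreesClassifier(
            n_estimators=n_est, random_state=0, class_weight="balanced")
    for lr in (0.1, 0.05):
        e[f"gbm_lr{lr}"] = GradientBoostingClassifier(learning_rate=lr, random_state=0)
    e["gaussian_nb"] = GaussianNB()
    e["lda"] = LinearDiscriminantAnalysis()
    e["qda"] = QuadraticDiscriminantAnalysis(reg_param=0.1)
    for depth in (3, 5, None):
        e[f"dtree_d{depth}"] = DecisionTreeClassifier(
            max_depth=depth, random_state=0, class_weight="balanced")
    e["xgboost"] = _xgb()
    e["lightgbm"] = _lgbm()
    e["mlp"] = MLPClassifier(hidden_layer_sizes=(32,), max_iter=500, random_state=0)
    reg = ClassifierRegistry(e)
    assert len(reg) == 32, f"classifier registry has {len(reg)} entries, expected 32"
    return reg


def _xgb():
    from xgboost import XGBClassifier

    return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.1,
                         eval_metric="logloss", random_state=0, verbosity=0)


def _lgbm():
    from lightgbm import LGBMClassifier

    return LGBMClassifier(n_estimators=100, max_depth=3, random_state=0, verbose=-1)


def enumerate_grid(selectors: SelectorRegistry, classifiers: ClassifierRegistry):
    """Full selector × classifier cross-product in stable registry order."""
    if len(selectors) == 0 or len(classifiers) == 0:
        raise ValueError("registries must be nonempty")
    return [(s, c) for s in selectors.names() for c in classifiers.names()]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    aucs: np.ndarray            # one AUC per replication
    mean_auc: float
    ci: tuple[float, float]     # percentile interval over replications
    roc_points: pd.DataFrame    # fpr, tpr of the first replication
    n_features: int

    @property
    def n_replications(self):
        return len(self.aucs)


def _scores(clf, X):
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def crossval_auc(selector, classifier, table, labels, folds: int = 5,
                 replications: int = 40, seed: int = 0,
                 n_features: int = 20, ci_level: float = 0.95) -> EvaluationReport:
    """Stratified repeated cross-validation of one selector/classifier pair.

    Within every training fold the features are min–max normalized and the
    selector is fitted on the training rows only (no leakage); the
    replication AUC pools the out-of-fold scores.  The confidence interval
    is the percentile interval of the replication AUC distribution.
    """
    X = _as_frame(table)
    y = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if np.bincount(y).min() < folds:
        raise ValueError("minority class smaller than fold count")
    aucs = []
    roc_pts = None
    used_features = n_features
    for rep in range(replications):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        oof = np.zeros(len(y))
        for tr, te in cv.split(X, y):
            Xtr, Xte = X.iloc[tr], X.iloc[te]
            lo, hi = Xtr.min(axis=0), Xtr.max(axis=0)
            span = (hi - lo).replace(0, 1.0)
            Xtr_n = (Xtr - lo) / span
            Xte_n = (Xte - lo) / span
            if selector is not None:
                cols = selector.select(Xtr_n, y[tr], n_features)
                used_features = len(cols)
                Xtr_n, Xte_n = Xtr_n[cols], Xte_n[cols]
            clf = clone(classifier)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr_n.to_numpy(dtype=float), y[tr])
                oof[te] = _scores(clf, Xte_n.to_numpy(dtype=float))
        aucs.append(roc_auc_score(y, oof))
        if rep == 0:
            fpr, tpr, _ = roc_curve(y, oof)
            roc_pts = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    aucs = np.array(aucs)
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha)))
    return EvaluationReport(aucs=aucs, mean_auc=float(aucs.mean()), ci=ci,
                            roc_points=roc_pts, n_features=used_features)


@dataclass
class GridResult:
    table: pd.DataFrame  # index selector, columns classifier, values mean AUC
    reports: dict[tuple[str, str], EvaluationReport]
    best: tuple[str, str]

    @property
    def best_auc(self) -> float:
        return float(self.table.loc[self.best[0], self.best[1]])


def run_grid(table, labels, selectors: SelectorRegistry,
             classifiers: ClassifierRegistry, folds: int = 5,
             replications: int = 5, seed: int = 0,
             n_features: int = 20) -> GridResult:
    """Evaluate every selector × classifier combination; best mean AUC wins.

    A combination that crashes is recorded as a missing cell (NaN) rather
    than aborting the grid.
    """
    combos = enumerate_grid(selectors, classifiers)
    mat = pd.DataFrame(np.nan, index=selectors.names(), columns=classifiers.names())
    reports = {}
    for sel_name, clf_name in combos:
        try:
            rep = crossval_auc(selectors[sel_name], classifiers[clf_name],
                               table, labels, folds=folds,
                               replications=replications, seed=seed,
                               n_features=n_features)
            mat.loc[sel_name, clf_name] = rep.mean_auc
            reports[(sel_name, clf_name)] = rep
        except Exception as exc:  # missing cell, not global failure
            warnings.warn(f"grid cell ({sel_name}, {clf_name}) failed: {exc}")
    if mat.isna().all().all():
        raise RuntimeError("every grid cell failed")
    flat = mat.stack()
    best = flat.idxmax()
    return GridResult(table=mat, reports=reports, best=tuple(best))


def confusion_metrics(predictions, labels, threshold: float = 0.5) -> dict:
    """Accuracy, sensitivity, specificity and the 2×2 confusion matrix.

    ``predictions`` may be scores (thresholded at ``threshold``) or hard
    0/1 calls.  Metrics with an empty denominator are returned as NaN.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=float)
    calls = (p >= threshold).astype(int)
    tp = int(((calls == 1) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": sens,
        "specificity": spec,
        "matrix": np.array([[tn, fp], [fn, tp]]),
    }


# ---------------------------------------------------------------------------
# propensity-score matching

DEFAULT_PSM_COVARIATES = (
    "original_shape_MeshVolume",
    "original_shape_SurfaceArea",
    "original_shape_Sphericity",
    "original_shape_Maximum3DDiameter",
    "original_firstorder_Mean",
    "original_firstorder_Entropy",
)


@dataclass
class PSMResult:
    matched_ids: list          # row labels, positives then their matches
    pairs: list[tuple]         # (positive id, negative id)
    smd_before: pd.Series
    smd_after: pd.Series


def _smd(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    a, b = X[y == 1], X[y == 0]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0).replace(0, 1.0)
    return (a.mean() - b.mean()).abs() / pooled


def psm_match(table, labels, covariate_names=DEFAULT_PSM_COVARIATES,
              caliper_sd: float = 0.2, seed: int = 0) -> PSMResult:
    """1:1 nearest-neighbor propensity matching without replacement.

    The propensity score is a logistic regression of the label on the six
    shape/first-order covariates; matching runs on the logit with a
    caliper of ``caliper_sd`` × SD(logit).  Returns equal-sized matched
    groups (smaller than the minority class if overlap is insufficient,
    with a warning) plus standardized mean differences before/after.
    """
    X = _as_frame(table)
    cov = [c for c in covariate_names if c in X.columns]
    if len(cov) < len(covariate_names):
        missing = set(covariate_names) - set(cov)
        raise ValueError(f"covariates missing from table: {sorted(missing)}")
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be nonempty")
    Z = X[cov].copy()
    Zs = (Z - Z.mean()) / Z.std(ddof=0).replace(0, 1.0)
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit(Zs.to_numpy(dtype=float), y)
    ps = np.clip(lr.predict_proba(Zs.to_numpy(dtype=float))[:, 1], 1e-9, 1 - 1e-9)
    logit = np.log(ps / (1 - ps))
    caliper = caliper_sd * logit.std(ddof=0)
    pos = np.where(y == 1)[0]
    neg = list(np.where(y == 0)[0])
    pairs = []
    # match positives in order of descending propensity (hardest first)
    for i in pos[np.argsort(-logit[pos], kind="stable")]:
        if not neg:
            break
        dists = np.abs(logit[neg] - logit[i])
        j = int(np.argmin(dists))
        if dists[j] <= caliper:
            pairs.append((i, neg.pop(j)))
    if len(pairs) < len(pos):
        warnings.warn(
            f"only {len(pairs)} of {len(pos)} positives matched within the "
            f"caliper ({caliper:.3f} logit units)")
    idx = X.index
    matched = [idx[i] for i, _ in pairs] + [idx[j] for _, j in pairs]
    keep = [i for pair in pairs for i in pair]
    smd_after = (_smd(X[cov].iloc[keep], y[keep])
                 if pairs else pd.Series(np.nan, index=cov))
    return PSMResult(matched_ids=matched,
                     pairs=[(idx[i], idx[j]) for i, j in pairs],
                     smd_before=_smd(X[cov], y), smd_after=smd_after)


# ---------------------------------------------------------------------------
# embedding and interval grouping

def embed_features(table, perplexity: float = 20.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of the (normalized) feature table."""
    from sklearn.manifold import TSNE

    X = _as_frame(table).to_numpy(dtype=float)
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs >= {int(3 * perplexity)} samples")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)


INTERVAL_GROUPS = {"A": (21, 91), "B": (91, 365), "C": (365, 730)}


def group_by_interval(manifest: pd.DataFrame, column: str = "interval_days") -> pd.Series:
    """Follow-up interval subgroup per subject: A [21, 91) d, B [91, 365) d,
    C [365, 730) d; intervals outside all groups are NaN (excluded)."""
    iv = manifest[column] if isinstance(manifest, pd.DataFrame) else pd.Series(manifest)
    out = pd.Series(pd.NA, index=iv.index, dtype="object")
    for name, (lo, hi) in INTERVAL_GROUPS.items():
        out[(iv >= lo) & (iv < hi)] = name
    return out
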