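"""Supervised odor-grade classification and quantification.

The modelling protocol mirrors standard chemometric practice on fingerprint
matrices:

* stratified 70/30 train/test split (every grade present on both sides);
* Gaussian-kernel SVM / SVR with an exponential grid search, log2 C and
  log2 sigma from -10 to 10 in 0.5 steps (41 x 41 = 1681 combinations),
  scored by 5-fold cross-validation; the kernel is
  ``k(x, x') = exp(-sigma * ||x - x'||^2)`` so sigma maps directly onto
  scikit-learn's ``gamma``;
* random forests as bagged decision trees with per-split feature
  subsampling (mtry = floor(sqrt(p)) for classification, floor(p/3) for
  regression), an ntree sweep from 2 to 100 in steps of 2, out-of-bag error,
  and per-tree out-of-bag permutation importances (the randomForest
  convention — robust to redundant markers, unlike whole-forest permutation);
* PLS regression with the component count chosen by 5-fold CV RMSE and
  variable importances from variance-weighted absolute component weights;
* metrics: accuracy and Cohen's kappa for classification; RMSE and R^2 for
  regression, with R^2 reported as the squared Pearson correlation between
  predicted and observed (the caret convention; the 1 - SSres/SStot form is
  reported alongside).

Feature reduction keeps channels whose relative permutation importance
exceeds a threshold (default 70 on the 0-100 scale) and refits on those
channels only; a per-channel one-way ANOVA across grades documents the
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .tis import TisMatrix

__all__ = [
    "SplitSpec",
    "SvmConfig",
    "RfConfig",
    "ModelResult",
    "Spectralprint",
    "split_data",
    "cv_folds",
    "tune_svm",
    "train_svm",
    "train_svr",
    "cohen_kappa",
    "rf_fit",
    "rf_sweep",
    "importance_reduce",
    "marker_anova",
    "pls_fit",
    "regression_metrics",
    "extract_spectralprint",
]


# --------------------------------------------------------------------------
# configuration containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _log2_grid() -> np.ndarray:
    return np.arange(-10, 10 + 0.25, 0.5)


@dataclass(frozen=True)
class SvmConfig:
    log2_C_grid: tuple = field(default_factory=lambda: tuple(_log2_grid()))
    log2_sigma_grid: tuple = field(default_factory=lambda: tuple(_log2_grid()))
    epsilon: float = 0.1  # SVR only

    @property
    def n_combinations(self) -> int:
        return len(self.log2_C_grid) * len(self.log2_sigma_grid)


@dataclass(frozen=True)
class RfConfig:
    ntree_grid: tuple = field(default_factory=lambda: tuple(range(2, 101, 2)))
    ntree_final: int = 100
    mtry: int | None = None  # None -> task default

    @staticmethod
    def mtry_default(p: int, task: str) -> tuple[float, int]:
        """(raw, integer) default predictors-per-split for p predictors."""
        raw = float(np.sqrt(p)) if task == "classify" else p / 3.0
        return raw, max(1, int(raw))


@dataclass
class ModelResult:
    """Fitted model with its hyperparameters, CV/test metrics and importances."""

    algorithm: str
    task: str
    hyperparameters: dict
    cv_metrics: dict
    test_metrics: dict = field(default_factory=dict)
    n_support_vectors: int | None = None
    oob_error: float | None = None
    importances: pd.Series | None = None  # 0-100 relative scale
    model: object | None = None
    feature_names: list | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_array(X, self.feature_names)
        return self.model.predict(X)

    def evaluate(self, X, y) -> dict:
        """Score on held-out data and store the result in ``test_metrics``."""
        pred = self.predict(X)
        y = np.asarray(y)
        if self.task == "classify":
            self.test_metrics = {
                "accuracy": float(np.mean(pred == y)),
                "kappa": cohen_kappa(pred, y),
            }
        else:
            rmse, r2 = regression_metrics(pred, y)
            self.test_metrics = {"rmse": rmse, "r2": r2}
        return self.test_metrics


def _as_array(X, feature_names=None):
    if isinstance(X, TisMatrix):
        df = X.values.T  # samples x channels
        if feature_names is not None:
            df = df[list(feature_names)]
        return df.to_numpy()
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            X = X[list(feature_names)]
        return X.to_numpy()
    return np.asarray(X, dtype=float)


# --------------------------------------------------------------------------
# splitting and folds
# --------------------------------------------------------------------------
def split_data(matrix: TisMatrix, labels, spec: SplitSpec = SplitSpec()):
    """Stratified train/test split of the sample columns.

    Per class, ``round(train_fraction * n_class)`` samples (round half up)
    go to training, so a 75-sample, 5-grade study splits 55/20 at 0.7.
    Returns ``(X_train, X_test, y_train, y_test)`` with X as DataFrames of
    samples by channels.
    """
    y = np.asarray(labels)
    X = matrix.values.T  # samples x channels
    if len(y) != len(X):
        raise ValueError("labels must match sample columns")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples")
        n_train = int(np.floor(spec.train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(rng.permutation(idx)[:n_train])
    train_mask = np.zeros(len(y), dtype=bool)
    train_mask[train_idx] = True
    return X[train_mask], X[~train_mask], y[train_mask], y[~train_mask]


def cv_folds(y, n_folds: int = 5, seed: int = 0):
    """Stratified, seed-fixed CV folds.

    Discrete labels (or discrete blend levels used as a response) are
    stratified; a genuinely continuous response falls back to shuffled
    unstratified folds.
    """
    y_str = np.asarray(y).astype(str)
    _, counts = np.unique(y_str, return_counts=True)
    if counts.min() >= n_folds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(len(y_str)), y_str))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(len(y_str))))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
def cohen_kappa(predicted, actual) -> float:
    """Unweighted Cohen's kappa, (p_o - p_e) / (1 - p_e)."""
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.size == 0 or pred.shape != act.shape:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    classes = np.unique(np.concatenate([pred, act]))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size))
    for p, a in zip(pred, act):
        cm[index[a], index[p]] += 1
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=0) * cm.sum(axis=1)).sum() / n**2)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def regression_metrics(predicted, actual) -> tuple[float, float]:
    """(RMSE, R^2) with R^2 as the squared Pearson correlation."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.size < 2 or pred.shape != act.shape:
        raise ValueError("need equal-length arrays of at least 2 values")
    rmse = float(np.sqrt(np.mean((pred - act) ** 2)))
    if np.std(act) == 0:
        raise ValueError("R^2 undefined for zero-variance actuals")
    if np.std(pred) == 0:
        return rmse, 0.0
    r = float(np.corrcoef(pred, act)[0, 1])
    return rmse, r * r


def r_squared_classic(predicted, actual) -> float:
    """1 - SSres/SStot, the alternative R^2 convention."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    ss_tot = float(((act - act.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance actuals")
    return 1.0 - float(((act - pred) ** 2).sum()) / ss_tot


# --------------------------------------------------------------------------
# Gaussian SVM / SVR
# --------------------------------------------------------------------------
def _make_svm(task: str, C: float, sigma: float, epsilon: float = 0.1):
    if C <= 0 or sigma <= 0:
        raise ValueError("C and sigma must be positive")
    if task == "classify":
        return SVC(C=C, kernel="rbf", gamma=sigma)
    return SVR(C=C, kernel="rbf", gamma=sigma, epsilon=epsilon)


def tune_svm(
    X, y, config: SvmConfig = SvmConfig(), task: str = "classify",
    seed: int = 0, n_folds: int = 5,
):
    """Exhaustive (C, sigma) grid search under stratified 5-fold CV.

    Classification maximizes CV accuracy; regression minimizes CV RMSE.
    Ties go to the smallest C, then the smallest sigma. Returns
    ``(best_C, best_sigma, surface)`` where ``surface`` is a DataFrame with
    one row per combination and the fold-averaged score.
    """
    X = _as_array(X)
    y = np.asarray(y)
    folds = cv_folds(y, n_folds, seed)
    for tr, te in folds:
        if task == "classify" and len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate fold: single-class training part")
    rows = []
    y_num = y.astype(float) if task == "regress" else y
    for log2_C in config.log2_C_grid:
        for log2_s in config.log2_sigma_grid:
            C, sigma = 2.0**log2_C, 2.0**log2_s
            scores = []
            for tr, te in folds:
                est = _make_svm(task, C, sigma, config.epsilon)
                est.fit(X[tr], y_num[tr])
                pred = est.predict(X[te])
                if task == "classify":
                    scores.append(np.mean(pred == y_num[te]))
                else:
                    scores.append(np.sqrt(np.mean((pred - y_num[te]) ** 2)))
            rows.append(
                {"log2_C": log2_C, "log2_sigma": log2_s, "C": C, "sigma": sigma,
                 "score": float(np.mean(scores))}
            )
    surface = pd.DataFrame(rows)
    ascending = task == "regress"  # RMSE: smaller is better
    ordered = surface.sort_values(
        ["score", "C", "sigma"], ascending=[ascending, True, True]
    )
    best = ordered.iloc[0]
    return float(best["C"]), float(best["sigma"]), surface


def _svm_cv_metrics(X, y, est_factory, task, folds):
    preds = np.empty(len(y), dtype=object)
    for tr, te in folds:
        est = est_factory()
        est.fit(X[tr], y[tr])
        preds[te] = est.predict(X[te])
    if task == "classify":
        pred = np.array([p for p in preds])
        return {"accuracy": float(np.mean(pred == y)), "kappa": cohen_kappa(pred, y)}
    pred = preds.astype(float)
    rmse, r2 = regression_metrics(pred, y.astype(float))
    return {"rmse": rmse, "r2": r2}


def train_svm(
    X, y, C: float, sigma: float, seed: int = 0, n_folds: int = 5,
    feature_names=None,
) -> ModelResult:
    """Fit the Gaussian SVM classifier at tuned (C, sigma), with CV metrics."""
    Xa = _as_array(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    folds = cv_folds(y, n_folds, seed)
    cv = _svm_cv_metrics(Xa, y, lambda: _make_svm("classify", C, sigma), "classify", folds)
    est = _make_svm("classify", C, sigma)
    est.fit(Xa, y)
    return ModelResult(
        algorithm="gaussian_svm", task="classify",
        hyperparameters={"C": C, "sigma": sigma},
        cv_metrics=cv, n_support_vectors=int(est.n_support_.sum()),
        model=est, feature_names=feature_names,
    )


def train_svr(
    X, y, C: float, sigma: float, epsilon: float = 0.1, seed: int = 0,
    n_folds: int = 5, feature_names=None,
) -> ModelResult:
    """Fit the Gaussian SVR at tuned (C, sigma) with the fixed epsilon tube."""
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float)
    folds = cv_folds(y, n_folds, seed)
    cv = _svm_cv_metrics(
        Xa, y, lambda: _make_svm("regress", C, sigma, epsilon), "regress", folds
    )
    est = _make_svm("regress", C, sigma, epsilon)
    est.fit(Xa, y)
    return ModelResult(
        algorithm="gaussian_svr", task="regress",
        hyperparameters={"C": C, "sigma": sigma, "epsilon": epsilon},
        cv_metrics=cv, n_support_vectors=int(est.support_.size),
        model=est, feature_names=feature_names,
    )


# --------------------------------------------------------------------------
# random forest (bagged trees with per-split feature subsampling)
# --------------------------------------------------------------------------
def _make_forest(task: str, mtry: int, ntree: int, seed: int):
    if task == "classify":
        base = DecisionTreeClassifier(max_features=mtry)
        return BaggingClassifier(
            estimator=base, n_estimators=ntree, bootstrap=True, random_state=seed
        )
    base = DecisionTreeRegressor(max_features=mtry)
    return BaggingRegressor(
        estimator=base, n_estimators=ntree, bootstrap=True, random_state=seed
    )


def _tree_predict(forest, est, X, task: str):
    """Predict with one bagged tree in the original label space."""
    pred = est.predict(X)
    if task == "classify":
        # Bagging trains its trees on integer-encoded labels
        return forest.classes_[pred.astype(int)]
    return pred


def _oob_error(forest, X, y, task: str) -> float:
    """Out-of-bag error (misclassification rate or MSE) by vote aggregation."""
    n = len(y)
    if task == "classify":
        classes = forest.classes_
        votes = np.zeros((n, classes.size))
        lut = {c: i for i, c in enumerate(classes)}
        for est, samples in zip(forest.estimators_, forest.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), samples)
            if oob.size == 0:
                continue
            pred = _tree_predict(forest, est, X[oob], task)
            for i, p in zip(oob, pred):
                votes[i, lut[p]] += 1
        covered = votes.sum(axis=1) > 0
        pred_cls = classes[np.argmax(votes[covered], axis=1)]
        return float(np.mean(pred_cls != y[covered]))
    sums = np.zeros(n)
    counts = np.zeros(n)
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if oob.size == 0:
            continue
        sums[oob] += est.predict(X[oob])
        counts[oob] += 1
    covered = counts > 0
    pred = sums[covered] / counts[covered]
    return float(np.mean((pred - y[covered]) ** 2))


def _oob_permutation_importance(
    forest, X, y, task: str, seed: int, n_repeats: int = 5
) -> np.ndarray:
    """Per-tree OOB permutation importance, SE-normalized over trees.

    For each tree: error on its out-of-bag samples, then again with one
    feature's OOB values permuted (averaged over ``n_repeats`` draws to
    stabilize small OOB sets); a feature's raw importance is the mean error
    increase across trees divided by its standard error — the mean-decrease-
    accuracy convention of classical random-forest implementations. Features
    a tree never splits on contribute an exact zero for that tree.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    ntree = len(forest.estimators_)
    deltas = np.zeros((ntree, p))
    for t, (est, samples) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), samples)
        if oob.size < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        pred = _tree_predict(forest, est, Xo, task)
        if task == "classify":
            base_err = np.mean(pred != yo)
        else:
            base_err = np.mean((pred - yo) ** 2)
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        for j in used:
            acc = 0.0
            for _ in range(n_repeats):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                pred_p = _tree_predict(forest, est, Xp, task)
                if task == "classify":
                    acc += np.mean(pred_p != yo) - base_err
                else:
                    acc += np.mean((pred_p - yo) ** 2) - base_err
            deltas[t, j] = acc / n_repeats
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(ntree)
    return np.divide(mean, se, out=mean.copy(), where=se > 0)


def _scale_importance(raw: np.ndarray) -> np.ndarray:
    """Min-max scale to 0-100 (the caret varImp convention)."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    scaled = 100.0 * (raw - lo) / (hi - lo)
    scaled[np.argmax(raw)] = 100.0  # guard against rounding at the top
    return scaled


def rf_fit(
    X, y, config: RfConfig = RfConfig(), task: str = "classify",
    seed: int = 0, n_folds: int = 5, feature_names=None,
) -> ModelResult:
    """Fit the final forest at ntree_final with OOB error and importances."""
    Xa = _as_array(X)
    if isinstance(X, pd.DataFrame) and feature_names is None:
        feature_names = list(X.columns)
    y = np.asarray(y)
    p = Xa.shape[1]
    mtry_raw, mtry = RfConfig.mtry_default(p, task)
    if config.mtry is not None:
        mtry = config.mtry
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds {p} predictors")
    y_num = y.astype(float) if task == "regress" else y
    folds = cv_folds(y, n_folds, seed)
    # CV metrics at the final forest size
    preds = np.empty(len(y), dtype=object)
    for k, (tr, te) in enumerate(folds):
        forest = _make_forest(task, mtry, config.ntree_final, seed + 1000 + k)
        forest.fit(Xa[tr], y_num[tr])
        preds[te] = forest.predict(Xa[te])
    if task == "classify":
        pred = np.array(list(preds))
        cv = {"accuracy": float(np.mean(pred == y_num)), "kappa": cohen_kappa(pred, y_num)}
    else:
        rmse, r2 = regression_metrics(preds.astype(float), y_num)
        cv = {"rmse": rmse, "r2": r2}
    forest = _make_forest(task, mtry, config.ntree_final, seed)
    forest.fit(Xa, y_num)
    oob = _oob_error(forest, Xa, y_num, task)
    raw_imp = _oob_permutation_importance(forest, Xa, y_num, task, seed)
    index = feature_names if feature_names is not None else np.arange(p)
    importances = pd.Series(_scale_importance(raw_imp), index=index)
    return ModelResult(
        algorithm="random_forest", task=task,
        hyperparameters={
            "mtry": mtry, "mtry_raw": mtry_raw, "ntree": config.ntree_final
        },
        cv_metrics=cv, oob_error=oob, importances=importances,
        model=forest, feature_names=feature_names,
    )


def rf_sweep(
    X, y, config: RfConfig = RfConfig(), task: str = "classify",
    seed: int = 0, n_folds: int = 5,
) -> pd.DataFrame:
    """CV metric versus forest size over the ntree grid (stability curve)."""
    Xa = _as_array(X)
    y = np.asarray(y)
    y_num = y.astype(float) if task == "regress" else y
    p = Xa.shape[1]
    _, mtry = RfConfig.mtry_default(p, task)
    if config.mtry is not None:
        mtry = config.mtry
    folds = cv_folds(y, n_folds, seed)
    rows = []
    for ntree in config.ntree_grid:
        scores = []
        for k, (tr, te) in enumerate(folds):
            forest = _make_forest(task, mtry, int(ntree), seed + 1000 + k)
            forest.fit(Xa[tr], y_num[tr])
            pred = forest.predict(Xa[te])
            if task == "classify":
                scores.append(np.mean(pred == y_num[te]))
            else:
                scores.append(np.sqrt(np.mean((pred - y_num[te]) ** 2)))
        rows.append({"ntree": int(ntree), "score": float(np.mean(scores))})
    return pd.DataFrame(rows)


def importance_reduce(result: ModelResult, threshold: float = 70.0, top_k: int = 8):
    """Channels whose relative importance exceeds ``threshold`` (0-100 scale).

    Falls back (with a warning) to the ``top_k`` highest-ranked channels if
    the threshold selects nothing.
    """
    if result.importances is None:
        raise ValueError("model result carries no importances")
    imp = result.importances
    selected = list(imp.index[imp > threshold])
    if not selected:
        warnings.warn(
            f"no channel above importance {threshold}; falling back to top {top_k}",
            stacklevel=2,
        )
        selected = list(imp.sort_values(ascending=False).index[:top_k])
    return sorted(selected)


def marker_anova(X: pd.DataFrame, labels, mz_set) -> pd.DataFrame:
    """Per-channel one-way ANOVA across the grade groups for selected channels."""
    y = np.asarray(labels)
    rows = []
    for mz in mz_set:
        groups = [X[mz].to_numpy()[y == g] for g in np.unique(y)]
        f, p = stats.f_oneway(*groups)
        rows.append({"mz": mz, "f": float(f), "p": float(p)})
    return pd.DataFrame(rows).set_index("mz")


# --------------------------------------------------------------------------
# PLS regression
# --------------------------------------------------------------------------
def pls_fit(
    X, y, max_components: int = 10, seed: int = 0, n_folds: int = 5,
    feature_names=None,
) -> ModelResult:
    """PLS regression with the component count minimizing 5-fold CV RMSE.

    Importances are variance-weighted sums of absolute component weights
    (each component's |weights| scaled by the response variance it explains),
    min-max scaled to 0-100.
    """
    Xa = _as_array(X)
    if isinstance(X, pd.DataFrame) and feature_names is None:
        feature_names = list(X.columns)
    y = np.asarray(y, dtype=float)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rank = min(Xa.shape[0] - 1, Xa.shape[1])
    if max_components > rank:
        raise ValueError(f"max_components exceeds the data rank ({rank})")
    folds = cv_folds(y, n_folds, seed)
    curve = []
    for a in range(1, max_components + 1):
        errs = []
        for tr, te in folds:
            pls = PLSRegression(n_components=a, scale=False)
            pls.fit(Xa[tr], y[tr])
            pred = pls.predict(Xa[te]).ravel()
            errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
        curve.append({"n_components": a, "cv_rmse": float(np.mean(errs))})
    curve = pd.DataFrame(curve)
    best_a = int(curve.loc[curve["cv_rmse"].idxmin(), "n_components"])
    # CV metrics at the chosen size
    preds = np.empty(len(y))
    for tr, te in folds:
        pls = PLSRegression(n_components=best_a, scale=False)
        pls.fit(Xa[tr], y[tr])
        preds[te] = pls.predict(Xa[te]).ravel()
    rmse, r2 = regression_metrics(preds, y)
    pls = PLSRegression(n_components=best_a, scale=False)
    pls.fit(Xa, y)
    # variance explained per component
    x_scores = pls.x_scores_
    Xc = Xa - Xa.mean(axis=0)
    yc = y - y.mean()
    x_var = np.array(
        [np.sum((np.outer(x_scores[:, a], pls.x_loadings_[:, a])) ** 2)
         for a in range(best_a)]
    ) / np.sum(Xc**2)
    y_var = np.array(
        [np.sum((x_scores[:, a] * pls.y_loadings_[0, a]) ** 2) for a in range(best_a)]
    ) / np.sum(yc**2)
    raw_imp = (np.abs(pls.x_weights_[:, :best_a]) * y_var).sum(axis=1)
    index = feature_names if feature_names is not None else np.arange(Xa.shape[1])
    importances = pd.Series(_scale_importance(raw_imp), index=index)
    result = ModelResult(
        algorithm="plsr", task="regress",
        hyperparameters={"n_components": best_a},
        cv_metrics={"rmse": rmse, "r2": r2},
        importances=importances, model=pls, feature_names=feature_names,
    )
    result.hyperparameters["x_variance_explained_pct"] = float(x_var.sum() * 100)
    result.hyperparameters["y_variance_explained_pct"] = float(y_var.sum() * 100)
    result.cv_metrics["curve"] = curve
    return result


# --------------------------------------------------------------------------
# spectralprints
# --------------------------------------------------------------------------
@dataclass
class Spectralprint:
    """Per-grade mean normalized intensities at the reduced marker channels."""

    mz_set: list[int]
    table: pd.DataFrame  # grades x mz, renormalized to per-grade maximum

    def argmax_channel(self, grade) -> int:
        return int(self.table.loc[grade].idxmax())


def extract_spectralprint(matrix: TisMatrix, mz_set, grade_labels) -> Spectralprint:
    """Grade-wise mean fingerprint at selected channels, per-grade max = 1."""
    mz_set = sorted(int(m) for m in mz_set)
    missing = set(mz_set) - set(matrix.mz_axis.tolist())
    if missing:
        raise ValueError(f"channels not on the m/z axis: {sorted(missing)}")
    y = np.asarray(grade_labels)
    if len(y) != matrix.values.shape[1]:
        raise ValueError("grade_labels must match sample columns")
    X = matrix.values.T[mz_set]  # samples x selected channels
    rows = {}
    for grade in pd.unique(y):
        means = X[y == grade].mean(axis=0)
        peak = means.max()
        if peak <= 0:
            raise ValueError(f"grade {grade!r} has an all-zero mean fingerprint")
        rows[grade] = means / peak
    table = pd.DataFrame(rows).T
    table.columns = mz_set
    return Spectralprint(mz_set=mz_set, table=table)
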