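"""Class-weighted RBF-SVM classification under nested LOOCV.

The estimation protocol mirrors small-cohort radiomics practice:

* outer leave-one-out loop for unbiased error assessment;
* inner leave-one-out grid search over (C, gamma) on each training fold,
  ties broken toward the smallest C then smallest gamma;
* per-class weighting of the soft-margin penalty (C * n / (2 * n_i)) to
  handle class imbalance;
* feature standardisation with training-fold statistics only;
* Platt scaling of decision values into posterior probabilities, fitted
  on out-of-sample decision values from an internal stratified 3-fold
  split of the training fold.

The statistics layer provides ROC/AUC with the rank (Mann-Whitney) tie
convention, DeLong's test for paired ROC curves, and the usual group
tests (Shapiro-Wilk, one-way ANOVA, Kruskal-Wallis, chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:  # fast path for the thousands of tiny LOO fits (same solver as SVC)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - depends on sklearn internals
    _libsvm = None

__all__ = [
    "SvmConfig",
    "CvRun",
    "RocResult",
    "RocComparison",
    "PlattCalibration",
    "train_weighted_svm",
    "platt_calibrate",
    "nested_loocv",
    "anova_filtered_loocv",
    "roc_auc",
    "compare_auc_paired",
    "group_tests",
    "standardize_train_test",
    "balanced_class_weights",
]

#: libsvm-style log2 default grids.
DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**p for p in range(-15, 4, 2))

#: Compact grid for simulation studies where the full grid is overkill.
SMALL_C_GRID = (2.0**-3, 1.0, 2.0**3, 2.0**6, 2.0**9)
SMALL_GAMMA_GRID = (2.0**-7, 2.0**-5, 2.0**-3, 2.0**-1, 2.0)


@dataclass
class SvmConfig:
    """Hyperparameters of the class-weighted RBF-SVM search."""

    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    class_weight: object = "balanced"  # n / (2 * n_i)
    platt: bool = True
    seed: int = 0

    def __post_init__(self):
        self.c_grid = tuple(sorted(float(c) for c in self.c_grid))
        self.gamma_grid = tuple(sorted(float(g) for g in self.gamma_grid))
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.c_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("C and gamma must be positive")


def balanced_class_weights(y) -> dict:
    """Inverse-frequency weights w_i = n / (2 * n_i) for binary labels."""
    y = np.asarray(y)
    n = y.size
    return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}


def standardize_train_test(X_train, X_test=None):
    """Z-score features with training statistics; zero-variance features
    are left centred (scale guard -> SD 1)."""
    X_train = np.asarray(X_train, dtype=float)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xt = (X_train - mu) / sd
    if X_test is None:
        return Xt
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    return Xt, (X_test - mu) / sd


def train_weighted_svm(X, y, c: float, gamma: float, class_weights=None, tol: float = 1e-6) -> SVC:
    """Fit a class-weighted soft-margin RBF-SVM.

    ``class_weights`` may be a dict, "balanced", or None; class i's
    misclassification penalty is C * w_i.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(C=c, gamma=gamma, kernel="rbf", class_weight=class_weights, tol=tol)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


# ---------------------------------------------------------------------------
# Platt scaling


@dataclass
class PlattCalibration:
    """Sigmoid P(y=1|f) = 1 / (1 + exp(A*f + B))."""

    a: float
    b: float

    def __call__(self, decision_values):
        f = np.asarray(decision_values, dtype=float)
        z = self.a * f + self.b
        # numerically stable logistic
        out = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        return out if out.ndim else float(out)


def platt_calibrate(decision_values, labels) -> PlattCalibration:
    """Fit Platt's sigmoid by regularised maximum likelihood.

    Uses Platt's target smoothing (t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2)) and the Newton iteration with backtracking of
    Lin, Weng & Keerthi (2007), which is robust to separable inputs.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if f.ndim != 1 or f.size != y.size:
        raise ValueError("decision_values and labels must be 1D and aligned")
    if np.ptp(f) == 0:
        raise ValueError("degenerate (all-identical) decision values")
    prior1 = float(np.sum(y == 1))
    prior0 = float(np.sum(y == 0))
    if prior0 == 0 or prior1 == 0:
        raise ValueError("both classes must be present")

    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)

    a, b = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))

    def objective(a_, b_):
        z = a_ * f + b_
        # sum of t*z + log(1+exp(-z)), stable for both signs of z
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1.0) * z + np.log1p(np.exp(z)))))

    fval = objective(a, b)
    min_step, sigma = 1e-10, 1e-12
    for _ in range(100):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        d1 = t - p
        d2 = p * (1.0 - p)
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= min_step:
            new_f = objective(a + step * da, b + step * db)
            if new_f < fval + 1e-4 * step * gd:
                a, b = a + step * da, b + step * db
                fval = new_f
                break
            step /= 2.0
        else:
            break
    return PlattCalibration(a=a, b=b)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]


def _rank_auc(scores, labels) -> float:
    """AUC by the Mann-Whitney rank formulation (ties get half credit)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(probabilities, labels, threshold: float = 0.5) -> RocResult:
    """ROC curve, AUC, and the operating point at the given threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    auc = _rank_auc(p, y)
    fpr, tpr, thr = roc_curve(y, p, drop_intermediate=False)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / y.size
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def compare_auc_paired(scores_a, scores_b, labels) -> RocComparison:
    """DeLong's test for two correlated ROC curves on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if not (a.size == b.size == y.size):
        raise ValueError("scores and labels must have equal length")
    pos = y == 1
    neg = y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((a, b)):
        x, yv = s[pos], s[neg]
        rx = _midrank(x)
        ry = _midrank(yv)
        rall = _midrank(np.concatenate([x, yv]))
        aucs[k] = (rall[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[k] = (rall[:m] - rx) / n
        v01[k] = 1.0 - (rall[m:] - ry) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = aucs[0] - aucs[1]
    if var <= 1e-16:
        z = 0.0 if abs(delta) < 1e-12 else np.inf * np.sign(delta)
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return RocComparison(auc_a=float(aucs[0]), auc_b=float(aucs[1]), delta=float(delta), z=float(z), p_value=max(p, np.finfo(float).tiny))


def group_tests(groups, contingency=None) -> dict:
    """Standard group-comparison tests.

    Parameters
    ----------
    groups : sequence of 1D arrays
        Continuous values per group (>= 2 groups of >= 2 values).
    contingency : 2D array, optional
        Counts for a chi-square test of independence.

    Returns a dict with ``shapiro_p`` (per group), ``anova_p``,
    ``kruskal_p`` and, when a table is given, ``chi2_p``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    shapiro_p = []
    for g in groups:
        if np.ptp(g) == 0:
            shapiro_p.append(float("nan"))
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    out = {
        "shapiro_p": shapiro_p,
        "anova_p": float(sps.f_oneway(*groups).pvalue),
        "kruskal_p": float(sps.kruskal(*groups).pvalue),
    }
    if contingency is not None:
        out["chi2_p"] = float(sps.chi2_contingency(np.asarray(contingency)).pvalue)
    return out


# ---------------------------------------------------------------------------
# Nested LOOCV


@dataclass
class CvRun:
    """Record of one nested-LOOCV experiment."""

    subject_ids: list
    y_true: np.ndarray
    probabilities: np.ndarray
    decision_values: np.ndarray
    predicted: np.ndarray
    params: list  # per outer fold (C, gamma)
    selected_features: list  # per outer fold, or None entries
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    auc: float = field(init=False)
    roc: RocResult = field(init=False)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=int)
        self.roc = roc_auc(self.probabilities, self.y_true)
        self.auc = self.roc.auc
        self.accuracy = float(np.mean(self.predicted == self.y_true))
        tp = int(np.sum((self.predicted == 1) & (self.y_true == 1)))
        tn = int(np.sum((self.predicted == 0) & (self.y_true == 0)))
        fn = int(np.sum((self.predicted == 0) & (self.y_true == 1)))
        fp = int(np.sum((self.predicted == 1) & (self.y_true == 0)))
        self.sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        self.specificity = tn / (tn + fp) if tn + fp else float("nan")
        self.confusion = np.array([[tn, fp], [fn, tp]])

    @property
    def n_folds(self) -> int:
        return len(self.y_true)


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    return d2


def _weight_array(y, class_weight):
    """Per-label penalty multipliers as the array libsvm expects."""
    if class_weight is None:
        return np.ones(2)
    if class_weight == "balanced":
        w = balanced_class_weights(y)
    else:
        w = dict(class_weight)
    return np.array([float(w.get(0, 1.0)), float(w.get(1, 1.0))])


def fit_svm_precomputed(K, y, c: float, class_weight="balanced"):
    """Fit a weighted SVC on a precomputed kernel; returns (model, predict).

    ``model`` is ``(dual_coef, support, intercept)`` with ``dual_coef``
    the signed alpha_i*y_i over support vectors; ``predict`` maps kernel
    rows (columns over the full training set) to labels.  Uses the
    libsvm low-level interface when available, else :class:`SVC`.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if _libsvm is not None:
        out = _libsvm.fit(
            K,
            y.astype(np.float64),
            svm_type=0,
            kernel="precomputed",
            C=float(c),
            class_weight=_weight_array(y, class_weight),
        )
        support, sv, n_sv, coef, intercept = out[:5]

        def predict(rows):
            rows = np.ascontiguousarray(np.atleast_2d(rows), dtype=np.float64)
            return _libsvm.predict(
                rows, support, sv, n_sv, coef, intercept, svm_type=0, kernel="precomputed"
            ).astype(int)

        return (coef[0], support.astype(int), float(intercept[0])), predict

    clf = SVC(C=c, kernel="precomputed", class_weight=class_weight)
    clf.fit(K, y)

    def predict(rows):
        return clf.predict(np.atleast_2d(rows)).astype(int)

    return (clf.dual_coef_[0], clf.support_.astype(int), float(clf.intercept_[0])), predict


def _fold_weights(y_train, class_weight):
    """Resolve the class-weight setting ONCE per training fold.

    The weights are computed from the training-fold labels and then held
    fixed for every fit inside that fold (inner LOO, calibration splits,
    final refit).  Recomputing "balanced" weights inside each inner
    leave-one-out fit would make the decision bias track the one-subject
    composition change, which leaks the inner held-out label into the
    grid search on otherwise uninformative data.
    """
    if class_weight == "balanced":
        return balanced_class_weights(y_train)
    return class_weight


def _inner_loo_grid_search(Xs, y, config: SvmConfig, weights=None):
    """Inner LOOCV accuracy over the (C, gamma) grid on standardized
    training data; returns the accuracy-maximising pair, ties broken
    toward smallest C then smallest gamma."""
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("inner LOOCV needs >= 2 subjects per class")
    if weights is None:
        weights = _fold_weights(y, config.class_weight)
    d2 = _pairwise_sq_dists(Xs)
    acc = np.zeros((len(config.c_grid), len(config.gamma_grid)))
    idx = np.arange(n)
    folds = [(idx[idx != j], j) for j in range(n)]
    for gi, g in enumerate(config.gamma_grid):
        K = np.exp(-g * d2)
        sub_K = [np.ascontiguousarray(K[np.ix_(tr, tr)]) for tr, _ in folds]
        sub_rows = [np.ascontiguousarray(K[j, tr][None, :]) for tr, j in folds]
        for ci, c in enumerate(config.c_grid):
            correct = 0
            for (tr, j), Ktr, row in zip(folds, sub_K, sub_rows):
                _, predict = fit_svm_precomputed(Ktr, y[tr], c, weights)
                correct += int(predict(row)[0] == y[j])
            acc[ci, gi] = correct / n
    best_acc, best = -1.0, None
    for ci, c in enumerate(config.c_grid):
        for gi, g in enumerate(config.gamma_grid):
            if acc[ci, gi] > best_acc:
                best_acc, best = acc[ci, gi], (c, g)
    return best, best_acc


def _oos_decision_values(Xs, y, c, g, weights, seed: int):
    """Out-of-sample decision values on the training fold via an internal
    stratified 3-fold split (for honest Platt calibration)."""
    counts = np.bincount(y, minlength=2)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        clf = train_weighted_svm(Xs, y, c, g, weights)
        return clf.decision_function(Xs)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31 - 1))
    f = np.empty(len(y))
    for tr, te in skf.split(Xs, y):
        clf = train_weighted_svm(Xs[tr], y[tr], c, g, weights)
        f[te] = clf.decision_function(Xs[te])
    return f


def _fit_fold(X_tr, y_tr, x_te, config: SvmConfig, seed: int):
    """One outer fold: tune, calibrate, refit, score the held-out row."""
    weights = _fold_weights(y_tr, config.class_weight)
    Xs, xs_te = standardize_train_test(X_tr, x_te)
    (c, g), _ = _inner_loo_grid_search(Xs, y_tr, config, weights)
    clf = train_weighted_svm(Xs, y_tr, c, g, weights)
    f_te = float(clf.decision_function(xs_te)[0])
    if config.platt:
        f_oos = _oos_decision_values(Xs, y_tr, c, g, weights, seed)
        try:
            cal = platt_calibrate(f_oos, y_tr)
            p_te = float(cal(f_te))
        except ValueError:  # degenerate decision values
            p_te = 1.0 if f_te > 0 else 0.0
    else:
        p_te = f_te
    pred = int(p_te >= 0.5) if config.platt else int(f_te > 0)
    return (c, g), f_te, p_te, pred


def nested_loocv(X, y, config: SvmConfig = None, feature_subset=None, subject_ids=None) -> CvRun:
    """Nested leave-one-out cross-validation of the weighted RBF-SVM.

    Each subject is held out once; hyperparameters are chosen by inner
    LOOCV on the remaining subjects; no statistic (scaling, tuning,
    calibration) sees the held-out subject.

    Parameters
    ----------
    X : (n, p) feature matrix
    y : (n,) binary labels in {0, 1}
    feature_subset : optional sequence of 0-based column indices
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("nested LOOCV needs n >= 4")
    if feature_subset is not None:
        feature_subset = list(feature_subset)
        if any(i < 0 or i >= X.shape[1] for i in feature_subset):
            raise ValueError("invalid feature subset")
        X = X[:, feature_subset]
    if subject_ids is None:
        subject_ids = list(range(n))

    params, decs, probs, preds = [], [], [], []
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            raise ValueError("a class is absent from a training fold")
        pr, f_te, p_te, pred = _fit_fold(X[tr], y[tr], X[i], config, seed=config.seed + i)
        params.append(pr)
        decs.append(f_te)
        probs.append(p_te)
        preds.append(pred)
    return CvRun(
        subject_ids=list(subject_ids),
        y_true=y,
        probabilities=np.array(probs),
        decision_values=np.array(decs),
        predicted=np.array(preds),
        params=params,
        selected_features=[feature_subset] * n if feature_subset is not None else [None] * n,
    )


FIRST_ORDER_FEATURE_NAMES = ("mean", "median", "sd", "kurtosis", "p5", "p95")


def anova_filtered_loocv(X, y, config: SvmConfig = None, feature_names=FIRST_ORDER_FEATURE_NAMES):
    """LOOCV with a per-fold one-way ANOVA feature filter (p < 0.05).

    Designed for the six first-order MDK statistics, but accepts any
    feature matrix.  In each outer fold, features whose between-class
    ANOVA p-value on the training subjects is below 0.05 are kept (if
    none passes, the single smallest-p feature is used); tuning and
    evaluation then proceed as in :func:`nested_loocv`.

    Returns
    -------
    (CvRun, per_fold_selected, consistent)
        ``per_fold_selected`` is a list of name tuples; ``consistent``
        the set of features selected in every fold.
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if len(feature_names) != p:
        raise ValueError("feature_names must match the number of columns")

    params, decs, probs, preds, selected = [], [], [], [], []
    for i in range(n):
        tr = np.arange(n) != i
        ytr = y[tr]
        pvals = np.array(
            [sps.f_oneway(X[tr][ytr == 0, j], X[tr][ytr == 1, j]).pvalue for j in range(p)]
        )
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        keep = np.flatnonzero(pvals < 0.05)
        if keep.size == 0:
            keep = np.array([int(np.argmin(pvals))])
        pr, f_te, p_te, pred = _fit_fold(
            X[tr][:, keep], ytr, X[i, keep], config, seed=config.seed + i
        )
        params.append(pr)
        decs.append(f_te)
        probs.append(p_te)
        preds.append(pred)
        selected.append(tuple(feature_names[j] for j in keep))
    run = CvRun(
        subject_ids=list(range(n)),
        y_true=y,
        probabilities=np.array(probs),
        decision_values=np.array(decs),
        predicted=np.array(preds),
        params=params,
        selected_features=selected,
    )
    consistent = set(selected[0])
    for s in selected[1:]:
        consistent &= set(s)
    return run, selected, consistent
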