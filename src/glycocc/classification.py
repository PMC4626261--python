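"""Penalized logistic classification of disease status from glycan peaks.

The classifier minimizes

    (1/n) * neg-log-likelihood + lambda * [ (1-alpha)/2 ||b||^2 + alpha ||b||_1 ]

over the non-intercept coefficients, with predictors standardized
internally, so ``lambda`` is portable across implementations.  ``alpha=0``
is pure ridge (the tuned configuration, lambda = 0.1) and is solved by
Newton iteration in-package; ``alpha>0`` delegates to the saga coordinate
solver.  Performance is always assessed on merged out-of-fold predictions:
a seeded stratified k-fold partition, preprocessing statistics computed on
training folds only, and one ROC/AUC per model over the concatenated
held-out predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from ._errors import DesignError, StratificationError
from .association import newton_logistic


@dataclass(frozen=True)
class ClassifierConfig:
    """Elastic-net configuration: mixing alpha in [0,1], penalty lambda > 0."""

    alpha: float = 0.0
    lam: float = 0.1
    standardize: bool = True
    penalize_covariates: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


@dataclass
class PenalizedLogisticModel:
    """Fitted penalized logistic model (coefficients on the standardized scale)."""

    intercept: float
    coef: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    config: ClassifierConfig
    feature_names: list[str] = field(default_factory=list)

    def decision_function(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return self.intercept + Z @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.decision_function(X))


def fit_penalized_logistic(
    X, y, config: ClassifierConfig, penalize: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> PenalizedLogisticModel:
    """Fit the elastic-net logistic objective; intercept unpenalized.

    ``penalize`` optionally marks which columns receive the penalty
    (default: all non-intercept columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise DesignError("single-class outcome: nothing to classify")
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            idx = int(np.nonzero(sd == 0)[0][0])
            label = feature_names[idx] if feature_names else f"column {idx}"
            raise DesignError(f"constant feature {label!r} cannot be standardized")
    else:
        mu = np.zeros(p)
        sd = np.ones(p)
    Z = (X - mu) / sd
    pen_mask = np.ones(p, dtype=bool) if penalize is None else np.asarray(penalize, bool)

    if config.alpha == 0.0:
        # Newton on (1/n) NLL + lam/2 ||b||^2 <=> NLL + n*lam/2 ||b||^2
        D = np.column_stack([np.ones(n), Z])
        mask = np.concatenate([[False], pen_mask])
        beta, _ = newton_logistic(
            D, y, ridge=n * config.lam, penalize=mask,
            max_iter=200, tol_score=1e-10,
        )
        intercept, coef = float(beta[0]), beta[1:]
    else:
        if not np.all(pen_mask):
            raise NotImplementedError(
                "partial penalization is only supported for alpha = 0"
            )
        if config.lam == 0:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        else:
            clf = LogisticRegression(
                solver="saga", l1_ratio=config.alpha,
                C=1.0 / (n * config.lam), max_iter=20000, tol=1e-8,
            )
        clf.fit(Z, y)
        intercept, coef = float(clf.intercept_[0]), clf.coef_[0]

    return PenalizedLogisticModel(
        intercept=intercept, coef=np.asarray(coef, dtype=float),
        feature_means=mu, feature_sds=sd, config=config,
        feature_names=list(feature_names or []),
    )


def elastic_net_objective(intercept, coef, Z, y, alpha, lam, pen_mask=None):
    """The (1/n)-scaled penalized objective, for diagnostics and oracles."""
    n = len(y)
    eta = intercept + Z @ coef
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) / n
    b = coef if pen_mask is None else coef[pen_mask]
    return nll + lam * ((1 - alpha) / 2 * float(b @ b) + alpha * float(np.abs(b).sum()))


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve and Mann-Whitney AUC (ties counted 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == "case").astype(int)
    y = y.astype(int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise DesignError("need both classes to compute a ROC curve")
    ranks = stats.rankdata(s, method="average")
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCCurve(fpr, tpr, thr), float(auc)


@dataclass
class CVResult:
    """Merged out-of-fold evaluation of one model over a k-fold partition."""

    model_name: str
    fold_assignment: np.ndarray
    predictions: np.ndarray
    roc: ROCCurve
    auc: float
    config: ClassifierConfig
    coefficients: list = field(default_factory=list)


def _check_partition(y, folds, k):
    for tr, te in folds:
        if np.unique(y[tr]).size < 2:
            raise StratificationError("a training fold lost one class")


def cross_validate_merged(
    X_glycans,
    age,
    sex,
    y,
    config: ClassifierConfig,
    k: int = 10,
    models=("base", "full"),
    glycan_names: list[str] | None = None,
) -> dict[str, CVResult]:
    """Seeded stratified k-fold CV with one merged ROC/AUC per model.

    ``base`` uses age and sex only; ``full`` adds the 24 glycan peaks.
    Standardization statistics are computed within training folds only.
    """
    X_glycans = np.asarray(X_glycans, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise DesignError(f"need n >= 2k samples for {k}-fold CV, got {n}")
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "UOS":
        y_arr = (y_arr == "case").astype(int)
    y_arr = y_arr.astype(int)
    if np.unique(y_arr).size < 2:
        raise StratificationError("outcome has a single class")
    sex_num = np.asarray(sex)
    if sex_num.dtype.kind in "UOS":
        sex_num = (sex_num == "M").astype(float)
    covs = np.column_stack([np.asarray(age, dtype=float), sex_num.astype(float)])

    design = {"base": covs, "full": np.column_stack([covs, X_glycans])}
    names = {
        "base": ["age", "sex"],
        "full": ["age", "sex"] + list(glycan_names or [f"GP{i}" for i in range(1, X_glycans.shape[1] + 1)]),
    }

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(n), y_arr))
    _check_partition(y_arr, folds, k)

    out = {}
    for model_name in models:
        X = design[model_name]
        preds = np.full(n, np.nan)
        assign = np.full(n, -1, dtype=int)
        coefs = []
        for fold_id, (tr, te) in enumerate(folds):
            fitted = fit_penalized_logistic(
                X[tr], y_arr[tr], config, feature_names=names[model_name]
            )
            preds[te] = fitted.predict_proba(X[te])
            assign[te] = fold_id
            coefs.append(np.concatenate([[fitted.intercept], fitted.coef]))
        assert not np.isnan(preds).any() and (assign >= 0).all()
        roc, auc = roc_auc(preds, y_arr)
        out[model_name] = CVResult(
            model_name=model_name, fold_assignment=assign, predictions=preds,
            roc=roc, auc=auc, config=config, coefficients=coefs,
        )
    return out


def tune_hyperparameters(
    X, y, grid: list[tuple[float, float]], seed: int = 0, k: int = 5,
) -> ClassifierConfig:
    """Grid search over (alpha, lambda) by internal cross-validated AUC.

    Ties in AUC are broken toward more regularization (larger lambda, then
    larger alpha).  Deterministic for a fixed seed.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "UOS":
        y_arr = (y_arr == "case").astype(int)
    y_arr = y_arr.astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y_arr)), y_arr))
    best = None
    for alpha, lam in grid:
        cfg = ClassifierConfig(alpha=alpha, lam=lam, seed=seed)
        preds = np.full(len(y_arr), np.nan)
        for tr, te in folds:
            m = fit_penalized_logistic(X[tr], y_arr[tr], cfg)
            preds[te] = m.predict_proba(X[te])
        _, auc = roc_auc(preds, y_arr)
        key = (auc, lam, alpha)
        if best is None or key > best[0]:
            best = (key, cfg)
    return best[1]


def stratified_half_split(y, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 50/50 stratified split; returns (tuning indices, holdout indices)."""
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "UOS":
        y_arr = (y_arr == "case").astype(int)
    rng = np.random.default_rng(seed)
    first, second = [], []
    for cls in np.unique(y_arr):
        idx = np.nonzero(y_arr == cls)[0]
        idx = rng.permutation(idx)
        half = len(idx) // 2
        first.append(idx[:half])
        second.append(idx[half:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


# ---------------------------------------------------------------------------
# bootstrap AUC comparison

@dataclass
class BootstrapComparison:
    delta_auc: float
    p: float
    n_boot: int
    seed: int


def bootstrap_auc_compare(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int = 0
) -> BootstrapComparison:
    """Paired bootstrap test for a difference in AUC between two score sets.

    Samples are resampled with replacement within each class; the
    two-sided p-value is the sign-agreement proportion of the bootstrap
    distribution of delta AUC.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == "case").astype(int)
    y = y.astype(int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be paired (equal length)")
    _, auc_a = roc_auc(a, y)
    _, auc_b = roc_auc(b, y)
    delta = auc_a - auc_b
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        _, aa = roc_auc(a[idx], y[idx])
        _, bb = roc_auc(b[idx], y[idx])
        deltas[i] = aa - bb
    p = 2.0 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    return BootstrapComparison(float(delta), min(1.0, p), n_boot, seed)


# ---------------------------------------------------------------------------
# PCA on the discriminative four-peak subset

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (features, components)
    explained_variance_ratio: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def pca_project(X, feature_names: list[str] | None = None) -> PCAResult:
    """Principal components of column-standardized variables.

    Component sign is fixed by making the largest-magnitude loading of
    each component positive, so scores are deterministic across runs.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise DesignError("need at least 4 samples for PCA")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.nonzero(sd == 0)[0][0])
        label = feature_names[idx] if feature_names else f"column {idx}"
        raise DesignError(f"constant column {label!r}")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * S
    evr = (S ** 2) / float((S ** 2).sum())
    return PCAResult(scores, Vt.T, evr, list(feature_names or []))


def severity_classifier(
    X_glycans, age, sex, counts, config: ClassifierConfig, k: int = 10,
    threshold: int = 2,
) -> dict[str, CVResult]:
    """Classify symptom burden (count >= threshold) within cases.

    Same merged out-of-fold machinery as the case-control classifier;
    ``base`` (age, sex) is compared with ``full`` (age, sex, glycans).
    """
    c = np.asarray(counts, dtype=int)
    target = (c >= threshold).astype(int)
    if np.unique(target).size < 2:
        raise StratificationError(
            f"severity split at >= {threshold} symptoms leaves an empty class"
        )
    return cross_validate_merged(X_glycans, age, sex, target, config, k=k)
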