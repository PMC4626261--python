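"""Case-control and intracase association statistics.

Every glycan variable is first mapped to a standard normal by rank-based
inverse-normal transformation, so effect sizes are comparable across
variables and cohorts: case-control logistic regression then yields an
odds ratio per 1 SD of the trait, and intracase linear regression yields a
between-class difference expressed in SDs.  Per-cohort estimates are
pooled by fixed-effect inverse-variance weighting, and discovery is
controlled by Benjamini-Hochberg FDR within each analysis family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from ._errors import DesignError, SeparationError

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


# ---------------------------------------------------------------------------
# rank-based inverse normal transform

@dataclass
class TransformedVariable:
    """Result of the rank inverse-normal transform."""

    values: np.ndarray
    n_ties: int = 0
    offset: str = "half"
    source: str = ""

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def inverse_normal_transform(
    x, offset: str = "half", source: str = ""
) -> TransformedVariable:
    """Map a numeric vector to standard-normal quantiles of its ranks.

    ``offset='half'`` (default) uses quantiles (r - 0.5)/n with average
    ranks for ties; ``offset='blom'`` uses (r - 3/8)/(n + 1/4).  The output
    is monotone in the source ranks and sign-symmetric: transforming ``-x``
    negates the result elementwise.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("need a 1-d vector with n >= 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    if np.all(arr == arr[0]):
        raise DesignError("constant vector: ranks carry no information")
    ranks = stats.rankdata(arr, method="average")
    n = arr.size
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    n_ties = int(n - np.unique(arr).size)
    return TransformedVariable(ndtri(q), n_ties=n_ties, offset=offset, source=source)


# ---------------------------------------------------------------------------
# result containers

@dataclass
class AssociationResult:
    """Effect of one glycan variable in one cohort (or meta-analyzed)."""

    glycan: str
    cohort: str
    beta: float
    se: float
    p: float
    n_cases: int = 0
    n_controls: int = 0
    p_adjusted: float | None = None
    description: str = ""
    kind: str = "case_control"  # or "intracase", "trend"

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(OR=self.or_, ci_low=self.ci_low, ci_high=self.ci_high)
        return d


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance combination of per-cohort effects."""

    beta: float
    se: float
    p: float
    weights: np.ndarray = field(repr=False, default=None)
    q: float = 0.0  # Cochran heterogeneity statistic (reported, not tested)
    n_studies: int = 0


# ---------------------------------------------------------------------------
# logistic regression by Newton/IRLS (shared with the ridge classifier)

def newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    penalize: np.ndarray | None = None,
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_dev: float = 1e-10,
    separation_bound: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-(penalized-)likelihood logistic fit by Newton/IRLS.

    Minimizes the negative log-likelihood plus ``ridge/2 * sum(beta_j^2)``
    over the coefficients flagged in ``penalize`` (never the intercept when
    the caller passes an all-ones first column with penalize[0]=False).
    Returns (beta, covariance) where the covariance is the inverse of the
    (penalized) observed information.

    Convergence: max |score| < tol_score or deviance change < tol_dev,
    within ``max_iter`` iterations.  Unpenalized fits whose coefficients
    exceed ``separation_bound`` in absolute value raise SeparationError.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if penalize is None:
        penalize = np.zeros(p, dtype=bool)
    pen = np.where(penalize, ridge, 0.0)
    beta = np.zeros(p)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        score = X.T @ (y - mu) - pen * beta
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"singular information matrix: {exc}") from exc
        # step-halving line search on the penalized deviance
        dev_fun = lambda b: -2.0 * float(
            y @ np.clip(X @ b, -30, 30)
            - np.logaddexp(0.0, np.clip(X @ b, -30, 30)).sum()
        ) + float(pen @ (b * b))
        step_size = 1.0
        for _ in range(25):
            cand = beta + step_size * step
            if dev_fun(cand) <= dev_fun(beta) + 1e-12:
                break
            step_size *= 0.5
        beta = beta + step_size * step
        if ridge == 0.0 and np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(
                "diverging coefficients (|beta| > "
                f"{separation_bound}): complete or quasi-complete separation"
            )
        dev = dev_fun(beta)
        if np.max(np.abs(score)) < tol_score or abs(dev_old - dev) < tol_dev:
            break
        dev_old = dev
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(info)
    return beta, cov


def _design(glycan, age, sex, extra=None):
    cols = [np.ones_like(np.asarray(glycan, dtype=float))]
    names = ["const"]
    cols.append(np.asarray(glycan, dtype=float))
    names.append("x")
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
        names.append("age")
    if sex is not None:
        s = np.asarray(sex)
        if s.dtype.kind in "UOS":
            s = (s == "M").astype(float)  # F = 0, M = 1
        cols.append(s.astype(float))
        names.append("sex")
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
        names.append("extra")
    X = np.column_stack(cols)
    return X, names


def fit_logistic(
    glycan,
    status,
    age=None,
    sex=None,
    name: str = "",
    cohort: str = "",
    description: str = "",
) -> AssociationResult:
    """Logistic regression of case/control status on one (INT-scaled) glycan.

    ``status`` may be 0/1 or "case"/"control".  Age and sex enter as
    covariates when given (sex dummy-coded F=0, M=1).  The reported OR
    corresponds to a 1-unit (i.e. 1 SD for INT variables) increase.
    """
    y = np.asarray(status)
    if y.dtype.kind in "UOS":
        y = (y == "case").astype(float)
    y = y.astype(float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise DesignError("need at least one case and one control")
    X, _ = _design(glycan, age, sex)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    beta, cov = newton_logistic(X, y)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        glycan=name, cohort=cohort, beta=float(beta[1]), se=se, p=float(p),
        n_cases=n1, n_controls=n0, description=description,
    )


def fit_intracase(
    glycan,
    trait,
    age=None,
    sex=None,
    name: str = "",
    cohort: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """OLS of an INT-scaled glycan on a clinical trait, within cases only.

    For a binary trait the coefficient is the between-class difference in
    the glycan expressed in SDs.  Disease duration should be dichotomized
    at > 8 years upstream (see :func:`dichotomize_duration`).
    """
    t = np.asarray(trait, dtype=float)
    if np.all(t == t[0]):
        raise DesignError(f"clinical trait {trait_name or 'trait'!r} constant within cases")
    X, _ = _design(t, age, sex)
    y = np.asarray(glycan, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise DesignError(
            f"insufficient degrees of freedom: n={X.shape[0]}, p={X.shape[1]}"
        )
    res = sm.OLS(y, X).fit()
    return AssociationResult(
        glycan=name, cohort=cohort, beta=float(res.params[1]),
        se=float(res.bse[1]), p=float(res.pvalues[1]),
        n_cases=X.shape[0], n_controls=0, description=trait_name, kind="intracase",
    )


def dichotomize_duration(duration_years, threshold: float = 8.0) -> np.ndarray:
    """Binary disease-duration contrast (> threshold years)."""
    return (np.asarray(duration_years, dtype=float) > threshold).astype(float)


# ---------------------------------------------------------------------------
# meta-analysis and multiplicity

def ivw_meta(effects: list[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance weighted combination of (beta, SE) pairs."""
    if not effects:
        raise ValueError("need at least one study")
    betas = np.array([b for b, _ in effects], dtype=float)
    ses = np.array([s for _, s in effects], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / ses ** 2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    q = float((w * (betas - beta) ** 2).sum())
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MetaResult(beta=beta, se=se, p=float(p), weights=w, q=q, n_studies=len(effects))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# symptom burden

SYMPTOM_FLAGS = ("ana", "pericarditis", "proteinuria")


def symptom_count(
    frame: pd.DataFrame,
    duration_threshold: float = 8.0,
    missing_policy: str = "absent",
) -> tuple[pd.Series, int]:
    """Number of present complications per case (0-4).

    Counts ANA positivity, pericarditis, proteinuria, and disease duration
    > ``duration_threshold`` years.  ``missing_policy='absent'`` treats a
    missing flag as not present; ``'exclude'`` drops samples missing *all*
    four flags and returns how many were dropped.
    """
    if missing_policy not in ("absent", "exclude"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    flags = pd.DataFrame(index=frame.index)
    for f in SYMPTOM_FLAGS:
        flags[f] = pd.to_numeric(frame[f], errors="coerce") if f in frame.columns else np.nan
    if "duration_years" in frame.columns:
        dur = pd.to_numeric(frame["duration_years"], errors="coerce")
        flags["duration_gt"] = (dur > duration_threshold).where(dur.notna())
    else:
        flags["duration_gt"] = np.nan
    n_excluded = 0
    if missing_policy == "exclude":
        all_missing = flags.isna().all(axis=1)
        n_excluded = int(all_missing.sum())
        flags = flags[~all_missing]
    counts = flags.fillna(0).astype(float).gt(0).sum(axis=1).astype(int)
    return counts, n_excluded


def symptom_burden_trend(
    glycan,
    counts,
    age=None,
    sex=None,
    name: str = "",
) -> tuple[AssociationResult, pd.DataFrame]:
    """Linear trend of an INT glycan trait on the symptom count (0-4).

    Returns the slope result (per additional complication, adjusted for
    age and sex) and per-group summaries (n, median, quartiles) for
    box-plot style reporting.
    """
    c = np.asarray(counts, dtype=float)
    if np.all(c == c[0]):
        raise DesignError("all symptom counts equal; trend undefined")
    X, _ = _design(c, age, sex)
    y = np.asarray(glycan, dtype=float)
    res = sm.OLS(y, X).fit()
    groups = (
        pd.DataFrame({"count": c.astype(int), "value": y})
        .groupby("count")["value"]
        .agg(n="size", median="median",
             q1=lambda v: float(np.percentile(v, 25)),
             q3=lambda v: float(np.percentile(v, 75)))
        .reset_index()
    )
    result = AssociationResult(
        glycan=name, cohort="pooled", beta=float(res.params[1]),
        se=float(res.bse[1]), p=float(res.pvalues[1]),
        n_cases=len(y), n_controls=0, description="symptom burden", kind="trend",
    )
    return result, groups
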