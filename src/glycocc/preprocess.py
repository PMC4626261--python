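"""Normalization, log transform, and empirical-Bayes batch correction.

The preprocessing chain for UPLC glycan peak areas is

    raw areas -> percent of total chromatogram area -> natural log
              -> batch correction (parametric empirical Bayes, plate as
                 batch) -> exponential back-transform to proportions.

Peak percentages are right-skewed and batch effects are multiplicative,
hence the log scale for correction.  The batch model shrinks per-plate
location and scale estimates toward plate-level hyperpriors (normal prior
on location, inverse-gamma on scale, hyperparameters by method of
moments), then removes them.  A ``mean_only`` mode subtracts only the
shrunken location effects for users who prefer a pure location adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigError
from .io import GlycanMatrix


def total_area_normalize(matrix: GlycanMatrix) -> GlycanMatrix:
    """Express each sample's peaks as percent of its total area (rows sum to 100)."""
    if matrix.scale not in ("raw_area", "percent_total"):
        raise ValueError(f"expected raw areas, got scale {matrix.scale!r}")
    x = matrix.values()
    if np.any(x < 0):
        raise ValueError("negative peak areas")
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        sample = matrix.data.index[np.nonzero(totals == 0)[0][0]]
        raise ValueError(f"zero total chromatogram area for sample {sample!r}")
    return matrix.replace(100.0 * x / totals[:, None], "percent_total")


def log_transform(
    matrix: GlycanMatrix, zero_policy: str = "strict", pseudo: float = 1e-3
) -> tuple[GlycanMatrix, int]:
    """Elementwise natural log; returns (matrix, number of pseudo-count substitutions).

    ``zero_policy='strict'`` (default) raises on any zero entry, since a
    zero percent means upstream peak integration failed.  With
    ``zero_policy='pseudo'`` zeros are replaced by ``pseudo`` before
    logging and the substitution count is returned.
    """
    if matrix.scale not in ("percent_total", "proportion"):
        raise ValueError(f"expected percent/proportion scale, got {matrix.scale!r}")
    x = matrix.values().copy()
    zeros = x == 0
    n_zero = int(zeros.sum())
    if n_zero:
        if zero_policy == "strict":
            i, j = np.nonzero(zeros)
            raise ValueError(
                f"zero entry at sample {matrix.data.index[i[0]]!r}, "
                f"peak {matrix.data.columns[j[0]]!r} (zero_policy='strict')"
            )
        elif zero_policy == "pseudo":
            x[zeros] = pseudo
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if np.any(x < 0):
        raise ValueError("negative entries cannot be log-transformed")
    return matrix.replace(np.log(x), "log"), n_zero


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model (per feature g, per batch i).

    ``gamma_star``/``delta_sq_star`` are the EB-shrunk location and scale
    batch effects on the standardized scale; ``gamma_bar``, ``tau_sq``,
    ``a_prior``, ``b_prior`` are the per-batch hyperparameters.
    """

    batches: list = field(default_factory=list)
    n_per_batch: np.ndarray | None = None
    grand_mean: np.ndarray | None = None
    pooled_sd: np.ndarray | None = None
    gamma_hat: np.ndarray | None = None
    delta_hat_sq: np.ndarray | None = None
    gamma_star: np.ndarray | None = None
    delta_sq_star: np.ndarray | None = None
    gamma_bar: np.ndarray | None = None
    tau_sq: np.ndarray | None = None
    a_prior: np.ndarray | None = None
    b_prior: np.ndarray | None = None
    mode: str = "full"
    trivial: bool = False  # single batch: adjustment is the identity


def _eb_solve(
    z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float,
    conv: float = 1e-10, max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the EB posterior equations for one batch.

    z: (n_i, G) standardized data for the batch; g_hat/d_hat: per-feature
    batch location / scale estimates.  Returns (gamma_star, delta_sq_star).
    """
    n = z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        ss = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        if change < conv:
            break
    return g_new, d_new


def combat_fit_adjust(
    matrix: GlycanMatrix,
    batches,
    mode: str = "full",
    preserve_grand_mean: bool = True,
) -> tuple[GlycanMatrix, BatchModel]:
    """Fit the parametric EB batch model on log-scale data and adjust it.

    Parameters
    ----------
    matrix : GlycanMatrix on the ``log`` scale.
    batches : per-sample batch (plate) labels, aligned with rows.
    mode : ``"full"`` removes location and scale effects (standard
        adjustment); ``"mean_only"`` subtracts only the shrunken location
        effects, the literal reading of "estimated batch effects were
        subtracted".
    preserve_grand_mean : re-centre each feature so its grand mean across
        all samples is exactly unchanged by the adjustment.

    With a single batch the data are returned unchanged.  Every batch must
    contain at least two samples, and no feature may have zero pooled
    variance.
    """
    if matrix.scale != "log":
        raise ValueError(f"batch correction expects log scale, got {matrix.scale!r}")
    if mode not in ("full", "mean_only"):
        raise ConfigError(f"unknown combat mode {mode!r}")
    labels = np.asarray(batches)
    if labels.shape[0] != len(matrix.data):
        raise ValueError("batch labels do not align with matrix rows")
    uniq = list(dict.fromkeys(labels.tolist()))  # stable order of appearance
    x = matrix.values()
    n_samples, n_feat = x.shape

    if len(uniq) == 1:
        model = BatchModel(batches=uniq, mode=mode, trivial=True)
        return matrix.replace(x.copy(), "corrected_log"), model

    groups = [np.nonzero(labels == b)[0] for b in uniq]
    n_i = np.array([len(g) for g in groups])
    if np.any(n_i < 2):
        small = uniq[int(np.argmin(n_i))]
        raise ValueError(
            f"batch {small!r} has fewer than 2 samples; its variance is undefined"
        )

    batch_means = np.stack([x[g].mean(axis=0) for g in groups])  # (B, G)
    grand_mean = (n_i[:, None] * batch_means).sum(axis=0) / n_samples
    resid = x.copy()
    for g, m in zip(groups, batch_means):
        resid[g] -= m
    pooled_var = (resid ** 2).sum(axis=0) / n_samples
    if np.any(pooled_var == 0):
        feat = matrix.data.columns[int(np.nonzero(pooled_var == 0)[0][0])]
        raise ValueError(f"feature {feat!r} has zero pooled variance")
    pooled_sd = np.sqrt(pooled_var)

    z = (x - grand_mean) / pooled_sd
    gamma_hat = np.stack([z[g].mean(axis=0) for g in groups])
    delta_hat_sq = np.stack([z[g].var(axis=0, ddof=1) for g in groups])

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat_sq.mean(axis=1)
    s2 = delta_hat_sq.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_sq_star = np.empty_like(delta_hat_sq)
    for bi, g in enumerate(groups):
        gamma_star[bi], delta_sq_star[bi] = _eb_solve(
            z[g], gamma_hat[bi], delta_hat_sq[bi],
            gamma_bar[bi], tau_sq[bi], a_prior[bi], b_prior[bi],
        )

    z_adj = z.copy()
    for bi, g in enumerate(groups):
        if mode == "full":
            z_adj[g] = (z[g] - gamma_star[bi]) / np.sqrt(delta_sq_star[bi])
        else:
            z_adj[g] = z[g] - gamma_star[bi]
    x_adj = z_adj * pooled_sd + grand_mean
    if preserve_grand_mean:
        x_adj += x.mean(axis=0) - x_adj.mean(axis=0)

    model = BatchModel(
        batches=uniq, n_per_batch=n_i, grand_mean=grand_mean, pooled_sd=pooled_sd,
        gamma_hat=gamma_hat, delta_hat_sq=delta_hat_sq,
        gamma_star=gamma_star, delta_sq_star=delta_sq_star,
        gamma_bar=gamma_bar, tau_sq=tau_sq, a_prior=a_prior, b_prior=b_prior,
        mode=mode,
    )
    return matrix.replace(x_adj, "corrected_log"), model


def to_proportions(matrix: GlycanMatrix, renormalize: bool = False) -> GlycanMatrix:
    """Exponential back-transform of corrected log measurements.

    ``renormalize=True`` additionally rescales each row to sum to 100;
    default off (plain exponentiation).
    """
    if matrix.scale not in ("corrected_log", "log"):
        raise ValueError(f"expected a log scale, got {matrix.scale!r}")
    x = np.exp(matrix.values())
    if renormalize:
        x = 100.0 * x / x.sum(axis=1)[:, None]
    return matrix.replace(x, "proportion")


def preprocess_matrix(
    matrix: GlycanMatrix,
    batches=None,
    combat: bool = True,
    combat_mode: str = "full",
    zero_policy: str = "strict",
    renormalize: bool = False,
) -> tuple[GlycanMatrix, BatchModel | None, int]:
    """Full chain raw areas -> proportions; returns (matrix, batch model, n zero subs)."""
    pct = total_area_normalize(matrix)
    logged, n_zero = log_transform(pct, zero_policy=zero_policy)
    model = None
    if combat:
        if batches is None:
            raise ConfigError("batch correction requested but no batch labels given")
        corrected, model = combat_fit_adjust(logged, batches, mode=combat_mode)
    else:
        corrected = logged.replace(logged.values(), "corrected_log")
    return to_proportions(corrected, renormalize=renormalize), model, n_zero
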