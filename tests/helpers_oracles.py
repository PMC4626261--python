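"""Independent brute-force oracles used by the test suite.

These are deliberately naive, loop-based re-implementations of the
published equations, kept independent of the package's vectorized code
paths so they can serve as cross-checks.
"""

import numpy as np


def combat_bruteforce(x, labels, mode="full", preserve_grand_mean=True):
    """Loop-coded parametric empirical-Bayes batch adjustment.

    Follows the standard parametric ComBat equations: per-feature
    standardization against the batch-size-weighted grand mean and pooled
    variance, per-batch location/scale estimates, method-of-moments
    hyperpriors (normal on location, inverse-gamma on scale), iterative
    posterior solution, location-scale adjustment, back-transformation.
    """
    x = np.asarray(x, dtype=float)
    labels = list(labels)
    n, G = x.shape
    batch_names = list(dict.fromkeys(labels))
    idx = {b: [i for i, l in enumerate(labels) if l == b] for b in batch_names}
    n_i = {b: len(idx[b]) for b in batch_names}

    grand_mean = np.zeros(G)
    pooled_var = np.zeros(G)
    for g in range(G):
        for b in batch_names:
            bm = sum(x[i, g] for i in idx[b]) / n_i[b]
            grand_mean[g] += n_i[b] / n * bm
        for b in batch_names:
            bm = sum(x[i, g] for i in idx[b]) / n_i[b]
            for i in idx[b]:
                pooled_var[g] += (x[i, g] - bm) ** 2 / n

    z = np.zeros_like(x)
    for i in range(n):
        for g in range(G):
            z[i, g] = (x[i, g] - grand_mean[g]) / np.sqrt(pooled_var[g])

    params = {}
    for b in batch_names:
        gamma_hat = np.array([np.mean([z[i, g] for i in idx[b]]) for g in range(G)])
        delta_hat = np.array([np.var([z[i, g] for i in idx[b]], ddof=1) for g in range(G)])
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        a = (2 * s2 + m ** 2) / s2
        bb = (m * s2 + m ** 3) / s2
        g_star = gamma_hat.copy()
        d_star = delta_hat.copy()
        for _ in range(2000):
            g_prev, d_prev = g_star.copy(), d_star.copy()
            g_star = (n_i[b] * t2 * gamma_hat + d_star * g_bar) / (n_i[b] * t2 + d_star)
            d_star = np.array([
                (bb + 0.5 * sum((z[i, g] - g_star[g]) ** 2 for i in idx[b]))
                / (n_i[b] / 2.0 + a - 1.0)
                for g in range(G)
            ])
            if (max(abs(g_star - g_prev) / np.maximum(abs(g_prev), 1e-12)) < 1e-12
                    and max(abs(d_star - d_prev) / np.maximum(abs(d_prev), 1e-12)) < 1e-12):
                break
        params[b] = dict(gamma_hat=gamma_hat, delta_hat_sq=delta_hat,
                         gamma_star=g_star, delta_sq_star=d_star,
                         gamma_bar=g_bar, tau_sq=t2, a_prior=a, b_prior=bb)

    adj = np.zeros_like(x)
    for b in batch_names:
        for i in idx[b]:
            for g in range(G):
                if mode == "full":
                    zz = (z[i, g] - params[b]["gamma_star"][g]) / np.sqrt(
                        params[b]["delta_sq_star"][g])
                else:
                    zz = z[i, g] - params[b]["gamma_star"][g]
                adj[i, g] = zz * np.sqrt(pooled_var[g]) + grand_mean[g]
    if preserve_grand_mean:
        for g in range(G):
            adj[:, g] += x[:, g].mean() - adj[:, g].mean()
    return adj, dict(grand_mean=grand_mean, pooled_var=pooled_var, params=params)


def bh_bruteforce(p):
    """Step-up BH by direct enumeration: p~_(i) = min_{j>=i} m p_(j) / j."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for j_pos, j in enumerate(order, start=1):
            if j_pos >= rank_pos:
                candidates.append(m * p[j] / j_pos)
        adjusted[i] = min(1.0, min(candidates))
    return np.array(adjusted)


def auc_bruteforce(scores, labels):
    """Mann-Whitney AUC by explicit pair counting, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
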