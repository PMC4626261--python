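"""Repeated-simulation benchmarks: effect recovery and error control.

These helpers run the full pipeline (simulate -> preprocess -> INT ->
logistic -> meta) over many seeded replicates and summarize estimator
quality.  They back both the acceptance checks and the reproducibility
script, and are useful for users validating configuration changes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .association import bh_adjust, fit_logistic, inverse_normal_transform, ivw_meta
from .classification import ClassifierConfig, cross_validate_merged
from .panel import PEAKS
from .preprocess import preprocess_matrix
from .simulate import CohortSpec, SimulationConfig, simulate_multi_cohort
from .traits import compute_traits, default_trait_library

Z95 = 1.959963984540054

#: the 16 classical summary traits (galactosylation, fucosylation,
#: sialylation, bisection families) from the default library
SUMMARY_TRAITS = [
    "G0n", "G1n", "G2n", "Fn total", "FG0 total/G0", "FG1 total/G1",
    "FG2 total/G2", "S total", "S1 total", "S2 total", "FBn",
    "FBG0/G0", "FBG1/G1", "FBG2/G2", "FBS1/(FS1 + FBS1)", "FBS2/(FS2 + FBS2)",
]


def cohort_association(table, variables=None, combat=True):
    """Preprocess one cohort and fit the per-variable logistic model.

    Returns a DataFrame indexed by variable with beta, se, p columns.
    """
    prop, _, _ = preprocess_matrix(
        table.matrix(),
        batches=table.frame["plate"].to_numpy() if combat else None,
        combat=combat,
    )
    data = prop.data
    if variables is not None and any(v not in data.columns for v in variables):
        lib = [d for d in default_trait_library() if d.name in set(variables)]
        trait_data = compute_traits(prop, library=lib).data
        data = pd.concat([data, trait_data], axis=1)
    use = list(variables) if variables is not None else list(data.columns)
    status = table.frame["status"].to_numpy()
    age = table.frame["age"].to_numpy(dtype=float)
    sex = table.frame["sex"].to_numpy()
    rows = {}
    for var in use:
        x = np.asarray(inverse_normal_transform(data[var].to_numpy()))
        r = fit_logistic(x, status, age, sex)
        rows[var] = (r.beta, r.se, r.p)
    return pd.DataFrame(rows, index=["beta", "se", "p"]).T


def recovery_study(n_reps: int = 200, seed: int = 0, n_per_arm: int = 250) -> dict:
    """Meta-analysis recovery of planted log-ORs in {0, +/-0.3, +/-0.7}.

    Three cohorts of ``2 * n_per_arm`` samples per replicate.  Returns the
    per-peak mean estimates, the largest |mean estimate - truth| over the
    24 peaks, and the pooled 95% CI coverage.
    """
    base = SimulationConfig.recovery_benchmark(seed=seed, n_per_arm=n_per_arm)
    truth = np.asarray(base.disease_logor_per_sd)
    est = np.empty((n_reps, len(PEAKS)))
    covered = np.empty((n_reps, len(PEAKS)), dtype=bool)
    for rep in range(n_reps):
        cfg = dataclasses.replace(base, seed=seed + 1 + rep)
        per_peak = {p: [] for p in PEAKS}
        for table, _ in simulate_multi_cohort(cfg):
            fits = cohort_association(table)
            for p in PEAKS:
                per_peak[p].append((fits.loc[p, "beta"], fits.loc[p, "se"]))
        for j, p in enumerate(PEAKS):
            m = ivw_meta(per_peak[p])
            est[rep, j] = m.beta
            covered[rep, j] = abs(m.beta - truth[j]) <= Z95 * m.se
    mean_est = est.mean(axis=0)
    return {
        "truth": truth,
        "mean_estimates": mean_est,
        "max_abs_error": float(np.max(np.abs(mean_est - truth))),
        "coverage": float(covered.mean()),
        "n_replicates": n_reps,
        "n_per_cohort": 2 * n_per_arm,
    }


def null_error_study(n_reps: int = 200, seed: int = 0, n_per_arm: int = 250) -> dict:
    """BH discovery rate under the global null (24 peaks + 16 summary traits)."""
    variables = list(PEAKS) + SUMMARY_TRAITS
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = SimulationConfig.null(
            seed=seed + 1 + rep,
            cohorts=(CohortSpec("null", n_per_arm, n_per_arm, 3),),
            cohort_effect_scale=(1.0,),
        )
        table, _ = simulate_multi_cohort(cfg)[0]
        fits = cohort_association(table, variables=variables)
        adj = bh_adjust(fits["p"].to_numpy())
        fractions[rep] = float((adj <= 0.05).mean())
    return {
        "bh_significant_fraction": float(fractions.mean()),
        "n_replicates": n_reps,
        "n_variables": len(variables),
    }


def confounding_study(n_reps: int = 200, seed: int = 0, n_per_arm: int = 100) -> dict:
    """Per-test type-I error with status-coupled plates, with and without
    batch correction (all true effects zero)."""
    naive = np.empty(n_reps)
    corrected = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = SimulationConfig.batch_confounded(seed=seed + 1 + rep, n_per_arm=n_per_arm)
        table, _ = simulate_multi_cohort(cfg)[0]
        fits_naive = cohort_association(table, combat=False)
        fits_corr = cohort_association(table, combat=True)
        naive[rep] = float((fits_naive["p"] < 0.05).mean())
        corrected[rep] = float((fits_corr["p"] < 0.05).mean())
    return {
        "type1_uncorrected": float(naive.mean()),
        "type1_corrected": float(corrected.mean()),
        "n_replicates": n_reps,
    }


def permuted_label_auc(seed: int = 0, n_per_arm: int = 500, k: int = 10) -> float:
    """Merged out-of-fold full-model AUC after permuting case/control labels."""
    cfg = SimulationConfig(
        seed=seed,
        cohorts=(CohortSpec("perm", n_per_arm, n_per_arm, 3),),
        cohort_effect_scale=(1.0,),
    )
    table, _ = simulate_multi_cohort(cfg)[0]
    prop, _, _ = preprocess_matrix(table.matrix(),
                                   batches=table.frame["plate"].to_numpy())
    rng = np.random.default_rng(seed + 17)
    y = rng.permutation((table.frame["status"] == "case").astype(int).to_numpy())
    res = cross_validate_merged(
        prop.values(), table.frame["age"].to_numpy(float),
        table.frame["sex"].to_numpy(), y, ClassifierConfig(seed=seed), k=k,
    )
    return float(res["full"].auc)


def planted_effect_auc_gap(seed: int = 0, n_per_arm: int = 250, k: int = 10) -> dict:
    """Base vs full model AUC gap on the default planted-effect pattern."""
    cfg = dataclasses.replace(
        SimulationConfig.default(seed=seed),
        cohorts=(CohortSpec("planted", n_per_arm, n_per_arm, 3),),
        cohort_effect_scale=(1.0,),
    )
    table, _ = simulate_multi_cohort(cfg)[0]
    prop, _, _ = preprocess_matrix(table.matrix(),
                                   batches=table.frame["plate"].to_numpy())
    y = (table.frame["status"] == "case").astype(int).to_numpy()
    res = cross_validate_merged(
        prop.values(), table.frame["age"].to_numpy(float),
        table.frame["sex"].to_numpy(), y, ClassifierConfig(seed=seed), k=k,
    )
    return {
        "auc_base": float(res["base"].auc),
        "auc_full": float(res["full"].auc),
        "gap": float(res["full"].auc - res["base"].auc),
    }
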