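"""Model/results interface for the full case-control glycome analysis.

:class:`GlycomeCaseControlModel` holds the cohort tables and analysis
settings; :meth:`~GlycomeCaseControlModel.fit` runs preprocessing, derived
traits, inverse-normal transformation, per-cohort logistic association,
intracase clinical regressions, fixed-effect meta-analysis and BH FDR, and
returns a :class:`GlycomeCaseControlResults` carrying tidy result tables,
a ``summary()`` view, and the classification machinery.

Example
-------
>>> from glycocc import SimulationConfig, GlycomeCaseControlModel
>>> model = GlycomeCaseControlModel.from_simulation(SimulationConfig.default(seed=1))
>>> results = model.fit()
>>> print(results.summary())            # doctest: +SKIP
>>> cls = results.classify()            # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError, DesignError, SeparationError
from .association import (
    AssociationResult,
    bh_adjust,
    dichotomize_duration,
    fit_intracase,
    fit_logistic,
    inverse_normal_transform,
    ivw_meta,
    symptom_burden_trend,
    symptom_count,
)
from .classification import (
    ClassifierConfig,
    bootstrap_auc_compare,
    cross_validate_merged,
    pca_project,
    roc_auc,
    severity_classifier,
)
from .io import CohortTable
from .panel import PEAKS, GlycanAnnotation
from .preprocess import preprocess_matrix
from .simulate import SimulationConfig, simulate_multi_cohort
from .traits import TraitDefinition, compute_traits, default_trait_library, trait_closure_check

logger = logging.getLogger("glycocc.model")

INTRACASE_CONTRASTS = ("ana", "pericarditis", "proteinuria", "duration_gt8")
TREND_TRAITS = ("G0n", "G2n", "Fn total", "S1 total", "FBn")
PCA_PEAKS = ("GP6", "GP9", "GP10", "GP14")


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


class GlycomeCaseControlModel:
    """Case-control IgG glycome analysis over one or more cohorts.

    Parameters
    ----------
    cohorts : list of CohortTable on the raw-area (or percent) scale.
    panel : GlycanAnnotation, default panel if omitted.
    trait_library : list of TraitDefinition, default library if omitted.
    combat : run empirical-Bayes plate correction (requires a ``plate``
        column in every cohort).
    combat_mode : ``"full"`` (location+scale) or ``"mean_only"``.
    int_offset : rank-INT offset convention, ``"half"`` or ``"blom"``.
    """

    def __init__(
        self,
        cohorts: list[CohortTable],
        panel: GlycanAnnotation | None = None,
        trait_library: list[TraitDefinition] | None = None,
        combat: bool = True,
        combat_mode: str = "full",
        zero_policy: str = "strict",
        int_offset: str = "half",
        duration_threshold: float = 8.0,
        pool_for_severity: tuple[str, ...] | None = None,
    ) -> None:
        if not cohorts:
            raise ConfigError("need at least one cohort")
        self.cohorts = list(cohorts)
        self.panel = panel or GlycanAnnotation.default()
        self.trait_library = trait_library if trait_library is not None else default_trait_library()
        self.combat = combat
        self.combat_mode = combat_mode
        self.zero_policy = zero_policy
        self.int_offset = int_offset
        self.duration_threshold = duration_threshold
        self.pool_for_severity = pool_for_severity
        self.ground_truth = None
        if combat:
            for t in self.cohorts:
                if "plate" not in t.frame.columns or t.frame["plate"].astype(str).eq("").any():
                    raise ConfigError(
                        f"cohort {t.name!r}: batch correction requested but plate "
                        "labels are missing"
                    )

    @classmethod
    def from_simulation(
        cls, sim_config: SimulationConfig, **kwargs
    ) -> "GlycomeCaseControlModel":
        pairs = simulate_multi_cohort(sim_config)
        model = cls([t for t, _ in pairs], **kwargs)
        model.ground_truth = [g for _, g in pairs]
        model.sim_config = sim_config
        return model

    # ------------------------------------------------------------------
    def fit(self) -> "GlycomeCaseControlResults":
        per_cohort: list[AssociationResult] = []
        intracase: list[AssociationResult] = []
        batch_models = {}
        proportions = {}
        traits = {}
        int_values = {}
        skipped: list[str] = []

        for table in self.cohorts:
            logger.info("preprocess: cohort %s (n=%d)", table.name, len(table))
            prop, bm, n_zero = preprocess_matrix(
                table.matrix(),
                batches=table.frame["plate"].to_numpy() if self.combat else None,
                combat=self.combat,
                combat_mode=self.combat_mode,
                zero_policy=self.zero_policy,
            )
            if n_zero:
                logger.info("preprocess: %d zero entries replaced in %s", n_zero, table.name)
            batch_models[table.name] = bm
            proportions[table.name] = prop
            trait_table = compute_traits(prop, self.panel, self.trait_library)
            traits[table.name] = trait_table
            violations = trait_closure_check(trait_table)
            if len(violations):
                logger.warning("trait closure violations in %s:\n%s", table.name, violations)

            variables = pd.concat([prop.data, trait_table.data], axis=1)
            frame = table.frame
            status = frame["status"].to_numpy()
            age = frame["age"].to_numpy(dtype=float)
            sex = frame["sex"].to_numpy()
            ints = {}
            for var in variables.columns:
                ints[var] = np.asarray(
                    inverse_normal_transform(
                        variables[var].to_numpy(), offset=self.int_offset, source=var
                    )
                )
            int_values[table.name] = pd.DataFrame(ints, index=variables.index)

            for var in variables.columns:
                desc = (
                    f"Percentage of {self.panel.structure(var)} glycan in total IgG glycans"
                    if var in PEAKS else "derived trait"
                )
                try:
                    res = fit_logistic(
                        ints[var], status, age, sex,
                        name=var, cohort=table.name, description=desc,
                    )
                except (SeparationError, DesignError) as exc:
                    logger.warning("association skipped for %s in %s: %s", var, table.name, exc)
                    skipped.append(f"case_control:{table.name}:{var}")
                    continue
                per_cohort.append(res)

            intracase.extend(
                self._intracase_cohort(table, int_values[table.name], skipped)
            )

        cc_frame = _results_frame(per_cohort)
        meta_frame = self._meta_analyze(cc_frame, family="case_control")
        cc_frame = self._adjust_within(cc_frame, ["cohort"])
        intra_frame = _results_frame(intracase) if intracase else pd.DataFrame()
        intra_meta = (
            self._meta_analyze(intra_frame, family="intracase", by="description")
            if len(intra_frame)
            else pd.DataFrame()
        )

        trend_results, trend_groups = self._trend(int_values)

        return GlycomeCaseControlResults(
            model=self,
            associations=cc_frame,
            meta=meta_frame,
            intracase=intra_frame,
            intracase_meta=intra_meta,
            trend=trend_results,
            trend_groups=trend_groups,
            batch_models=batch_models,
            proportions=proportions,
            traits=traits,
            int_values=int_values,
            skipped=skipped,
        )

    # ------------------------------------------------------------------
    def _intracase_cohort(self, table, ints, skipped) -> list[AssociationResult]:
        frame = table.frame
        cases = frame.index[frame["status"] == "case"]
        out = []
        if len(cases) < 10:
            return out
        age = frame.loc[cases, "age"].to_numpy(dtype=float)
        sex = frame.loc[cases, "sex"].to_numpy()
        for contrast in INTRACASE_CONTRASTS:
            if contrast == "duration_gt8":
                if "duration_years" not in frame.columns:
                    continue
                raw = pd.to_numeric(frame.loc[cases, "duration_years"], errors="coerce")
                ok = raw.notna().to_numpy()
                values = dichotomize_duration(raw[ok], self.duration_threshold)
            else:
                if contrast not in frame.columns:
                    continue
                raw = pd.to_numeric(frame.loc[cases, contrast], errors="coerce")
                ok = raw.notna().to_numpy()
                values = raw[ok].to_numpy(dtype=float)
            if ok.sum() < 10 or len(np.unique(values)) < 2:
                continue
            case_pos = np.asarray(cases)[ok]  # positional row indices of usable cases
            for var in ints.columns:
                try:
                    res = fit_intracase(
                        ints.iloc[case_pos][var].to_numpy(),
                        values, age[ok], sex[ok],
                        name=var, cohort=table.name, trait_name=contrast,
                    )
                except DesignError as exc:
                    skipped.append(f"intracase:{table.name}:{contrast}:{var}")
                    continue
                out.append(res)
        return out

    def _meta_analyze(self, frame: pd.DataFrame, family: str, by: str | None = None) -> pd.DataFrame:
        if frame.empty:
            return frame
        keys = ["glycan"] + ([by] if by else [])
        rows = []
        for key, grp in frame.groupby(keys, sort=False):
            meta = ivw_meta(list(zip(grp["beta"], grp["se"])))
            res = AssociationResult(
                glycan=key[0] if isinstance(key, tuple) else key,
                cohort="meta",
                beta=meta.beta, se=meta.se, p=meta.p,
                n_cases=int(grp["n_cases"].sum()),
                n_controls=int(grp["n_controls"].sum()),
                description=(key[1] if by else grp["description"].iloc[0]),
                kind=family,
            )
            d = res.as_dict()
            d["q_heterogeneity"] = meta.q
            d["n_studies"] = meta.n_studies
            rows.append(d)
        out = pd.DataFrame(rows)
        return self._adjust_within(out, [by] if by else None)

    @staticmethod
    def _adjust_within(frame: pd.DataFrame, by: list[str] | None) -> pd.DataFrame:
        if frame.empty:
            return frame
        frame = frame.copy()
        if by:
            for _, idx in frame.groupby(by, sort=False).groups.items():
                frame.loc[idx, "p_adjusted"] = bh_adjust(frame.loc[idx, "p"].to_numpy())
        else:
            frame["p_adjusted"] = bh_adjust(frame["p"].to_numpy())
        return frame

    def _trend(self, int_values) -> tuple[pd.DataFrame, dict]:
        pool_names = self.pool_for_severity or tuple(t.name for t in self.cohorts[:2])
        frames, ints = [], []
        for t in self.cohorts:
            if t.name in pool_names:
                mask = t.frame["status"] == "case"
                frames.append(t.frame[mask])
                ints.append(int_values[t.name][mask.to_numpy()])
        if not frames:
            return pd.DataFrame(), {}
        pooled = pd.concat(frames, ignore_index=True)
        pooled_int = pd.concat(ints, ignore_index=True)
        counts, _ = symptom_count(pooled, self.duration_threshold)
        rows, groups = [], {}
        for trait in TREND_TRAITS:
            if trait not in pooled_int.columns:
                continue
            try:
                res, grp = symptom_burden_trend(
                    pooled_int[trait].to_numpy(), counts.to_numpy(),
                    pooled["age"].to_numpy(dtype=float), pooled["sex"].to_numpy(),
                    name=trait,
                )
            except DesignError:
                continue
            rows.append(res.as_dict())
            groups[trait] = grp
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["p_adjusted"] = bh_adjust(frame["p"].to_numpy())
        return frame, groups


# ---------------------------------------------------------------------------

@dataclass
class ClassificationResults:
    """Per-cohort merged out-of-fold classification plus extras."""

    cv: dict  # cohort -> {"base": CVResult, "full": CVResult}
    auc_table: pd.DataFrame
    per_glycan_auc: pd.DataFrame
    pca: dict
    severity: dict | None
    bootstrap: pd.DataFrame
    config: ClassifierConfig


@dataclass
class GlycomeCaseControlResults:
    """Fitted association results with classification and reporting hooks."""

    model: GlycomeCaseControlModel
    associations: pd.DataFrame
    meta: pd.DataFrame
    intracase: pd.DataFrame
    intracase_meta: pd.DataFrame
    trend: pd.DataFrame
    trend_groups: dict
    batch_models: dict
    proportions: dict
    traits: dict
    int_values: dict
    skipped: list = field(default_factory=list)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        """Meta-analysis discoveries at the given FDR."""
        if self.meta.empty:
            return self.meta
        return self.meta[self.meta["p_adjusted"] <= fdr]

    # ------------------------------------------------------------------
    def classify(
        self,
        config: ClassifierConfig | None = None,
        k: int = 10,
        n_boot: int = 1000,
        run_severity: bool = True,
        severity_threshold: int = 2,
    ) -> ClassificationResults:
        """Penalized-logistic classification per cohort (base vs full model).

        Uses proportion-scale peak values; standardization happens inside
        training folds.  Also evaluates each glycan's individual ROC AUC,
        projects the four strongly predictive peaks by PCA, compares base
        and full AUCs by paired bootstrap, and (optionally) classifies
        symptom burden within pooled cases.
        """
        cfg = config or ClassifierConfig()
        cv, boot_rows, auc_rows, glycan_rows, pca = {}, [], [], [], {}
        for table in self.model.cohorts:
            prop = self.proportions[table.name]
            frame = table.frame
            y = (frame["status"] == "case").astype(int).to_numpy()
            age = frame["age"].to_numpy(dtype=float)
            sex = frame["sex"].to_numpy()
            X = prop.values()
            res = cross_validate_merged(
                X, age, sex, y, cfg, k=k, glycan_names=list(PEAKS)
            )
            cv[table.name] = res
            for name, r in res.items():
                auc_rows.append({"cohort": table.name, "model": name, "auc": r.auc,
                                 "n": len(y)})
            comp = bootstrap_auc_compare(
                res["full"].predictions, res["base"].predictions, y,
                n_boot=n_boot, seed=cfg.seed,
            )
            boot_rows.append({
                "cohort": table.name, "delta_auc": comp.delta_auc, "p": comp.p,
                "n_boot": comp.n_boot,
            })
            for j, peak in enumerate(PEAKS):
                _, auc = roc_auc(X[:, j], y)
                glycan_rows.append({
                    "cohort": table.name, "glycan": peak,
                    "auc": max(auc, 1.0 - auc),  # direction-free discriminative power
                    "auc_directed": auc,
                })
            idx = [list(PEAKS).index(p) for p in PCA_PEAKS]
            pca[table.name] = pca_project(X[:, idx], feature_names=list(PCA_PEAKS))

        severity = None
        if run_severity:
            severity = self._severity(cfg, k=k, threshold=severity_threshold)

        return ClassificationResults(
            cv=cv,
            auc_table=pd.DataFrame(auc_rows),
            per_glycan_auc=pd.DataFrame(glycan_rows),
            pca=pca,
            severity=severity,
            bootstrap=pd.DataFrame(boot_rows),
            config=cfg,
        )

    def _severity(self, cfg: ClassifierConfig, k: int, threshold: int):
        pool_names = self.model.pool_for_severity or tuple(
            t.name for t in self.model.cohorts[:2]
        )
        frames, mats = [], []
        for t in self.model.cohorts:
            if t.name in pool_names:
                mask = (t.frame["status"] == "case").to_numpy()
                frames.append(t.frame[mask])
                mats.append(self.proportions[t.name].values()[mask])
        if not frames:
            return None
        pooled = pd.concat(frames, ignore_index=True)
        X = np.vstack(mats)
        counts, _ = symptom_count(pooled, self.model.duration_threshold)
        try:
            res = severity_classifier(
                X, pooled["age"].to_numpy(dtype=float), pooled["sex"].to_numpy(),
                counts.to_numpy(), cfg, k=k, threshold=threshold,
            )
        except Exception as exc:  # burden split can be degenerate on tiny runs
            logger.warning("severity classification skipped: %s", exc)
            return None
        comp = bootstrap_auc_compare(
            res["full"].predictions, res["base"].predictions,
            (counts.to_numpy() >= threshold).astype(int), n_boot=1000, seed=cfg.seed,
        )
        return {"cv": res, "bootstrap": comp, "n": len(pooled)}

    # ------------------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        lines = ["Glycome case-control analysis", "=" * 34]
        for t in self.model.cohorts:
            lines.append(f"cohort {t.name}: {t.n_cases} cases / {t.n_controls} controls")
        if not self.meta.empty:
            m = self.meta.sort_values("p").head(top)
            lines.append("")
            lines.append(f"top meta-analysis associations (of {len(self.meta)}):")
            lines.append(f"{'variable':<22}{'OR':>8}{'95% CI':>18}{'p_adj':>12}")
            for _, r in m.iterrows():
                ci = f"({r['ci_low']:.2f}-{r['ci_high']:.2f})"
                lines.append(
                    f"{r['glycan']:<22}{r['OR']:>8.2f}{ci:>18}{r['p_adjusted']:>12.2e}"
                )
            n_sig = int((self.meta["p_adjusted"] <= 0.05).sum())
            lines.append(f"significant at FDR 0.05: {n_sig}/{len(self.meta)}")
        if len(self.trend):
            lines.append("")
            lines.append("symptom-burden trends (pooled cases, per complication):")
            for _, r in self.trend.iterrows():
                lines.append(
                    f"  {r['glycan']:<12} slope {r['beta']:+.3f} SD "
                    f"(SE {r['se']:.3f}, p_adj {r['p_adjusted']:.2e})"
                )
        return "\n".join(lines)

    # plotting -----------------------------------------------------------
    def plot_boxplots(self, variables, ax=None):
        """Case/control box plots of proportion-scale variables, per cohort."""
        import matplotlib.pyplot as plt

        variables = list(variables)
        fig, axes = plt.subplots(1, len(variables), figsize=(3 * len(variables), 3.2))
        axes = np.atleast_1d(axes)
        for ax_, var in zip(axes, variables):
            data, labels = [], []
            for t in self.model.cohorts:
                source = (
                    self.proportions[t.name].data if var in PEAKS
                    else self.traits[t.name].data
                )
                for status in ("control", "case"):
                    mask = (t.frame["status"] == status).to_numpy()
                    data.append(source[var].to_numpy()[mask])
                    labels.append(f"{t.name[:3]}\n{status[:4]}")
            ax_.boxplot(data, tick_labels=labels, whis=(10, 90), showfliers=True)
            ax_.set_title(var)
            ax_.tick_params(axis="x", labelsize=6)
        fig.tight_layout()
        return fig
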