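"""End-to-end orchestration: config, staged runs, artifacts, report.

A run executes, per cohort: preprocessing (total-area normalization, log,
plate correction), derived traits, inverse-normal transform, logistic
association; then meta-analysis across cohorts with BH FDR; then
classification per cohort; and writes every artifact with provenance into
an output directory together with a JSON run manifest (config, seed,
input/artifact hashes).  Reruns with the same config and seed produce
hash-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError
from .classification import ClassifierConfig
from .io import CohortTable, read_cohort_table, write_association_table, write_cohort_table
from .model import PCA_PEAKS, GlycomeCaseControlModel
from .panel import PEAKS, GlycanAnnotation
from .simulate import CohortSpec, SimulationConfig
from .traits import load_trait_library

logger = logging.getLogger("glycocc.pipeline")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    input_files: list = field(default_factory=list)  # empty -> simulate
    simulation: dict = field(default_factory=dict)   # overrides for SimulationConfig
    out_dir: str = "glycocc_run"
    combat: bool = True
    combat_mode: str = "full"
    zero_policy: str = "strict"
    int_offset: str = "half"
    duration_threshold: float = 8.0
    classifier_alpha: float = 0.0
    classifier_lambda: float = 0.1
    cv_folds: int = 10
    n_boot: int = 1000
    stages: dict = field(default_factory=lambda: {
        "associate": True, "intracase": True, "classify": True, "report": True,
    })
    trait_library: str | None = None
    annotation: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.combat_mode not in ("full", "mean_only"):
            raise ConfigError(f"combat_mode {self.combat_mode!r} invalid")
        if self.zero_policy not in ("strict", "pseudo"):
            raise ConfigError(f"zero_policy {self.zero_policy!r} invalid")
        if not 0 <= self.classifier_alpha <= 1:
            raise ConfigError("classifier_alpha must be in [0,1]")
        if self.classifier_lambda < 0:
            raise ConfigError("classifier_lambda must be >= 0")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        for f in self.input_files:
            if not Path(f).exists():
                raise ConfigError(f"input file not found: {f}")
        if self.input_files and self.combat:
            # pre-flight: plate column must exist before any computation
            for f in self.input_files:
                header = Path(f).open().readline().rstrip("\n")
                sep = "," if str(f).endswith(".csv") else "\t"
                if "plate" not in header.split(sep):
                    raise ConfigError(
                        f"{f}: batch correction enabled but no 'plate' column"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimulationConfig:
        overrides = dict(self.simulation)
        overrides.setdefault("seed", self.seed)
        if "cohorts" in overrides:
            overrides["cohorts"] = tuple(
                CohortSpec(**c) if isinstance(c, dict) else CohortSpec(*c)
                for c in overrides["cohorts"]
            )
            overrides.setdefault(
                "cohort_effect_scale", tuple(1.0 for _ in overrides["cohorts"])
            )
        return SimulationConfig(**overrides)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_case_control_study(config: RunConfig) -> dict:
    """Execute the full study; returns the run manifest (also written to disk).

    Stage failures abort with the stage name; artifacts written so far are
    kept and flagged in the partial manifest on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "glycocc_version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "inputs": {},
        "artifacts": {},
        "stages_completed": [],
    }

    def checkpoint(stage=None):
        if stage:
            manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def register(name: str, path: Path):
        manifest["artifacts"][name] = {
            "file": str(path.relative_to(out)), "sha256": _sha256_file(path),
        }

    try:
        panel = GlycanAnnotation.read(config.annotation) if config.annotation \
            else GlycanAnnotation.default()
        library = load_trait_library(config.trait_library, panel)

        # --- stage: ingest / simulate
        if config.input_files:
            cohorts = [read_cohort_table(f, panel) for f in config.input_files]
            for f in config.input_files:
                manifest["inputs"][Path(f).name] = _sha256_file(Path(f))
            model = GlycomeCaseControlModel(
                cohorts, panel, library,
                combat=config.combat, combat_mode=config.combat_mode,
                zero_policy=config.zero_policy, int_offset=config.int_offset,
                duration_threshold=config.duration_threshold,
            )
        else:
            sim = config.sim_config()
            model = GlycomeCaseControlModel.from_simulation(
                sim,
                panel=panel, trait_library=library,
                combat=config.combat, combat_mode=config.combat_mode,
                zero_policy=config.zero_policy, int_offset=config.int_offset,
                duration_threshold=config.duration_threshold,
            )
            for table in model.cohorts:
                path = out / f"simulated_{table.name}.tsv"
                write_cohort_table(table, path)
                register(f"simulated_{table.name}", path)
        checkpoint("ingest")

        # --- stage: associate (preprocess + traits + association + meta)
        results = model.fit()
        for name, trait_table in results.traits.items():
            path = out / f"traits_{name}.tsv"
            _write_tsv(trait_table.data.reset_index(), path)
            register(f"traits_{name}", path)
        path = out / "associations_per_cohort.tsv"
        write_association_table(results.associations, path)
        register("associations_per_cohort", path)
        path = out / "associations_meta.tsv"
        write_association_table(results.meta, path)
        register("associations_meta", path)
        if config.stages.get("intracase", True) and len(results.intracase_meta):
            path = out / "intracase_meta.tsv"
            write_association_table(results.intracase_meta, path)
            register("intracase_meta", path)
        if len(results.trend):
            path = out / "symptom_trend.tsv"
            _write_tsv(results.trend, path)
            register("symptom_trend", path)
        checkpoint("associate")

        # --- stage: classify
        classification = None
        if config.stages.get("classify", True):
            cfg = ClassifierConfig(
                alpha=config.classifier_alpha, lam=config.classifier_lambda,
                seed=config.seed,
            )
            classification = results.classify(cfg, k=config.cv_folds, n_boot=config.n_boot)
            _write_tsv(classification.auc_table, out / "auc_summary.tsv")
            register("auc_summary", out / "auc_summary.tsv")
            _write_tsv(classification.per_glycan_auc, out / "per_glycan_auc.tsv")
            register("per_glycan_auc", out / "per_glycan_auc.tsv")
            _write_tsv(classification.bootstrap, out / "auc_bootstrap.tsv")
            register("auc_bootstrap", out / "auc_bootstrap.tsv")
            roc_rows = []
            for cohort, res in classification.cv.items():
                for mname, r in res.items():
                    roc_rows.append(pd.DataFrame({
                        "cohort": cohort, "model": mname,
                        "fpr": r.roc.fpr, "tpr": r.roc.tpr,
                    }))
            _write_tsv(pd.concat(roc_rows, ignore_index=True), out / "roc_points.tsv")
            register("roc_points", out / "roc_points.tsv")
            pca_rows = []
            for cohort, p in classification.pca.items():
                df = pd.DataFrame(p.scores[:, :2], columns=["pc1", "pc2"])
                df.insert(0, "cohort", cohort)
                df["explained_1"] = p.explained_variance_ratio[0]
                df["explained_2"] = p.explained_variance_ratio[1]
                pca_rows.append(df)
            _write_tsv(pd.concat(pca_rows, ignore_index=True), out / "pca_scores.tsv")
            register("pca_scores", out / "pca_scores.tsv")
            if classification.severity is not None:
                sev = classification.severity
                sev_df = pd.DataFrame([
                    {"model": m, "auc": r.auc, "n": sev["n"]}
                    for m, r in sev["cv"].items()
                ])
                sev_df["delta_auc"] = sev["bootstrap"].delta_auc
                sev_df["p_bootstrap"] = sev["bootstrap"].p
                _write_tsv(sev_df, out / "severity_auc.tsv")
                register("severity_auc", out / "severity_auc.tsv")
        checkpoint("classify")

        (out / "summary.txt").write_text(results.summary() + "\n")
        register("summary", out / "summary.txt")

        if config.stages.get("report", True):
            generate_report(out, results, classification)
            manifest["artifacts"]["report"] = {"file": "report.md", "sha256": None}
        checkpoint("report")
        manifest["status"] = "completed"
        checkpoint()
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        checkpoint()
        raise
    return manifest


NUMERIC_ARTIFACT_SUFFIXES = (".tsv", ".txt")


def verify_reconstruction(manifest: dict, workdir: str | Path) -> bool:
    """Re-run the study from the manifest's config+seed and compare hashes.

    Returns True when every numeric artifact is reproduced byte-identically
    (figures and the rendered report are excluded).
    """
    cfg = RunConfig(**manifest["config"])
    cfg.out_dir = str(Path(workdir) / "reconstruction")
    cfg.stages = dict(cfg.stages, report=False)
    new_manifest = run_case_control_study(cfg)
    for name, art in manifest["artifacts"].items():
        if art.get("sha256") is None:
            continue
        if not str(art["file"]).endswith(NUMERIC_ARTIFACT_SUFFIXES):
            continue
        other = new_manifest["artifacts"].get(name)
        if other is None or other["sha256"] != art["sha256"]:
            logger.warning("reconstruction mismatch for artifact %s", name)
            return False
    return True


def generate_report(out: Path, results, classification) -> Path:
    """Render box plots, ROC overlays, PCA scatter and summary tables.

    Missing pieces (e.g. a skipped classification stage) are noted in the
    report rather than failing it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    blocks = ["# Glycome case-control run report", ""]

    top = results.meta.sort_values("p").head(6)["glycan"].tolist() if len(results.meta) else []
    if top:
        fig = results.plot_boxplots(top[:4])
        fig.savefig(out / "fig_boxplots.png", dpi=110)
        plt.close(fig)
        blocks += ["## Case-control differences", "![boxplots](fig_boxplots.png)", ""]
    else:
        blocks += ["## Case-control differences", "_association table missing_", ""]

    if classification is not None:
        fig, axes = plt.subplots(1, len(classification.cv),
                                 figsize=(3.2 * len(classification.cv), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (cohort, res) in zip(axes, classification.cv.items()):
            for mname, r in res.items():
                ax.plot(r.roc.fpr, r.roc.tpr, label=f"{mname} (AUC {r.auc:.3f})")
            ax.plot([0, 1], [0, 1], "k:", lw=0.5)
            ax.set_title(cohort)
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_roc.png", dpi=110)
        plt.close(fig)
        blocks += ["## Classification (merged out-of-fold ROC)", "![roc](fig_roc.png)", ""]

        fig, axes = plt.subplots(1, len(classification.pca),
                                 figsize=(3.2 * len(classification.pca), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (cohort, p) in zip(axes, classification.pca.items()):
            table = next(t for t in results.model.cohorts if t.name == cohort)
            colors = np.where(table.frame["status"] == "case", "tab:red", "tab:blue")
            ax.scatter(p.scores[:, 0], p.scores[:, 1], s=6, c=colors, alpha=0.6)
            ax.set_xlabel(f"PC1 ({100 * p.explained_variance_ratio[0]:.0f}%)")
            ax.set_ylabel(f"PC2 ({100 * p.explained_variance_ratio[1]:.0f}%)")
            ax.set_title(cohort)
        fig.tight_layout()
        fig.savefig(out / "fig_pca.png", dpi=110)
        plt.close(fig)
        blocks += [f"## PCA of {', '.join(PCA_PEAKS)}", "![pca](fig_pca.png)", ""]
    else:
        blocks += ["## Classification", "_classification stage not run_", ""]

    if results.trend_groups:
        traits = list(results.trend_groups)
        fig, axes = plt.subplots(1, len(traits), figsize=(2.6 * len(traits), 3.0))
        axes = np.atleast_1d(axes)
        for ax, trait in zip(axes, traits):
            grp = results.trend_groups[trait]
            ax.errorbar(grp["count"], grp["median"],
                        yerr=[grp["median"] - grp["q1"], grp["q3"] - grp["median"]],
                        fmt="o-", capsize=3)
            ax.set_title(trait, fontsize=8)
            ax.set_xlabel("symptoms")
        fig.tight_layout()
        fig.savefig(out / "fig_trend.png", dpi=110)
        plt.close(fig)
        blocks += ["## Symptom burden", "![trend](fig_trend.png)", ""]

    blocks += ["## Summary", "```", results.summary(), "```", ""]
    path = out / "report.md"
    path.write_text("\n".join(blocks))
    return path
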