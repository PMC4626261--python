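"""Seeded multi-cohort synthetic glycome generator with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, for three case-control cohorts measured on multi-sample plates:

- compositional 24-peak profiles from a logistic-normal model (softmax of
  correlated Gaussians on the log scale), which yields closure, inter-peak
  correlation and the right skew that motivates log transformation;
- multiplicative plate batch effects (per-plate, per-peak location shifts
  and scale multipliers in log space);
- age and sex effects on the latent log-abundances, with case/control
  age and sex drawn from the same distributions (matched design);
- per-glycan disease effects planted as Gaussian location shifts for
  cases.  Because status is drawn first and the latent shift is Gaussian,
  the marginal single-glycan logistic model is exactly linear, and the
  shift is calibrated (fixed-point solve over mixture-variance inflation,
  covariate variance and the first-order compositional closure shift) so
  the planted value IS the log-OR per 1 SD that the pipeline estimates;
- a latent severity score per case that loads on glycans and drives
  clinical complication flags (ANA, pericarditis, proteinuria) and
  disease duration.

This is a statistical stand-in for real cohorts, not a biological model;
see the methods note for what it does and does not emulate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .io import CohortTable, write_cohort_table
from .panel import N_PEAKS, PEAKS

# baseline mean percentages of total area per peak (typical adult IgG glycome)
_BASELINE_PCT = np.array([
    0.20, 0.45, 0.10, 18.0, 0.15, 6.0, 0.70, 18.0, 9.0, 4.0, 0.70, 1.20,
    0.60, 16.0, 2.50, 2.50, 1.50, 12.0, 2.00, 0.50, 1.00, 1.00, 2.50, 1.00,
])

# demo disease pattern (log-OR per SD): agalactosylated / bisected analogues
# up in cases, digalactosylated / sialylated analogues down
_DEFAULT_BETA = np.array([
    0.40, 0.45, 0.00, 0.40, 0.20, 0.70, 0.30, -0.10, -0.80, 0.45, 0.00, 0.10,
    0.00, -0.60, 0.00, -0.30, 0.10, -0.40, 0.20, -0.10, 0.00, 0.30, -0.30, 0.30,
])

_DEFAULT_AGE_SLOPE = np.zeros(N_PEAKS)
_DEFAULT_AGE_SLOPE[[3, 5]] = [0.004, 0.003]       # GP4, GP6 rise with age
_DEFAULT_AGE_SLOPE[[7, 13, 17]] = [-0.002, -0.004, -0.002]  # GP8, GP14, GP18 fall

_DEFAULT_SEX_EFFECT = np.zeros(N_PEAKS)
_DEFAULT_SEX_EFFECT[[3, 13]] = [0.05, -0.05]      # modest M-vs-F differences

_DEFAULT_SEVERITY_LOADING = np.zeros(N_PEAKS)
_DEFAULT_SEVERITY_LOADING[[0, 1, 3, 5, 9]] = 0.08          # burden raises G0/B peaks
_DEFAULT_SEVERITY_LOADING[[8, 13, 17, 22]] = -0.08         # and lowers G2/S peaks


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_cases: int
    n_controls: int
    n_plates: int = 4

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_plates <= 0:
            raise ConfigError(f"cohort {self.name!r}: all sizes must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory for reproducibility."""

    seed: int
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("latin_american", 261, 247, 6),
        CohortSpec("trinidad", 108, 193, 4),
        CohortSpec("han_chinese", 106, 105, 3),
    )
    baseline_log_mean: tuple = tuple(np.log(_BASELINE_PCT))
    log_sd: tuple = tuple(np.full(N_PEAKS, 0.25))
    corr_rho: float = 0.10
    disease_logor_per_sd: tuple = tuple(_DEFAULT_BETA)
    cohort_effect_scale: tuple = (1.0, 1.0, 1.0)
    age_slope: tuple = tuple(_DEFAULT_AGE_SLOPE)
    sex_effect: tuple = tuple(_DEFAULT_SEX_EFFECT)
    severity_loading: tuple = tuple(_DEFAULT_SEVERITY_LOADING)
    batch_loc_sd: float = 0.15
    batch_scale_sd: float = 0.08
    confound_strength: float = 0.0  # >0 couples plate assignment to status
    age_mean: float = 42.0
    age_sd: float = 12.0
    female_fraction: float = 0.90
    total_area_log_mean: float = np.log(2.0e6)
    total_area_log_sd: float = 0.15
    calibrate_effects: bool = True

    def __post_init__(self):
        if not 0.0 <= self.corr_rho < 1.0:
            raise ConfigError("corr_rho must be in [0, 1)")
        for name in ("baseline_log_mean", "log_sd", "disease_logor_per_sd",
                     "age_slope", "sex_effect", "severity_loading"):
            if len(getattr(self, name)) != N_PEAKS:
                raise ConfigError(f"{name} must have length {N_PEAKS}")
        if any(s <= 0 for s in self.log_sd):
            raise ConfigError("log_sd entries must be positive")
        if len(self.cohort_effect_scale) < len(self.cohorts):
            raise ConfigError("cohort_effect_scale shorter than cohorts")

    def covariance(self) -> np.ndarray:
        sd = np.asarray(self.log_sd)
        corr = np.full((N_PEAKS, N_PEAKS), self.corr_rho)
        np.fill_diagonal(corr, 1.0)
        cov = sd[:, None] * corr * sd[None, :]
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin < -1e-10:
            raise ConfigError(f"covariance not positive semidefinite (min eig {eigmin})")
        return cov

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationConfig":
        return cls(seed=seed)

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """All disease effects and severity loadings zero."""
        return cls(
            seed=seed,
            disease_logor_per_sd=tuple(np.zeros(N_PEAKS)),
            severity_loading=tuple(np.zeros(N_PEAKS)),
            **kw,
        )

    @classmethod
    def recovery_benchmark(cls, seed: int = 0, n_per_arm: int = 250) -> "SimulationConfig":
        """Three equal cohorts with planted log-ORs in {0, +/-0.3, +/-0.7}.

        The +/- pairs sit on comparable-abundance peaks (GP4/GP8 at +/-0.7,
        GP6/GP9 at +/-0.3) so compositional closure shifts nearly cancel;
        severity loadings are zero (association recovery only).
        """
        beta = np.zeros(N_PEAKS)
        beta[3] = 0.7    # GP4
        beta[7] = -0.7   # GP8
        beta[5] = 0.3    # GP6
        beta[8] = -0.3   # GP9
        return cls(
            seed=seed,
            cohorts=(
                CohortSpec("sim_a", n_per_arm, n_per_arm, 3),
                CohortSpec("sim_b", n_per_arm, n_per_arm, 3),
                CohortSpec("sim_c", n_per_arm, n_per_arm, 3),
            ),
            disease_logor_per_sd=tuple(beta),
            severity_loading=tuple(np.zeros(N_PEAKS)),
        )

    @classmethod
    def batch_confounded(cls, seed: int = 0, n_per_arm: int = 100) -> "SimulationConfig":
        """Null effects but strong plate shifts with status-coupled plating."""
        cfg = cls.null(
            seed=seed,
            cohorts=(CohortSpec("confounded", n_per_arm, n_per_arm, 2),),
            cohort_effect_scale=(1.0,),
        )
        return replace(cfg, batch_loc_sd=0.30, confound_strength=2.0)


@dataclass
class GroundTruth:
    """Everything needed to recompute any planted quantity downstream."""

    cohort: str
    seed: int
    beta_target: np.ndarray
    latent_shift: np.ndarray
    closure_shift: float
    plate_loc: np.ndarray    # (n_plates, 24)
    plate_scale: np.ndarray  # (n_plates, 24)
    severity: np.ndarray     # per sample; NaN for controls
    age_slope: np.ndarray
    sex_effect: np.ndarray
    symptom_model: dict = field(default_factory=dict)


def _solve_latent_shifts(
    beta: np.ndarray,
    sigma: np.ndarray,
    weights: np.ndarray,
    rho: float,
    age_slope: np.ndarray,
    sex_effect: np.ndarray,
    age_var: float,
    sex_var: float,
    case_fraction: float,
) -> tuple[np.ndarray, float]:
    """Latent case-shift vector whose induced per-SD log-OR equals ``beta``.

    The pipeline measures log *percentages* y_g = x_g - log(total), so the
    calibration works on the closure scale: under first-order linearization
    log(total) ~ sum_h w_h x_h with w the baseline shares, giving

        var(y_g) = s_g^2 + V_T - 2*C_g,
        V_T = (1-rho) sum w^2 s^2 + rho (sum w s)^2,
        C_g = (1-rho) w_g s_g^2 + rho s_g sum w s,

    and effective age/sex slopes a_g - sum(w a), b_g - sum(w b).  The fixed
    point solves d so that the per-marginal-SD slope (d - kappa) *
    sd_marg / var(y) equals beta, where kappa = log of the relative change
    in expected total abundance (null peaks receive exactly kappa so their
    measured effect is zero) and sd_marg adds the case/control mixture and
    covariate variance components.
    """
    p = case_fraction
    w = weights / weights.sum()
    ws = (w * sigma).sum()
    v_total = (1 - rho) * (w ** 2 * sigma ** 2).sum() + rho * ws ** 2
    cov_g = (1 - rho) * w * sigma ** 2 + rho * sigma * ws
    v = sigma ** 2 + v_total - 2 * cov_g  # within-class variance of log-percent
    a_eff = age_slope - (w * age_slope).sum()
    b_eff = sex_effect - (w * sex_effect).sum()
    var_extra = a_eff ** 2 * age_var + b_eff ** 2 * sex_var
    d = beta * np.sqrt(v)
    kappa = 0.0
    for _ in range(200):
        kappa = float(np.log((w * np.exp(d)).sum()))
        sd_marg = np.sqrt(v + var_extra + p * (1 - p) * (d - kappa) ** 2)
        d_new = kappa + beta * v / sd_marg
        if np.max(np.abs(d_new - d)) < 1e-13:
            d = d_new
            break
        d = d_new
    return d, kappa


def _assign_plates(rng, status: np.ndarray, n_plates: int, confound: float) -> np.ndarray:
    n = len(status)
    if confound == 0.0:
        return rng.permutation(np.tile(np.arange(n_plates), n // n_plates + 1)[:n])
    # status-coupled categorical assignment: cases favour later plates
    j = np.arange(n_plates)
    plates = np.empty(n, dtype=int)
    for i, s in enumerate(status):
        logits = confound * j * (1.0 if s else -1.0) / max(1, n_plates - 1)
        w = np.exp(logits - logits.max())
        plates[i] = rng.choice(n_plates, p=w / w.sum())
    return plates


def simulate_cohort(
    cfg: SimulationConfig,
    cohort: CohortSpec | str,
    seed: int | None = None,
    effect_scale: float | None = None,
) -> tuple[CohortTable, GroundTruth]:
    """Generate one cohort table (raw-area scale) plus its ground truth."""
    if isinstance(cohort, str):
        matches = [c for c in cfg.cohorts if c.name == cohort]
        if not matches:
            raise ConfigError(f"no cohort named {cohort!r} in config")
        spec = matches[0]
    else:
        spec = cohort
    if effect_scale is None:
        idx = [c.name for c in cfg.cohorts].index(spec.name) if spec in cfg.cohorts else 0
        effect_scale = float(cfg.cohort_effect_scale[idx]) if spec in cfg.cohorts else 1.0
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    n = spec.n_cases + spec.n_controls
    status = np.array([1] * spec.n_cases + [0] * spec.n_controls)
    status = status[rng.permutation(n)]
    p_case = spec.n_cases / n

    mu = np.asarray(cfg.baseline_log_mean)
    sigma = np.asarray(cfg.log_sd)
    a = np.asarray(cfg.age_slope)
    b = np.asarray(cfg.sex_effect)
    beta = effect_scale * np.asarray(cfg.disease_logor_per_sd)
    weights = np.exp(mu)

    if cfg.calibrate_effects:
        shift, kappa = _solve_latent_shifts(
            beta, sigma, weights, cfg.corr_rho, a, b,
            cfg.age_sd ** 2, cfg.female_fraction * (1 - cfg.female_fraction), p_case,
        )
    else:
        shift, kappa = beta * sigma, 0.0

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18.0, 85.0)
    sex_male = rng.random(n) >= cfg.female_fraction
    plates = _assign_plates(rng, status, spec.n_plates, cfg.confound_strength)
    plate_loc = rng.normal(0.0, cfg.batch_loc_sd, size=(spec.n_plates, N_PEAKS))
    plate_scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=(spec.n_plates, N_PEAKS)))

    # correlated noise: exchangeable correlation via shared + idiosyncratic parts
    rho = cfg.corr_rho
    common = rng.standard_normal((n, 1))
    noise = (np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal((n, N_PEAKS)))
    noise = noise * sigma[None, :] * plate_scale[plates]

    severity = np.where(status == 1, rng.standard_normal(n), np.nan)
    load = np.asarray(cfg.severity_loading)
    sev_term = np.where(status[:, None] == 1, np.nan_to_num(severity)[:, None] * load[None, :], 0.0)

    latent = (
        mu[None, :]
        + (age - cfg.age_mean)[:, None] * a[None, :]
        + sex_male[:, None] * b[None, :]
        + status[:, None] * shift[None, :]
        + sev_term
        + plate_loc[plates]
        + noise
    )
    percent = 100.0 * np.exp(latent) / np.exp(latent).sum(axis=1)[:, None]
    totals = np.exp(rng.normal(cfg.total_area_log_mean, cfg.total_area_log_sd, size=n))
    areas = percent / 100.0 * totals[:, None]

    # clinical flags for cases from latent severity; controls carry NA
    thr = {"ana": -0.5244005, "pericarditis": 0.6744898, "proteinuria": 0.3853205}
    mix = {"ana": 0.8, "pericarditis": 0.7, "proteinuria": 0.7}
    flags = {}
    for key in thr:
        z = mix[key] * np.nan_to_num(severity) + np.sqrt(1 - mix[key] ** 2) * rng.standard_normal(n)
        flags[key] = np.where(status == 1, (z > thr[key]).astype(float), np.nan)
    dur_lat = 0.3 * np.nan_to_num(severity) + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(n)
    duration = np.where(status == 1, np.exp(1.8 + 0.7 * dur_lat), np.nan)

    frame = pd.DataFrame({
        "sample_id": [f"{spec.name}_{i:04d}" for i in range(n)],
        "cohort": spec.name,
        "plate": [f"plate{j + 1}" for j in plates],
        "age": np.round(age, 1),
        "sex": np.where(sex_male, "M", "F"),
        "status": np.where(status == 1, "case", "control"),
        "ana": flags["ana"],
        "pericarditis": flags["pericarditis"],
        "proteinuria": flags["proteinuria"],
        "duration_years": np.round(duration, 2),
    })
    for k, peak in enumerate(PEAKS):
        frame[peak] = areas[:, k]

    table = CohortTable(
        frame, scale="raw_area", name=spec.name,
        provenance={"synthetic": True, "seed": int(cfg.seed if seed is None else seed)},
    )
    truth = GroundTruth(
        cohort=spec.name, seed=int(cfg.seed if seed is None else seed),
        beta_target=beta, latent_shift=shift, closure_shift=kappa,
        plate_loc=plate_loc, plate_scale=plate_scale, severity=severity,
        age_slope=a, sex_effect=b,
        symptom_model={"thresholds": thr, "loadings": mix,
                       "duration_loading": 0.3, "duration_log_mean": 1.8,
                       "duration_log_sd": 0.7},
    )
    return table, truth


def simulate_multi_cohort(cfg: SimulationConfig) -> list[tuple[CohortTable, GroundTruth]]:
    """Generate every cohort in the config with independent derived seeds."""
    cfg.covariance()  # validates PSD up front
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.cohorts))
    out = []
    for spec, child, scale in zip(cfg.cohorts, children, cfg.cohort_effect_scale):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(simulate_cohort(cfg, spec, seed=sub_seed, effect_scale=float(scale)))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write four canonical small fixtures plus a manifest of seeds and truths.

    Fixtures: ``null`` (no effects), ``planted`` (default demo effect
    pattern), ``batch_confounded`` (null effects, status-coupled plates),
    ``severity_coupled`` (effects plus severity loadings).  Re-running with
    the same seed reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    small = (CohortSpec("fixture", 100, 100, 3),)
    configs = {
        "null": SimulationConfig.null(seed=seed, cohorts=small, cohort_effect_scale=(1.0,)),
        "planted": replace(
            SimulationConfig.default(seed=seed + 1),
            cohorts=(CohortSpec("fixture", 150, 150, 3),), cohort_effect_scale=(1.0,),
        ),
        "batch_confounded": SimulationConfig.batch_confounded(seed=seed + 2),
        "severity_coupled": replace(
            SimulationConfig.default(seed=seed + 3),
            cohorts=(CohortSpec("fixture", 150, 150, 3),), cohort_effect_scale=(1.0,),
        ),
    }
    manifest = {"suite_seed": seed, "datasets": {}}
    for name, cfg in configs.items():
        table, truth = simulate_multi_cohort(cfg)[0]
        path = out / f"{name}.tsv"
        write_cohort_table(table, path)
        manifest["datasets"][name] = {
            "file": path.name,
            "sha256": _sha256(path),
            "seed": truth.seed,
            "n_cases": table.n_cases,
            "n_controls": table.n_controls,
            "beta_target": [float(v) for v in truth.beta_target],
            "latent_shift": [float(v) for v in truth.latent_shift],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
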