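"""Synthetic cortisol profiles and metabolite matrices with planted structure.

The generator emulates the study conditions of a randomized crossover trial
of hydrocortisone replacement in primary adrenal insufficiency:

* **Cortisol profiles** are sums of Bateman-type first-order
  absorption/elimination pulses on the trial's 8-point sampling grid
  (baseline, 25 min, 2, 4, 8, 12, 16 and 24 h after the first intake).
  The thrice-daily (TID) regimen doses at 0, 4 and 8 h; the once-daily (OD)
  dual-release regimen is a fast pulse plus a slow-release pulse at time 0,
  giving a rapid morning rise followed by a gradual decline.  Default dose
  scales are calibrated so the regimen-mean grid-trapezoid AUC_0-24h matches
  the trial's reported means (3851 OD vs 4698 TID nmol/L·h, an ~18% gap),
  and the OD shape is smoother (higher lag-1 autocorrelation) than TID.

* **Metabolite matrices** plant a known truth for recovery tests: each
  feature's log-abundance is ``intercept + beta_auc * z(AUC) +
  beta_auto * z(AUTO) + noise`` with the betas zeroed according to its class
  (AUC-only / AUTO-only / both / null), multiplicative log-normal noise,
  optional missingness, and the trial's platform layout (GC-MS serum,
  targeted LC-MS serum, untargeted LC-MS serum, targeted LC-MS urine).
  Serum platforms emit one sample per patient x period x timepoint; urine
  one per patient x period (24-h collection).  Identified features receive
  ids from the packaged synthetic pathway library, with AUC-only and
  AUTO-only features seeded into designated pathways so that pathway-level
  recovery is testable.

All randomness flows from explicit seeds; identical seeds give bit-identical
output.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .features import CortisolProfile, exposure_table
from .pathway import PathwayLibrary, load_default_library
from .preprocess import MetaboliteMatrix

__all__ = [
    "RegimenSpec",
    "EffectDesign",
    "OD_DEFAULT",
    "TID_DEFAULT",
    "DEFAULT_GRID",
    "DEFAULT_PLATFORM_PLAN",
    "TRIAL_SHAPED_CLASSES",
    "COMPACT_CLASSES",
    "simulate_profile",
    "simulate_cohort",
    "simulate_metabolome",
    "write_profiles_csv",
]

#: Trial sampling grid: baseline, 25 min, 2, 4, 8, 12, 16, 24 h (hours).
DEFAULT_GRID: tuple[float, ...] = (0.0, 5.0 / 12.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0)

GROUND_TRUTH_CLASSES = ("auc_only", "auto_only", "both", "none")

#: platform -> biological matrix
DEFAULT_PLATFORM_PLAN: dict[str, str] = {
    "GCMS_serum": "serum",
    "LCMS_targeted_serum": "serum",
    "LCMS_untargeted_serum": "serum",
    "LCMS_targeted_urine": "urine",
}

#: Planted class layout mirroring the trial's per-platform detection and
#: correlation counts (detected / AUC-correlated / AUTO-correlated / overlap:
#: 126/55/24/12, 209/87/49/21, 1938/610/402/172, 143/21/2/0).
TRIAL_SHAPED_CLASSES: dict[str, dict[str, int]] = {
    "GCMS_serum": {"auc_only": 43, "auto_only": 12, "both": 12, "none": 59},
    "LCMS_targeted_serum": {"auc_only": 66, "auto_only": 28, "both": 21, "none": 94},
    "LCMS_untargeted_serum": {"auc_only": 438, "auto_only": 230, "both": 172, "none": 1098},
    "LCMS_targeted_urine": {"auc_only": 21, "auto_only": 2, "both": 0, "none": 120},
}

#: Small single-platform layout for quick recovery experiments.
COMPACT_CLASSES: dict[str, dict[str, int]] = {
    "GCMS_serum": {"auc_only": 20, "auto_only": 20, "both": 10, "none": 30},
}

#: Library pathways into which planted effects are seeded, per biological
#: matrix (amino-acid-like vs bile-acid-like pathways for serum; the urine
#: analysis surfaces different chemistry).
SEED_PATHWAYS: dict[str, dict[str, str]] = {
    "serum": {"auc_only": "PW01", "auto_only": "PW02"},
    "urine": {"auc_only": "PW08", "auto_only": "PW07"},
}


class RegimenSpec(BaseModel):
    """Pharmacokinetic shape of one dosing regimen (sum of Bateman pulses)."""

    model_config = ConfigDict(frozen=True)

    regimen_label: Literal["OD", "TID"]
    dose_times_h: tuple[float, ...]
    absorption_rate: float = Field(2.0, gt=0, description="fast-pulse ka, 1/h")
    elimination_rate: float = Field(0.35, gt=0, description="ke, 1/h")
    dose_scale: float = Field(..., ge=0, description="pulse amplitude, nmol/L")
    sustained_fraction: float = Field(0.0, ge=0, le=1)
    sustained_rate: float = Field(0.5, gt=0, description="slow-release ka, 1/h (OD)")

    @model_validator(mode="after")
    def _check(self) -> "RegimenSpec":
        if any(not 0 <= t < 24 for t in self.dose_times_h):
            raise ValueError("dose times must lie in [0, 24)")
        if self.absorption_rate <= self.elimination_rate:
            raise ValueError("absorption must be faster than elimination (ka > ke)")
        if self.sustained_fraction > 0 and self.sustained_rate <= self.elimination_rate:
            raise ValueError("sustained-release absorption must exceed elimination")
        return self


# Dose scales calibrated so the regimen-mean AUC_0-24h on DEFAULT_GRID equals
# the trial means (3851 / 4698 nmol/L·h).
OD_DEFAULT = RegimenSpec(
    regimen_label="OD", dose_times_h=(0.0,), dose_scale=2646.04, sustained_fraction=0.6
)
TID_DEFAULT = RegimenSpec(regimen_label="TID", dose_times_h=(0.0, 4.0, 8.0), dose_scale=932.46)


class EffectDesign(BaseModel):
    """Planted-effect design for the synthetic metabolome."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(18, ge=1)
    features_per_class: Mapping[str, Mapping[str, int]] = TRIAL_SHAPED_CLASSES
    beta_auc: float = 0.8
    beta_auto: float = 0.8
    noise_sd: float = Field(0.5, gt=0)
    missing_rate: float = Field(0.02, ge=0, lt=1)
    hmdb_coverage: float = Field(0.35, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EffectDesign":
        for platform, counts in self.features_per_class.items():
            for cls, n in counts.items():
                if cls not in GROUND_TRUTH_CLASSES:
                    raise ValueError(f"unknown class {cls!r} for platform {platform}")
                if n < 0:
                    raise ValueError("class counts must be nonnegative")
        return self


def _bateman(dt: np.ndarray, ka: float, ke: float) -> np.ndarray:
    """A(e^{-ke dt} - e^{-ka dt}) shape for dt >= 0, 0 before the dose."""
    dt = np.maximum(np.asarray(dt, float), 0.0)
    out = np.exp(-ke * dt) - np.exp(-ka * dt)
    out[np.asarray(dt) <= 0] = 0.0
    return out


def _pulse_sum(spec: RegimenSpec, t: np.ndarray) -> np.ndarray:
    c = np.zeros_like(t, dtype=float)
    fast_w = 1.0 - spec.sustained_fraction
    for d in spec.dose_times_h:
        c += spec.dose_scale * fast_w * _bateman(t - d, spec.absorption_rate, spec.elimination_rate)
        if spec.sustained_fraction > 0:
            c += (
                spec.dose_scale
                * spec.sustained_fraction
                * _bateman(t - d, spec.sustained_rate, spec.elimination_rate)
            )
    return c


def simulate_profile(
    spec: RegimenSpec,
    grid=DEFAULT_GRID,
    jitter_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    *,
    patient_id: str = "P01",
    period: int = 1,
) -> CortisolProfile:
    """One cortisol profile on ``grid`` with truncated-Gaussian assay jitter.

    ``grid`` must be strictly increasing, start at 0 and end at 24 h.  Noise
    is additive Gaussian (SD ``jitter_sd`` nmol/L) truncated at zero, so
    concentrations stay nonnegative.
    """
    t = np.asarray(grid, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("sampling grid must be strictly increasing")
    if t[0] != 0 or t[-1] != 24:
        raise ValueError("sampling grid must start at 0 and end at 24 h")
    c = _pulse_sum(spec, t)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        c = np.maximum(c + rng.normal(0.0, jitter_sd, size=t.shape), 0.0)
    return CortisolProfile(
        patient_id=patient_id, period=period, regimen=spec.regimen_label, times_h=t, conc_nmol_l=c
    )


def simulate_cohort(
    n_patients: int = 18,
    seed: int = 0,
    *,
    od_spec: RegimenSpec = OD_DEFAULT,
    tid_spec: RegimenSpec = TID_DEFAULT,
    grid=DEFAULT_GRID,
    jitter_sd: float = 15.0,
    amplitude_cv: float = 0.2,
    rate_cv: float = 0.08,
) -> tuple[list[CortisolProfile], pd.DataFrame]:
    """Crossover cohort: every patient is sampled on both regimens.

    Patient-level pharmacokinetic heterogeneity is log-normal: one shared
    amplitude multiplier per patient (geometric CV ``amplitude_cv``, applied
    to both regimens) and per-patient rate multipliers (CV ``rate_cv``).
    Treatment sequence (OD first vs TID first) alternates deterministically
    across the enrolment order after a seeded shuffle.

    Returns the profiles and a cohort table (patient_id, sequence).
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    sequences = np.array(["OD_first", "TID_first"])[
        rng.permutation(np.arange(n_patients) % 2)
    ]
    profiles: list[CortisolProfile] = []
    meta = []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        amp = rng.lognormal(mean=0.0, sigma=amplitude_cv)
        ka_mult = rng.lognormal(0.0, rate_cv)
        ke_mult = rng.lognormal(0.0, rate_cv)
        seq = sequences[i]
        meta.append({"patient_id": pid, "sequence": seq})
        for period, label in enumerate(("OD", "TID") if seq == "OD_first" else ("TID", "OD"), 1):
            base = od_spec if label == "OD" else tid_spec
            spec = base.model_copy(
                update={
                    "dose_scale": base.dose_scale * amp,
                    "absorption_rate": base.absorption_rate * ka_mult,
                    "elimination_rate": base.elimination_rate * ke_mult,
                }
            )
            profiles.append(
                simulate_profile(
                    spec,
                    grid,
                    jitter_sd=jitter_sd,
                    seed=np.random.SeedSequence(seed, spawn_key=(i, period)),
                    patient_id=pid,
                    period=period,
                )
            )
    return profiles, pd.DataFrame(meta)


def _assign_hmdb(
    classes: pd.Series,
    matrix_kind: str,
    library: PathwayLibrary,
    coverage: float,
    rng: np.random.Generator,
) -> list[str | None]:
    """Database ids for identified features; planted classes seed designated pathways.

    Only a ``coverage`` fraction of the non-seeded features receives an id —
    mirroring that just a minority of detected metabolites carry a confident,
    unique database identifier — so mapped DEM lists stay a minority of the
    library universe and over-representation has contrast to work with.
    """
    seeds = SEED_PATHWAYS.get(matrix_kind, {})
    designated = {cls: sorted(library.pathways[pid].members) for cls, pid in seeds.items()}
    reserved = {m for ms in designated.values() for m in ms}
    pool = sorted(set(library.universe) - reserved)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    queues = {cls: iter(ms) for cls, ms in designated.items()}
    out: list[str | None] = []
    for cls in classes:
        assigned = next(queues[cls], None) if cls in queues else None
        if assigned is None and rng.random() < coverage:
            assigned = next(pool_iter, None)
        out.append(assigned)
    return out


def simulate_metabolome(
    metrics: pd.DataFrame,
    design: EffectDesign,
    platform_plan: Mapping[str, str] = DEFAULT_PLATFORM_PLAN,
    *,
    grid=DEFAULT_GRID,
    library: PathwayLibrary | None = None,
) -> tuple[dict[str, MetaboliteMatrix], pd.DataFrame]:
    """Metabolite matrices per platform plus the planted ground truth.

    ``metrics`` is the per patient x period exposure table (columns
    patient_id, period, regimen, auc_0_24, auto_lag1).  For each feature,
    log-abundance = intercept + beta_auc * z(AUC) + beta_auto * z(AUTO) +
    Normal(0, noise_sd) noise per sample, with the betas zeroed by class and
    alternating in sign across planted features.  Values are exponentiated
    (log-normal abundances); ``missing_rate`` of entries are then blanked.

    Returns ``(matrices, truth)`` where truth has one row per feature:
    feature_id, platform, class, beta_auc, beta_auto, hmdb_id.
    """
    required = {"patient_id", "period", "regimen", "auc_0_24", "auto_lag1"}
    if missing := required - set(metrics.columns):
        raise ValueError(f"metrics missing columns: {sorted(missing)}")
    if metrics[["auc_0_24", "auto_lag1"]].isna().any().any():
        raise ValueError("metrics contain missing exposure values")
    if unknown := set(design.features_per_class) - set(platform_plan):
        raise ValueError(f"platforms without a plan entry: {sorted(unknown)}")
    if library is None:
        library = load_default_library()

    met = metrics.reset_index(drop=True)
    z = {}
    for name, col in (("auc", "auc_0_24"), ("auto", "auto_lag1")):
        v = met[col].to_numpy(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"{col} has zero variance across patient x period")
        z[name] = (v - v.mean()) / sd

    root = np.random.SeedSequence(design.seed)
    matrices: dict[str, MetaboliteMatrix] = {}
    truth_rows = []
    sample_times = [t for t in grid]

    for p_idx, (platform, counts) in enumerate(sorted(design.features_per_class.items())):
        rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(p_idx,)))
        matrix_kind = platform_plan[platform]
        untargeted = "untargeted" in platform

        cls_list: list[str] = []
        for cls in GROUND_TRUTH_CLASSES:
            cls_list += [cls] * counts.get(cls, 0)
        n_features = len(cls_list)
        if n_features == 0:
            continue
        fids = [f"{platform}:F{k + 1:04d}" for k in range(n_features)]
        classes = pd.Series(cls_list, index=fids, name="class")

        # alternating-sign planted slopes
        beta_a = np.zeros(n_features)
        beta_t = np.zeros(n_features)
        sign = 1.0
        for k, cls in enumerate(cls_list):
            if cls in ("auc_only", "both"):
                beta_a[k] = sign * design.beta_auc
            if cls in ("auto_only", "both"):
                beta_t[k] = sign * design.beta_auto
            if cls != "null":
                sign = -sign

        if matrix_kind == "serum":
            reps = len(sample_times)
            sample_ids = [
                f"{pid}_p{per}_t{ti}"
                for pid, per in zip(met["patient_id"], met["period"])
                for ti in range(reps)
            ]
            obs_idx = np.repeat(np.arange(len(met)), reps)
            time_h = np.tile(sample_times, len(met))
        else:
            sample_ids = [f"{pid}_p{per}_u24" for pid, per in zip(met["patient_id"], met["period"])]
            obs_idx = np.arange(len(met))
            time_h = np.full(len(met), np.nan)

        # baseline log-abundances span several decades, as MS intensities do;
        # planted shifts then rarely reorder features within a sample
        intercept = rng.normal(5.0, 3.0, size=n_features)
        mean_log = (
            intercept[None, :]
            + np.outer(z["auc"][obs_idx], beta_a)
            + np.outer(z["auto"][obs_idx], beta_t)
        )
        log_ab = mean_log + rng.normal(0.0, design.noise_sd, size=mean_log.shape)
        values = np.exp(log_ab)
        if design.missing_rate > 0:
            # left-censored missingness: each feature's lowest values fall
            # below its detection limit (the mechanism min/5 imputation assumes)
            n_obs_rows = values.shape[0]
            for col in range(values.shape[1]):
                k = rng.binomial(n_obs_rows, design.missing_rate)
                if k:
                    cutoff_idx = np.argsort(values[:, col])[:k]
                    values[cutoff_idx, col] = np.nan

        if untargeted:
            hmdb: list[str | None] = [None] * n_features
            id_level = 2
            annot = [f"{200 + rng.integers(0, 800)}.{rng.integers(0, 9999):04d}@{rng.uniform(0.5, 12):.2f}min" for _ in fids]
        else:
            hmdb = _assign_hmdb(classes, matrix_kind, library, design.hmdb_coverage, rng)
            id_level = 1
            annot = [f"{platform.split('_')[0]} compound {k + 1}" for k in range(n_features)]

        feature_meta = pd.DataFrame(
            {
                "platform": platform,
                "matrix": matrix_kind,
                "id_level": id_level,
                "hmdb_id": hmdb,
                "annotation": annot,
            },
            index=pd.Index(fids, name="feature_id"),
        )
        sample_meta = pd.DataFrame(
            {
                "patient_id": met["patient_id"].to_numpy()[obs_idx],
                "period": met["period"].to_numpy()[obs_idx],
                "regimen": met["regimen"].to_numpy()[obs_idx],
                "time_h": time_h,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        matrices[platform] = MetaboliteMatrix(
            values=pd.DataFrame(values, index=sample_meta.index, columns=fids),
            sample_meta=sample_meta,
            feature_meta=feature_meta,
            state="raw",
        )
        for k, fid in enumerate(fids):
            truth_rows.append(
                {
                    "feature_id": fid,
                    "platform": platform,
                    "class": cls_list[k],
                    "beta_auc": beta_a[k],
                    "beta_auto": beta_t[k],
                    "hmdb_id": hmdb[k],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return matrices, truth


def write_profiles_csv(profiles: list[CortisolProfile], path) -> None:
    """Long-format CSV: patient_id, period, regimen, time_h, cortisol_nmol_L."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times_h, p.conc_nmol_l):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "period": p.period,
                    "regimen": p.regimen,
                    "time_h": t,
                    "cortisol_nmol_L": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_exposure(profiles: list[CortisolProfile]) -> pd.DataFrame:
    """Convenience: per patient x period exposure metrics for a cohort."""
    metrics, _ = exposure_table(profiles)
    return metrics
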