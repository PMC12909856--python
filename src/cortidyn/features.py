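"""Cortisol exposure and time-profile-variability metrics.

A 24-hour serum cortisol sampling day yields one concentration time series per
patient and treatment period.  Two scalar features summarise it:

* **total / partial exposure** — the area under the concentration–time curve
  (trapezoidal rule) over 0–24 h and the windows 0–4 h, 4–10 h and 10–24 h,
  in nmol/L·h;
* **time-profile variability (AUTO)** — the lag-1 sample autocorrelation of
  the series.  Values near 1 indicate a smooth, stable profile; lower values
  indicate pronounced intra-day fluctuation.

Exposure and AUTO are deliberately different axes: multiplying every
concentration by a constant scales every AUC but leaves AUTO unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CortisolProfile",
    "ExposureMetrics",
    "ZeroVarianceError",
    "trapezoid_auc",
    "lag1_autocorrelation",
    "compute_exposure",
    "exposure_table",
    "percent_difference",
    "read_profiles_csv",
    "write_metrics_tsv",
    "DEFAULT_WINDOWS",
]

#: Partial-exposure windows reported alongside the 0–24 h total (hours).
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 4.0), (4.0, 10.0), (10.0, 24.0))


class ZeroVarianceError(ValueError):
    """Raised when a statistic is undefined because the series is constant."""


@dataclass(frozen=True)
class CortisolProfile:
    """One patient x period serum cortisol time series.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    period : int
        Treatment period, 1 or 2.
    regimen : str
        ``"OD"`` (once-daily dual-release) or ``"TID"`` (thrice-daily).
    times_h : ndarray
        Sampling times in hours; strictly increasing, starting at 0,
        within [0, 24].
    conc_nmol_l : ndarray
        Serum cortisol concentrations (nmol/L); nonnegative, same length.
    """

    patient_id: str
    period: int
    regimen: str
    times_h: np.ndarray = field(repr=False)
    conc_nmol_l: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_nmol_l, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and the same length")
        if t.size < 3:
            raise ValueError("a profile needs at least 3 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("the first sampling time must be 0 (pre-dose baseline)")
        if t[-1] > 24 + 1e-9:
            raise ValueError("sampling times must lie within [0, 24] hours")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and nonnegative")
        if self.period not in (1, 2):
            raise ValueError("period must be 1 or 2")
        if self.regimen not in ("OD", "TID"):
            raise ValueError("regimen must be 'OD' or 'TID'")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_nmol_l", c)


@dataclass(frozen=True)
class ExposureMetrics:
    """Exposure (AUC windows, nmol/L·h) and variability (AUTO) of one profile."""

    auc_0_24: float
    auc_0_4: float
    auc_4_10: float
    auc_10_24: float
    auto_lag1: float

    def __post_init__(self) -> None:
        for name in ("auc_0_24", "auc_0_4", "auc_4_10", "auc_10_24"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 - 1e-12 <= self.auto_lag1 <= 1.0 + 1e-12:
            raise ValueError("auto_lag1 must lie in [-1, 1]")
        total = self.auc_0_4 + self.auc_4_10 + self.auc_10_24
        if not np.isclose(total, self.auc_0_24, rtol=1e-9, atol=1e-6):
            raise ValueError("partial AUCs must sum to the total AUC")


def trapezoid_auc(profile: CortisolProfile, window: tuple[float, float] = (0.0, 24.0)) -> float:
    """Trapezoidal AUC of the profile restricted to ``window`` (nmol/L·h).

    Window endpoints that do not coincide with sampling times are obtained by
    linear interpolation between the neighbouring samples, so that e.g. a
    4–10 h window is well defined on a grid with no 10 h sample.

    Raises
    ------
    ValueError
        If the window is empty or extends beyond the observed time range.
    """
    a, b = float(window[0]), float(window[1])
    t, c = profile.times_h, profile.conc_nmol_l
    if not a < b:
        raise ValueError(f"window must satisfy a < b, got [{a}, {b}]")
    if a < t[0] - 1e-12 or b > t[-1] + 1e-12:
        raise ValueError(f"window [{a}, {b}] outside observed range [{t[0]}, {t[-1]}]")
    inner = (t > a) & (t < b)
    tt = np.concatenate(([a], t[inner], [b]))
    cc = np.concatenate(([np.interp(a, t, c)], c[inner], [np.interp(b, t, c)]))
    if tt.size < 2:
        raise ValueError("fewer than 2 points in window")
    return float(np.trapezoid(cc, tt))


def lag1_autocorrelation(
    profile: CortisolProfile | Sequence[float], *, resample_hourly: bool = False
) -> float:
    """Lag-1 sample autocorrelation (AUTO) of a cortisol series.

    Uses the conventional biased sample ACF,

    .. math:: r_1 = \\frac{\\sum_{t=1}^{n-1}(x_t-\\bar x)(x_{t+1}-\\bar x)}
                          {\\sum_{t=1}^{n}(x_t-\\bar x)^2},

    computed on the observed series in sampling order.  The sampling grid is
    uneven; by default no resampling is performed — the statistic compares
    each observation with the next one regardless of the interval length.
    With ``resample_hourly=True`` the series is first linearly interpolated
    onto an hourly grid spanning the observed range.

    Raises
    ------
    ZeroVarianceError
        If the series is constant (the statistic is undefined).
    """
    if isinstance(profile, CortisolProfile):
        t, x = profile.times_h, profile.conc_nmol_l
    else:
        x = np.asarray(profile, dtype=float)
        t = np.arange(x.size, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if resample_hourly:
        grid = np.arange(t[0], t[-1] + 1e-9, 1.0)
        x = np.interp(grid, t, x)
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise ZeroVarianceError("lag-1 autocorrelation undefined for a constant series")
    r1 = float(d[:-1] @ d[1:]) / denom
    # |r1| <= (n-1)/n by Cauchy-Schwarz on the biased ACF; clip rounding only
    return float(np.clip(r1, -1.0, 1.0))


def compute_exposure(
    profile: CortisolProfile,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
    *,
    resample_hourly: bool = False,
) -> ExposureMetrics:
    """AUC_0-24h, the partial AUC windows and AUTO for one profile."""
    total = trapezoid_auc(profile, (windows[0][0], windows[-1][1]))
    parts = [trapezoid_auc(profile, w) for w in windows]
    return ExposureMetrics(
        auc_0_24=total,
        auc_0_4=parts[0],
        auc_4_10=parts[1],
        auc_10_24=parts[2],
        auto_lag1=lag1_autocorrelation(profile, resample_hourly=resample_hourly),
    )


_METRIC_COLS = ["auc_0_24", "auc_0_4", "auc_4_10", "auc_10_24", "auto_lag1"]


def percent_difference(mean_od: float, mean_tid: float) -> float:
    """How much lower the OD regimen mean is than the TID mean, in percent.

    ``100 * (mean_tid - mean_od) / mean_tid``; positive when OD is lower.
    """
    if mean_tid == 0:
        raise ValueError("TID mean must be nonzero")
    return 100.0 * (mean_tid - mean_od) / mean_tid


def exposure_table(
    profiles: Iterable[CortisolProfile], *, resample_hourly: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per patient x period exposure metrics plus a regimen-level summary.

    Returns
    -------
    metrics : DataFrame
        One row per profile: patient_id, period, regimen and the five metrics.
    summary : DataFrame
        One row per metric with mean/SD per regimen, the mean within-patient
        OD−TID difference (patients with both regimens), and — for the total
        exposure — the percent by which the OD regimen mean is lower than the
        TID mean.  With a single profile in a regimen the SD is reported as 0
        together with an ``sd_degenerate`` flag.
    """
    rows = []
    for p in profiles:
        m = compute_exposure(p, resample_hourly=resample_hourly)
        rows.append(
            {"patient_id": p.patient_id, "period": p.period, "regimen": p.regimen}
            | {k: getattr(m, k) for k in _METRIC_COLS}
        )
    if not rows:
        raise ValueError("no profiles supplied")
    metrics = pd.DataFrame(rows)
    for reg in ("OD", "TID"):
        if not (metrics["regimen"] == reg).any():
            raise ValueError(f"need at least one profile for regimen {reg}")

    wide = metrics.pivot_table(index="patient_id", columns="regimen", values=_METRIC_COLS)
    out = []
    for col in _METRIC_COLS:
        g = metrics.groupby("regimen")[col]
        mean, sd, n = g.mean(), g.std(ddof=1).fillna(0.0), g.size()
        diff = (wide[(col, "OD")] - wide[(col, "TID")]).dropna()
        row = {
            "metric": col,
            "mean_od": mean["OD"],
            "sd_od": sd["OD"],
            "n_od": int(n["OD"]),
            "mean_tid": mean["TID"],
            "sd_tid": sd["TID"],
            "n_tid": int(n["TID"]),
            "mean_within_patient_od_minus_tid": diff.mean() if len(diff) else np.nan,
            "sd_degenerate": bool(n["OD"] < 2 or n["TID"] < 2),
        }
        if col == "auc_0_24":
            row["pct_lower_od_vs_tid"] = percent_difference(mean["OD"], mean["TID"])
        out.append(row)
    return metrics, pd.DataFrame(out)


def read_profiles_csv(path) -> list[CortisolProfile]:
    """Read long-format profiles (patient_id, period, regimen, time_h, cortisol_nmol_L)."""
    df = pd.read_csv(path)
    required = {"patient_id", "period", "regimen", "time_h", "cortisol_nmol_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for (pid, period, reg), grp in df.groupby(["patient_id", "period", "regimen"], sort=True):
        grp = grp.sort_values("time_h")
        profiles.append(
            CortisolProfile(
                patient_id=str(pid),
                period=int(period),
                regimen=str(reg),
                times_h=grp["time_h"].to_numpy(float),
                conc_nmol_l=grp["cortisol_nmol_L"].to_numpy(float),
            )
        )
    return profiles


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False)
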