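"""Metabolite-matrix container and the concentration-data pre-processing chain.

The chain mirrors standard metabolomics practice for compound concentration
tables: impute missing/zero entries from each feature's detection floor,
discard near-constant features by relative standard deviation, quantile
normalise samples to a common intensity distribution, then log-transform and
autoscale each metabolite to mean 0 / SD 1.  Each platform (GC-MS serum,
targeted LC-MS serum, untargeted LC-MS serum, targeted LC-MS urine) is
processed independently.

Every feature drop is recorded in a drop log with a stage and reason code, and
the whole chain is deterministic: the same input yields bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteMatrix",
    "replace_missing",
    "rsd_filter",
    "quantile_normalize",
    "log_and_autoscale",
    "preprocess_chain",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "STATES",
]

#: Allowed processing states, in order.
STATES = ("raw", "filtered", "normalized", "scaled")

FEATURE_META_COLS = ["platform", "matrix", "id_level", "hmdb_id", "annotation"]

_EMPTY_LOG = pd.DataFrame(columns=["feature_id", "stage", "reason"])


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Samples x features abundance table with metadata and a processing state.

    ``values`` has sample ids as the index and feature ids as columns.
    ``sample_meta`` (indexed by sample id) carries patient_id, period, regimen
    and, for serum samples, time_h.  ``feature_meta`` (indexed by feature id)
    carries platform, matrix (serum/urine), id_level (1 = confidently
    identified), hmdb_id and an annotation label.  ``state`` advances only
    along raw -> filtered -> normalized -> scaled.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    state: str = "raw"
    drop_log: pd.DataFrame = field(default_factory=lambda: _EMPTY_LOG.copy())

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.empty:
            raise ValueError("empty matrix")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not self.values.index.isin(self.sample_meta.index).all():
            raise ValueError("sample_meta missing entries for some samples")
        if not self.values.columns.isin(self.feature_meta.index).all():
            raise ValueError("feature_meta missing entries for some features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def _advance(self, new_state: str, values: pd.DataFrame, dropped: pd.DataFrame) -> "MetaboliteMatrix":
        if STATES.index(new_state) < STATES.index(self.state):
            raise ValueError(f"cannot move from state {self.state!r} back to {new_state!r}")
        return replace(
            self,
            values=values,
            feature_meta=self.feature_meta.loc[values.columns],
            state=new_state,
            drop_log=pd.concat([self.drop_log, dropped], ignore_index=True),
        )


def _drop_frame(feature_ids, stage: str, reason: str) -> pd.DataFrame:
    if len(feature_ids) == 0:
        return _EMPTY_LOG.copy()
    return pd.DataFrame({"feature_id": list(feature_ids), "stage": stage, "reason": reason})


def replace_missing(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each feature's missing/zero entries by min(positive values)/5.

    Features with no positive value at all carry no information about a
    detection floor and are dropped (logged with reason ``no_positive_values``).
    The state stays ``raw``; imputation does not advance the chain.
    """
    if m.state != "raw":
        raise ValueError(f"replace_missing expects a raw matrix, got {m.state!r}")
    v = m.values.copy()
    no_positive = []
    for fid in v.columns:
        col = v[fid]
        pos = col[col > 0]
        if pos.empty:
            no_positive.append(fid)
            continue
        fill = pos.min() / 5.0
        v[fid] = col.where((col > 0) & col.notna(), fill)
    if no_positive:
        logger.warning("replace_missing: dropping %d feature(s) with no positive values", len(no_positive))
        v = v.drop(columns=no_positive)
        if v.empty:
            raise ValueError("no features left after dropping all-nonpositive features")
    return m._advance("raw", v, _drop_frame(no_positive, "replace_missing", "no_positive_values"))


def rsd_filter(
    m: MetaboliteMatrix,
    *,
    keep_fraction: float | None = None,
    rsd_threshold: float | None = None,
) -> MetaboliteMatrix:
    """Remove low-variation features by relative standard deviation (SD/mean).

    Exactly one mode must be given: ``rsd_threshold`` removes features with
    RSD strictly below the threshold; ``keep_fraction`` removes the
    lowest-RSD ``1 - keep_fraction`` of features (``keep_fraction=1`` keeps
    everything).
    """
    if m.values.isna().any().any():
        raise ValueError("rsd_filter requires a matrix without missing values")
    if (keep_fraction is None) == (rsd_threshold is None):
        raise ValueError("give exactly one of keep_fraction or rsd_threshold")
    sd = m.values.std(axis=0, ddof=1)
    mean = m.values.mean(axis=0)
    rsd = sd / mean.replace(0, np.nan)
    rsd = rsd.fillna(0.0)
    if rsd_threshold is not None:
        if rsd_threshold <= 0:
            raise ValueError("rsd_threshold must be positive")
        drop = rsd.index[rsd < rsd_threshold]
    else:
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        n_drop = int(np.floor((1.0 - keep_fraction) * m.n_features + 1e-9))
        # stable sort: ties resolved by feature order, keeping the run deterministic
        drop = rsd.sort_values(kind="stable").index[:n_drop]
    v = m.values.drop(columns=drop)
    if v.empty:
        raise ValueError("no features left after RSD filtering")
    return m._advance("filtered", v, _drop_frame(drop, "rsd_filter", "low_rsd"))


def quantile_normalize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Force every sample's value distribution onto the mean quantile vector.

    The reference distribution is the across-sample mean of the per-sample
    sorted value vectors; each sample's values are replaced by the reference
    value at their rank, with ties receiving the mean of the reference values
    at the tied rank positions.  Afterwards all per-sample means are equal.
    """
    if m.state != "filtered":
        raise ValueError(f"quantile_normalize expects a filtered matrix, got {m.state!r}")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy(float)
    n = x.shape[1]
    reference = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for i in range(x.shape[0]):
        ranks = rankdata(x[i], method="average")
        out[i] = np.interp(ranks, positions, reference)
    v = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m._advance("normalized", v, _EMPTY_LOG.copy())


def log_and_autoscale(m: MetaboliteMatrix, *, base: float | None = None) -> MetaboliteMatrix:
    """Log-transform (natural log by default) then z-score each feature.

    Every retained feature ends with mean 0 and sample SD 1 (ddof=1).
    Features that are constant after the log are dropped (reason
    ``zero_variance``); nonpositive entries are an error — run
    :func:`replace_missing` first.
    """
    if m.state != "normalized":
        raise ValueError(f"log_and_autoscale expects a normalized matrix, got {m.state!r}")
    if (m.values <= 0).any().any():
        raise ValueError("log transform requires strictly positive values")
    logged = np.log(m.values.to_numpy(float))
    if base is not None:
        logged = logged / np.log(base)
    v = pd.DataFrame(logged, index=m.values.index, columns=m.values.columns)
    sd = v.std(axis=0, ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var):
        logger.warning("log_and_autoscale: dropping %d zero-variance feature(s)", len(zero_var))
        v = v.drop(columns=zero_var)
        sd = sd.drop(zero_var)
    if v.empty:
        raise ValueError("no features left after dropping zero-variance features")
    v = (v - v.mean(axis=0)) / sd
    return m._advance("scaled", v, _drop_frame(zero_var, "log_and_autoscale", "zero_variance"))


def preprocess_chain(
    m: MetaboliteMatrix,
    *,
    keep_fraction: float | None = 0.9,
    rsd_threshold: float | None = None,
    quantile: bool = True,
    log_base: float | None = None,
) -> MetaboliteMatrix:
    """Full chain: replace missing -> RSD filter -> quantile normalise -> log+autoscale.

    ``quantile=False`` skips the cross-sample quantile normalisation (the
    state still advances).  Quantile normalisation transfers signal between
    features when a large share of them shift strongly with the same
    covariate — rank crowding hands a feature's displacement to its
    neighbours — so analyses that need exact per-feature effect attribution
    may prefer to disable it.
    """
    m = replace_missing(m)
    m = rsd_filter(m, keep_fraction=keep_fraction, rsd_threshold=rsd_threshold)
    if quantile:
        m = quantile_normalize(m)
    else:
        m = m._advance("normalized", m.values, _EMPTY_LOG.copy())
    return log_and_autoscale(m, base=log_base)


# ---------------------------------------------------------------------------
# TSV round-trip (features as rows with metadata columns, samples as columns)

def write_matrix_tsv(m: MetaboliteMatrix, matrix_path, samples_path=None) -> None:
    """Write the matrix as TSV (rows=features with metadata; columns=samples)."""
    meta = m.feature_meta.reindex(columns=FEATURE_META_COLS)
    table = pd.concat([meta, m.values.T], axis=1)
    table.index.name = "feature_id"
    table.to_csv(matrix_path, sep="\t")
    if samples_path is not None:
        sm = m.sample_meta.copy()
        sm.index.name = "sample_id"
        sm.to_csv(samples_path, sep="\t")


def read_matrix_tsv(matrix_path, samples_path, state: str = "raw") -> MetaboliteMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`."""
    table = pd.read_csv(matrix_path, sep="\t", index_col="feature_id")
    meta = table[[c for c in FEATURE_META_COLS if c in table.columns]]
    values = table.drop(columns=meta.columns).astype(float).T
    values.index.name = "sample_id"
    values.columns.name = None
    sample_meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    sample_meta = sample_meta.loc[values.index]
    return MetaboliteMatrix(
        values=values, sample_meta=sample_meta, feature_meta=meta, state=state
    )
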