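"""Paired nonparametric tests for the crossover design.

Within-patient OD−TID differences are the analysis unit.  Sequence effects
(OD-first vs TID-first) are probed with a two-sample permutation test on the
differences; paired location shifts with the Wilcoxon signed-rank test; and
ordinal/dichotomous outcomes with the exact sign test.  All p-values are
two-sided; for the sign and permutation tests the smaller tail is doubled
and capped at 1.  Zero differences are dropped (and counted) per the usual
signed-rank/sign-test convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

__all__ = [
    "PairedOutcome",
    "wilcoxon_signed_rank",
    "permutation_two_sample",
    "sign_test",
    "sequence_effect_table",
]

EXACT_ENUMERATION_LIMIT = 20_000  # max number of group splits enumerated exactly
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedOutcome:
    """One patient's paired outcome under both regimens."""

    patient_id: str
    sequence: str  # "OD_first" | "TID_first"
    value_od: float
    value_tid: float

    @property
    def diff(self) -> float:
        return self.value_od - self.value_tid

    def __post_init__(self) -> None:
        if self.sequence not in ("OD_first", "TID_first"):
            raise ValueError("sequence must be 'OD_first' or 'TID_first'")


def _signed_rank_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2*W+ by dynamic programming over sign flips.

    ``scaled_ranks`` are midranks times 2, so they are integers even with
    ties.  Returns counts over achievable values 0..sum(scaled_ranks).
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs) -> dict:
    """Wilcoxon signed-rank test of median difference zero.

    Exact sign-flip permutation null (dynamic programming over midranks,
    tie-safe) for up to 25 nonzero differences; normal approximation with
    tie correction beyond that.  Zeros are dropped and reported.

    Returns ``{"W": W_plus, "p_two_sided": p, "n_nonzero": n, "n_zero": z,
    "mode": "exact"|"approx"}``.
    """
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    n = nz.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = pd.Series(np.abs(nz)).rank(method="average").to_numpy()
    w_plus = float(ranks[nz > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        scaled = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(scaled)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        p_ge = dist[w2:].sum() / total
        p_le = dist[: w2 + 1].sum() / total
        p = min(1.0, 2.0 * min(p_ge, p_le))
        mode = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_groups = pd.Series(ranks).value_counts()
        tie_term = ((tie_groups**3 - tie_groups).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        mode = "approx"
    return {"W": w_plus, "p_two_sided": float(p), "n_nonzero": n, "n_zero": n_zero, "mode": mode}


def permutation_two_sample(
    group_a, group_b, *, n_perm: int = 10_000, seed: int | None = None
) -> dict:
    """Two-sample permutation test on the difference of group means.

    All ``C(n, n_a)`` group relabelings are enumerated when there are at most
    20,000 of them; otherwise a seeded Monte-Carlo sample of relabelings is
    used (the observed split counts as one).  Two-sided by |difference of
    means|.

    Returns ``{"statistic", "p_two_sided", "mode", "n_perm"}``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = a.mean() - b.mean()
    tol = 1e-12 * max(1.0, abs(obs))
    if math.comb(n, na) <= EXACT_ENUMERATION_LIMIT:
        count = total = 0
        idx_all = frozenset(range(n))
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)]
            sb = pooled[list(idx_all - set(idx))]
            if abs(sa.mean() - sb.mean()) >= abs(obs) - tol:
                count += 1
            total += 1
        return {
            "statistic": float(obs),
            "p_two_sided": count / total,
            "mode": "exact",
            "n_perm": total,
        }
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= abs(obs) - tol:
            count += 1
    return {
        "statistic": float(obs),
        "p_two_sided": (count + 1) / (n_perm + 1),
        "mode": "monte_carlo",
        "n_perm": n_perm,
    }


def sign_test(values) -> dict:
    """Exact two-sided sign test (binomial at p = 1/2 on the nonzero signs).

    ``values`` may be signed differences or any +/−/0 coded outcome; zeros
    are dropped.  The smaller binomial tail is doubled and capped at 1.
    """
    v = np.asarray(values, dtype=float)
    nz = v[v != 0]
    if nz.size == 0:
        raise ValueError("no nonzero observations; the sign test is undefined")
    n = nz.size
    k = int((nz > 0).sum())
    p = min(1.0, 2.0 * min(binom.cdf(k, n, 0.5), binom.sf(k - 1, n, 0.5)))
    return {"n_positive": k, "n_negative": n - k, "n_zero": int(v.size - n), "p_two_sided": float(p)}


def sequence_effect_table(outcomes: pd.DataFrame, *, seed: int = 0) -> pd.DataFrame:
    """Sequence-effect and paired tests for each outcome in a long table.

    ``outcomes`` columns: patient_id, sequence, outcome_name, value_od,
    value_tid.  Per outcome: the Wilcoxon signed-rank test of the paired
    OD−TID differences, the sign test on their signs, and the permutation
    test comparing differences between OD-first and TID-first patients.
    """
    required = {"patient_id", "sequence", "outcome_name", "value_od", "value_tid"}
    if missing := required - set(outcomes.columns):
        raise ValueError(f"outcomes table missing columns: {sorted(missing)}")
    rows = []
    for name, grp in outcomes.groupby("outcome_name", sort=True):
        diffs = (grp["value_od"] - grp["value_tid"]).to_numpy(float)
        wil = wilcoxon_signed_rank(diffs)
        sg = sign_test(diffs)
        da = diffs[(grp["sequence"] == "OD_first").to_numpy()]
        db = diffs[(grp["sequence"] == "TID_first").to_numpy()]
        if da.size and db.size:
            perm = permutation_two_sample(da, db, seed=seed)
            p_seq, seq_mode = perm["p_two_sided"], perm["mode"]
        else:
            p_seq, seq_mode = np.nan, "unavailable"
        rows.append(
            {
                "outcome_name": name,
                "n_pairs": int(len(grp)),
                "mean_diff_od_minus_tid": float(np.mean(diffs)),
                "wilcoxon_W": wil["W"],
                "wilcoxon_p": wil["p_two_sided"],
                "wilcoxon_mode": wil["mode"],
                "sign_test_p": sg["p_two_sided"],
                "sequence_perm_p": p_seq,
                "sequence_perm_mode": seq_mode,
            }
        )
    return pd.DataFrame(rows)
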