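import numpy as np
import pandas as pd
import pytest

from cortidyn.features import CortisolProfile
from cortidyn.preprocess import MetaboliteMatrix

#: the trial's 8-point sampling grid (hours)
STUDY_GRID = np.array([0.0, 5.0 / 12.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0])


def make_profile(conc, times=None, patient_id="P01", period=1, regimen="OD"):
    t = STUDY_GRID if times is None else np.asarray(times, float)
    return CortisolProfile(
        patient_id=patient_id,
        period=period,
        regimen=regimen,
        times_h=t,
        conc_nmol_l=np.asarray(conc, float),
    )


def make_matrix(values, state="raw", platform="GCMS_serum", matrix_kind="serum",
                hmdb=None, id_level=1):
    """Small MetaboliteMatrix from a samples x features array."""
    values = np.asarray(values, float)
    n_samples, n_features = values.shape
    sids = [f"S{i}" for i in range(n_samples)]
    fids = [f"F{j}" for j in range(n_features)]
    sample_meta = pd.DataFrame(
        {
            "patient_id": [f"P{i % 4}" for i in range(n_samples)],
            "period": [1 + (i // 4) % 2 for i in range(n_samples)],
            "regimen": "OD",
            "time_h": 0.0,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    feature_meta = pd.DataFrame(
        {
            "platform": platform,
            "matrix": matrix_kind,
            "id_level": id_level,
            "hmdb_id": hmdb if hmdb is not None else [None] * n_features,
            "annotation": [f"compound {j}" for j in range(n_features)],
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return MetaboliteMatrix(
        values=pd.DataFrame(values, index=sample_meta.index, columns=fids),
        sample_meta=sample_meta,
        feature_meta=feature_meta,
        state=state,
    )


def random_profile(rng, n_points=None):
    """A random, valid cortisol profile for property tests."""
    n = int(n_points or rng.integers(4, 12))
    inner = np.sort(rng.uniform(0.1, 23.9, size=n - 2))
    while np.any(np.diff(inner) <= 1e-6):
        inner = np.sort(rng.uniform(0.1, 23.9, size=n - 2))
    times = np.concatenate([[0.0], inner, [24.0]])
    conc = rng.lognormal(mean=5.0, sigma=0.8, size=n)
    return make_profile(conc, times=times)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
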