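"""Synthetic cortisol profiles and planted-truth metabolite matrices."""

import numpy as np
import pandas as pd
import pytest

from cortidyn.features import exposure_table, lag1_autocorrelation, trapezoid_auc
from cortidyn.synth import (
    COMPACT_CLASSES,
    DEFAULT_GRID,
    OD_DEFAULT,
    TID_DEFAULT,
    EffectDesign,
    RegimenSpec,
    simulate_cohort,
    simulate_metabolome,
    simulate_profile,
)


def bateman_oracle(t, dose_times, A, ka, ke):
    """Independent closed-form pulse-sum evaluation."""
    total = 0.0
    for d in dose_times:
        dt = t - d
        if dt > 0:
            total += A * (np.exp(-ke * dt) - np.exp(-ka * dt))
    return total


class TestSimulateProfile:
    def test_zero_dose_gives_all_zero_profile(self):
        spec = TID_DEFAULT.model_copy(update={"dose_scale": 0.0})
        p = simulate_profile(spec, jitter_sd=0.0)
        assert np.all(p.conc_nmol_l == 0.0)

    def test_od_baseline_is_zero_before_intake(self):
        p = simulate_profile(OD_DEFAULT, jitter_sd=0.0)
        assert p.conc_nmol_l[0] == 0.0

    def test_tid_matches_bateman_sum_oracle(self):
        spec = RegimenSpec(
            regimen_label="TID",
            dose_times_h=(0.0, 4.0, 8.0),
            absorption_rate=2.0,
            elimination_rate=0.35,
            dose_scale=500.0,
        )
        p = simulate_profile(spec, jitter_sd=0.0)
        expected = [bateman_oracle(t, (0, 4, 8), 500.0, 2.0, 0.35) for t in DEFAULT_GRID]
        np.testing.assert_allclose(p.conc_nmol_l, expected, rtol=1e-12, atol=1e-12)

    def test_tid_has_one_local_maximum_per_dose_on_dense_grid(self):
        dense = np.linspace(0.0, 24.0, 961)
        p = simulate_profile(TID_DEFAULT, grid=dense, jitter_sd=0.0)
        c = p.conc_nmol_l
        peaks = np.flatnonzero((c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])) + 1
        assert len(peaks) == len(TID_DEFAULT.dose_times_h)
        # one peak after each dose
        for d, pk in zip(TID_DEFAULT.dose_times_h, dense[peaks]):
            assert d < pk < d + 4.0

    def test_od_declines_monotonically_after_peak_on_default_grid(self):
        p = simulate_profile(OD_DEFAULT, jitter_sd=0.0)
        i = int(np.argmax(p.conc_nmol_l))
        assert np.all(np.diff(p.conc_nmol_l[i:]) < 0)

    def test_invalid_grid_and_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_profile(OD_DEFAULT, grid=[0, 2, 1, 24])
        with pytest.raises(ValueError):
            simulate_profile(OD_DEFAULT, grid=[0, 2, 12])  # must end at 24
        with pytest.raises(ValueError):
            RegimenSpec(
                regimen_label="OD", dose_times_h=(0,), absorption_rate=-1.0, dose_scale=1.0
            )
        with pytest.raises(ValueError):
            # absorption slower than elimination breaks the pulse shape
            RegimenSpec(
                regimen_label="OD",
                dose_times_h=(0,),
                absorption_rate=0.1,
                elimination_rate=0.35,
                dose_scale=1.0,
            )

    def test_jitter_keeps_concentrations_nonnegative(self):
        p = simulate_profile(OD_DEFAULT, jitter_sd=500.0, seed=11)
        assert np.all(p.conc_nmol_l >= 0.0)


class TestCohort:
    def test_identical_seeds_are_bit_identical(self):
        a, meta_a = simulate_cohort(6, seed=42)
        b, meta_b = simulate_cohort(6, seed=42)
        for p, q in zip(a, b):
            np.testing.assert_array_equal(p.conc_nmol_l, q.conc_nmol_l)
        pd.testing.assert_frame_equal(meta_a, meta_b)

    def test_every_patient_gets_both_regimens(self):
        profiles, meta = simulate_cohort(7, seed=0)
        df = pd.DataFrame(
            {"pid": [p.patient_id for p in profiles], "reg": [p.regimen for p in profiles]}
        )
        per = df.groupby("pid")["reg"].agg(set)
        assert all(v == {"OD", "TID"} for v in per)
        assert set(meta["sequence"]) <= {"OD_first", "TID_first"}

    def test_regimen_direction_auc_and_auto(self):
        # TID gives higher total exposure; OD gives the smoother profile
        profiles, _ = simulate_cohort(50, seed=123)
        aucs = {"OD": [], "TID": []}
        autos = {"OD": [], "TID": []}
        for p in profiles:
            aucs[p.regimen].append(trapezoid_auc(p, (0, 24)))
            autos[p.regimen].append(lag1_autocorrelation(p))
        assert np.mean(aucs["TID"]) > np.mean(aucs["OD"])
        assert np.mean(autos["OD"]) > np.mean(autos["TID"])

    def test_default_calibration_reproduces_trial_auc_means(self):
        # regimen-mean AUC within ~5% of the trial's 3851 / 4698 nmol/L h
        profiles, _ = simulate_cohort(200, seed=9)
        _, summary = exposure_table(profiles)
        row = summary.set_index("metric").loc["auc_0_24"]
        assert row["mean_od"] == pytest.approx(3851, rel=0.05)
        assert row["mean_tid"] == pytest.approx(4698, rel=0.05)


@pytest.fixture(scope="module")
def small_cohort_metrics():
    profiles, _ = simulate_cohort(18, seed=1)
    metrics, _ = exposure_table(profiles)
    return metrics


class TestSimulateMetabolome:
    def test_all_zero_betas_label_everything_none(self, small_cohort_metrics):
        design = EffectDesign(
            features_per_class={"GCMS_serum": {"none": 20}}, seed=1
        )
        _, truth = simulate_metabolome(small_cohort_metrics, design)
        assert (truth["class"] == "none").all()

    def test_missing_rate_zero_gives_complete_matrix(self, small_cohort_metrics):
        design = EffectDesign(features_per_class=COMPACT_CLASSES, missing_rate=0.0, seed=1)
        mats, _ = simulate_metabolome(small_cohort_metrics, design)
        assert not mats["GCMS_serum"].values.isna().any().any()

    def test_missing_rate_produces_left_censored_gaps(self, small_cohort_metrics):
        design = EffectDesign(features_per_class=COMPACT_CLASSES, missing_rate=0.1, seed=1)
        mats, _ = simulate_metabolome(small_cohort_metrics, design)
        v = mats["GCMS_serum"].values
        frac = float(v.isna().to_numpy().mean())
        assert 0.05 < frac < 0.15
        # censoring removes each feature's lowest values
        col = v.iloc[:, 0]
        if col.isna().any():
            assert col.min() >= 0  # observed values all above the censored ones by design

    def test_planted_auc_effect_recovers_high_correlation(self, small_cohort_metrics):
        design = EffectDesign(
            features_per_class={"GCMS_serum": {"auc_only": 10, "none": 10}},
            beta_auc=1.0,
            noise_sd=0.1,
            missing_rate=0.0,
            seed=1,
        )
        mats, truth = simulate_metabolome(small_cohort_metrics, design)
        m = mats["GCMS_serum"]
        auc = small_cohort_metrics.set_index(["patient_id", "period"])["auc_0_24"]
        sample_auc = auc.loc[
            list(zip(m.sample_meta["patient_id"], m.sample_meta["period"]))
        ].to_numpy()
        z = (sample_auc - sample_auc.mean()) / sample_auc.std(ddof=1)
        for _, row in truth[truth["class"] == "auc_only"].iterrows():
            y = np.log(m.values[row["feature_id"]].to_numpy())
            r = np.corrcoef(z, y)[0, 1]  # independent correlation oracle
            assert np.sign(row["beta_auc"]) * r > 0.9

    def test_truth_classes_partition_features(self, small_cohort_metrics):
        design = EffectDesign(features_per_class=COMPACT_CLASSES, seed=3)
        mats, truth = simulate_metabolome(small_cohort_metrics, design)
        assert truth["feature_id"].is_unique
        assert set(truth["class"]) <= {"auc_only", "auto_only", "both", "none"}
        assert len(truth) == sum(sum(v.values()) for v in COMPACT_CLASSES.values())
        assert set(truth["feature_id"]) == set(mats["GCMS_serum"].values.columns)

    def test_serum_emits_per_timepoint_and_urine_per_period(self, small_cohort_metrics):
        design = EffectDesign(
            features_per_class={
                "GCMS_serum": {"none": 3},
                "LCMS_targeted_urine": {"none": 3},
            },
            seed=0,
        )
        mats, _ = simulate_metabolome(small_cohort_metrics, design)
        n_pp = len(small_cohort_metrics)
        assert mats["GCMS_serum"].n_samples == n_pp * len(DEFAULT_GRID)
        assert mats["LCMS_targeted_urine"].n_samples == n_pp

    def test_seeded_hmdb_ids_land_in_designated_pathways(self, small_cohort_metrics):
        from cortidyn.pathway import load_default_library

        lib = load_default_library()
        design = EffectDesign(features_per_class=COMPACT_CLASSES, seed=2)
        _, truth = simulate_metabolome(small_cohort_metrics, design)
        planted_auc = truth[truth["class"] == "auc_only"]["hmdb_id"].dropna()
        members = lib.pathways["PW01"].members
        assert set(planted_auc[:10]) <= set(members)

    def test_unknown_platform_or_missing_metrics_rejected(self, small_cohort_metrics):
        design = EffectDesign(features_per_class={"mystery_platform": {"none": 2}}, seed=0)
        with pytest.raises(ValueError):
            simulate_metabolome(small_cohort_metrics, design)
        broken = small_cohort_metrics.copy()
        broken.loc[broken.index[0], "auc_0_24"] = np.nan
        with pytest.raises(ValueError):
            simulate_metabolome(
                broken, EffectDesign(features_per_class=COMPACT_CLASSES, seed=0)
            )

    def test_same_seed_bit_identical_matrices(self, small_cohort_metrics):
        design = EffectDesign(features_per_class=COMPACT_CLASSES, seed=7)
        a, _ = simulate_metabolome(small_cohort_metrics, design)
        b, _ = simulate_metabolome(small_cohort_metrics, design)
        pd.testing.assert_frame_equal(a["GCMS_serum"].values, b["GCMS_serum"].values)
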