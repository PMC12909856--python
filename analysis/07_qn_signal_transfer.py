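#!/usr/bin/env python
"""Quantify signal transfer by quantile normalisation.

Quantile normalisation forces every sample onto a common value distribution.
When a large share of features shift strongly with the same covariate, a
feature's rank displacement is handed to its neighbours, so planted-null
features inherit spurious associations.  This driver measures the planted-null
significance rate and the unique-class recovery with and without the QN step,
holding everything else fixed.
"""

import argparse

import pandas as pd

from cortidyn.associate import associate_matrix, classify_features
from cortidyn.features import exposure_table
from cortidyn.preprocess import preprocess_chain
from cortidyn.synth import EffectDesign, simulate_cohort, simulate_metabolome


def run(seed: int, quantile: bool):
    profiles, _ = simulate_cohort(18, seed)
    metrics, _ = exposure_table(profiles)
    mats, truth = simulate_metabolome(metrics, EffectDesign(seed=seed))
    tmap = truth.set_index("feature_id")["class"]
    null_flagged = n_null = 0
    frames = []
    for platform in sorted(mats):
        scaled = preprocess_chain(mats[platform], keep_fraction=1.0, quantile=quantile)
        assoc = associate_matrix(scaled, metrics, seed=seed)
        frames.append(classify_features(assoc, scaled.feature_meta))
        nulls = assoc[assoc["feature_id"].map(tmap) == "none"]
        null_flagged += int(nulls["significant"].sum())
        n_null += len(nulls)
    merged = truth.merge(pd.concat(frames), on="feature_id", suffixes=("_t", "_e"))
    rec = {
        cls: float((merged[merged["class_t"] == cls]["class_e"] == target).mean())
        for cls, target in (("auc_only", "unique_AUC"), ("auto_only", "unique_AUTO"))
    }
    return null_flagged / n_null, rec


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for quantile in (True, False):
        null_rate, rec = run(args.seed, quantile)
        label = "with QN   " if quantile else "without QN"
        print(f"{label}: planted-null significance rate {null_rate:.3f} "
              f"(nominal ~0.11 at an 89% HDI); unique recovery "
              f"AUC {rec['auc_only']:.2f}, AUTO {rec['auto_only']:.2f}")
    print("conclusion: QN inflates the null rate and costs recovery when ~half "
          "of the features carry strong planted effects; the trial-faithful "
          "chain keeps QN, validation of the association stage disables it")


if __name__ == "__main__":
    main()
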