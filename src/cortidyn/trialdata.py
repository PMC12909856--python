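"""Published summary statistics of the hydrocortisone crossover trial.

These are the printed regimen-level cortisol exposure means and per-platform
metabolite counts from the randomized OD (once-daily dual-release) vs TID
(thrice-daily) trial in primary adrenal insufficiency.  They serve two jobs:

* calibration targets for the synthetic cohort defaults, and
* inputs for the set/percentage arithmetic checks (partial-AUC additivity,
  the ~18% exposure gap, unique/overlap counts) that the reporting layer
  reproduces.

They are summaries only — no patient-level trial data ships with the package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CORTISOL_AUC_MEANS",
    "PLATFORM_COUNTS",
    "REPORTED_TOTAL_DETECTED",
    "SERUM_IDENTIFIED_PLATFORMS",
    "URINE_PLATFORMS",
]

#: Regimen-mean cortisol exposure (nmol/L·h) over the full day and the
#: reported partial windows.
CORTISOL_AUC_MEANS: dict[str, dict[str, float]] = {
    "OD": {"auc_0_24": 3851.0, "auc_0_4": 2100.0, "auc_4_10": 1283.0, "auc_10_24": 468.0},
    "TID": {"auc_0_24": 4698.0, "auc_0_4": 1996.0, "auc_4_10": 1782.0, "auc_10_24": 921.0},
}

#: Per-platform detection and correlation counts (AUC = total exposure,
#: AUTO = time-profile variability; overlap = correlated with both).
PLATFORM_COUNTS = pd.DataFrame(
    [
        {"platform": "GCMS_serum", "matrix": "serum", "n_detected": 126,
         "n_AUC_correlated": 55, "n_AUTO_correlated": 24, "n_overlap": 12},
        {"platform": "LCMS_targeted_serum", "matrix": "serum", "n_detected": 209,
         "n_AUC_correlated": 87, "n_AUTO_correlated": 49, "n_overlap": 21},
        {"platform": "LCMS_untargeted_serum", "matrix": "serum", "n_detected": 1938,
         "n_AUC_correlated": 610, "n_AUTO_correlated": 402, "n_overlap": 172},
        {"platform": "LCMS_targeted_urine", "matrix": "urine", "n_detected": 143,
         "n_AUC_correlated": 21, "n_AUTO_correlated": 2, "n_overlap": 0},
    ]
)

#: Grand total of detected metabolites as printed in the trial report.  Note
#: the platform rows sum to 2416; the reporting layer flags (but does not
#: resolve) this kind of arithmetic inconsistency.
REPORTED_TOTAL_DETECTED = 2406

#: Platforms whose metabolites are confidently identified and enter the
#: serum Venn/pathway analyses (the untargeted serum features are excluded).
SERUM_IDENTIFIED_PLATFORMS = ("GCMS_serum", "LCMS_targeted_serum")
URINE_PLATFORMS = ("LCMS_targeted_urine",)
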