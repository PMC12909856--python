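"""End-to-end orchestration: simulate -> features -> preprocess -> associate
-> classify -> pathways -> crossover, with serialisable configuration and a
reproducibility manifest.

Outputs are plain TSV/CSV/JSON; a run re-executed from its saved config is
byte-identical (no timestamps enter any artifact).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .associate import associate_matrix, classify_features, platform_count_table, venn_summary
from .crossover import sequence_effect_table
from .features import exposure_table
from .pathway import (
    InsufficientDEMsError,
    load_default_library,
    load_library,
    run_pathway_analysis,
)
from .preprocess import preprocess_chain, write_matrix_tsv
from .synth import (
    DEFAULT_PLATFORM_PLAN,
    TRIAL_SHAPED_CLASSES,
    EffectDesign,
    simulate_cohort,
    simulate_metabolome,
    write_profiles_csv,
)
from .trialdata import SERUM_IDENTIFIED_PLATFORMS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


class RunConfig(BaseModel):
    """Fully serialisable configuration of one synthetic end-to-end run."""

    model_config = ConfigDict(frozen=True)

    out_dir: str = "results/run"
    seed: int = 0
    n_patients: int = 18
    jitter_sd: float = 15.0
    features_per_class: Mapping[str, Mapping[str, int]] = TRIAL_SHAPED_CLASSES
    platform_plan: Mapping[str, str] = DEFAULT_PLATFORM_PLAN
    beta_auc: float = 0.8
    beta_auto: float = 0.8
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    keep_fraction: float = 0.9
    quantile_normalize: bool = True
    prob: float = Field(0.89, gt=0, lt=1)
    n_draws: int = 4000
    joint_model: bool = True
    resample_hourly_auto: bool = False
    class_filters: tuple[str, ...] = ("unique_AUC", "unique_AUTO")
    gmt_path: str | None = None  # None -> packaged synthetic library
    sif_path: str | None = None


def run_all(config: RunConfig) -> dict[str, str]:
    """Execute the whole pipeline; returns a name -> path map of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    t0 = time.perf_counter()
    order = ["simulate", "features", "metabolome", "associate", "classify", "pathways", "crossover", "manifest"]
    completed: list[str] = []

    def stage(name):
        completed.append(name)
        logger.info("stage %-12s done at %6.1fs", name, time.perf_counter() - t0)

    try:
        # 1. cortisol profiles
        profiles, cohort = simulate_cohort(
            config.n_patients, config.seed, jitter_sd=config.jitter_sd
        )
        write_profiles_csv(profiles, out / "cortisol_profiles.csv")
        paths["profiles"] = str(out / "cortisol_profiles.csv")
        stage("simulate")

        # 2. exposure metrics + regimen summary
        metrics, summary = exposure_table(profiles, resample_hourly=config.resample_hourly_auto)
        metrics.to_csv(out / "exposure_metrics.tsv", sep="\t", index=False)
        summary.to_csv(out / "exposure_summary.tsv", sep="\t", index=False)
        paths["metrics"] = str(out / "exposure_metrics.tsv")
        paths["exposure_summary"] = str(out / "exposure_summary.tsv")
        stage("features")

        # 3. synthetic metabolome
        design = EffectDesign(
            n_patients=config.n_patients,
            features_per_class=config.features_per_class,
            beta_auc=config.beta_auc,
            beta_auto=config.beta_auto,
            noise_sd=config.noise_sd,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        matrices, truth = simulate_metabolome(metrics, design, config.platform_plan)
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        paths["ground_truth"] = str(out / "ground_truth.tsv")
        stage("metabolome")

        # 4. preprocessing + association per platform (processed independently)
        assoc_frames, meta_frames, droplogs = [], [], []
        for platform in sorted(matrices):
            scaled = preprocess_chain(
                matrices[platform],
                keep_fraction=config.keep_fraction,
                quantile=config.quantile_normalize,
            )
            droplogs.append(scaled.drop_log)
            write_matrix_tsv(
                scaled,
                out / f"scaled_{platform}.tsv",
                out / f"samples_{platform}.tsv",
            )
            assoc_frames.append(
                associate_matrix(
                    scaled,
                    metrics,
                    prob=config.prob,
                    n_draws=config.n_draws,
                    seed=config.seed,
                    joint=config.joint_model,
                )
            )
            meta_frames.append(scaled.feature_meta)
        associations = pd.concat(assoc_frames, ignore_index=True)
        feature_meta = pd.concat(meta_frames)
        associations.to_csv(out / "associations.tsv", sep="\t", index=False)
        pd.concat(droplogs, ignore_index=True).to_csv(out / "drop_log.tsv", sep="\t", index=False)
        paths["associations"] = str(out / "associations.tsv")
        paths["drop_log"] = str(out / "drop_log.tsv")
        stage("associate")

        # 5. classification, count table, Venn counts
        classified = classify_features(associations, feature_meta)
        classified.to_csv(out / "classified_features.tsv", sep="\t", index=False)
        counts = platform_count_table(classified)
        counts.to_csv(out / "platform_counts.tsv", sep="\t", index=False)
        paths["classified"] = str(out / "classified_features.tsv")
        paths["platform_counts"] = str(out / "platform_counts.tsv")
        per_platform = counts[counts["platform"] != "Total"]
        bad = per_platform[
            (per_platform["n_AUC_correlated"]
             != per_platform["n_unique_AUC"] + per_platform["n_overlap"])
            | (per_platform["n_AUTO_correlated"]
               != per_platform["n_unique_AUTO"] + per_platform["n_overlap"])
        ]
        if not bad.empty:  # cannot occur for counts we build; guards user-supplied tables
            logger.warning("count-table identity violated for platforms: %s", list(bad["platform"]))
        serum_platforms = [
            p for p in per_platform["platform"] if p in SERUM_IDENTIFIED_PLATFORMS
        ]
        urine_platforms = [
            p for p in per_platform["platform"]
            if config.platform_plan.get(p) == "urine"
        ]
        venn = {"serum_identified": venn_summary(counts, serum_platforms)}
        if urine_platforms:
            venn["urine"] = venn_summary(counts, urine_platforms)
        (out / "venn_counts.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
        paths["venn_counts"] = str(out / "venn_counts.json")
        stage("classify")

        # 6. pathway analysis per DEM class
        if config.gmt_path is not None:
            library = load_library(config.gmt_path, config.sif_path)
        else:
            library = load_default_library()
        # serum and urine metabolite lists are analysed separately, as the
        # trial reports them
        for matrix_kind in sorted(classified["matrix"].dropna().unique()):
            sub = classified[classified["matrix"] == matrix_kind]
            for cls in config.class_filters:
                key = f"pathways_{cls}_{matrix_kind}"
                try:
                    res = run_pathway_analysis(sub, library, cls)
                except InsufficientDEMsError as e:
                    logger.warning("pathway analysis skipped for %s/%s: %s", cls, matrix_kind, e)
                    continue
                res.to_csv(out / f"{key}.tsv", sep="\t", index=False)
                res[["pathway_id", "neg_log10_p", "impact", "q_fdr"]].to_csv(
                    out / f"pathway_scatter_{cls}_{matrix_kind}.tsv", sep="\t", index=False
                )
                paths[key] = str(out / f"{key}.tsv")
                paths[f"pathway_scatter_{cls}_{matrix_kind}"] = str(
                    out / f"pathway_scatter_{cls}_{matrix_kind}.tsv"
                )
        stage("pathways")

        # 7. crossover sequence-effect tests on the cortisol features
        paired = (
            metrics.pivot(index="patient_id", columns="regimen", values=["auc_0_24", "auto_lag1"])
            .dropna()
        )
        rows = []
        for metric in ("auc_0_24", "auto_lag1"):
            for pid in paired.index:
                rows.append(
                    {
                        "patient_id": pid,
                        "sequence": cohort.set_index("patient_id").loc[pid, "sequence"],
                        "outcome_name": metric,
                        "value_od": paired.loc[pid, (metric, "OD")],
                        "value_tid": paired.loc[pid, (metric, "TID")],
                    }
                )
        crossover_res = sequence_effect_table(pd.DataFrame(rows), seed=config.seed)
        crossover_res.to_csv(out / "crossover_tests.tsv", sep="\t", index=False)
        paths["crossover"] = str(out / "crossover_tests.tsv")
        stage("crossover")

        manifest = {
            "cortidyn_version": __version__,
            "config": json.loads(config.model_dump_json()),
            "artifacts": {k: str(Path(v).name) for k, v in sorted(paths.items())},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(out / "manifest.json")
    except Exception as e:
        failed = order[len(completed)] if len(completed) < len(order) else "manifest"
        raise RuntimeError(f"pipeline aborted at stage '{failed}': {e}") from e
    return paths
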