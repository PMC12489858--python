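"""End-to-end orchestration: read -> QC -> score -> describe -> associate.

Everything here is deterministic given the inputs and the config seed; a
JSON run manifest records versions, seed, thresholds and input checksums so
a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_models import (
    ALL_SCORES,
    contrasts_frame,
    emm_pairwise_contrasts,
    fit_biomarker_models,
    fit_extended_models,
    fit_stage_model,
    plot_scores_by_stage,
)
from .errors import PathPRSError, ValidationError
from .io_formats import (
    BIOMARKERS,
    read_genotypes,
    read_phenotypes,
    read_scoring_file,
    results_frame,
)
from .prs_engine import (
    SCORE_COLUMNS,
    align_effect_alleles,
    compute_all_scores,
    impute_missing_dosage,
)
from .variant_qc import QCThresholds, apply_variant_qc

log = logging.getLogger("pathprs")


@dataclass
class PipelineConfig:
    genotypes: str
    weights: str
    phenotypes: str
    out_dir: str
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    ambiguity_policy: str = "exclude"
    field_preference: tuple[str, ...] = ("DS", "GT")
    run_stage_model: bool = True
    run_biomarker_models: bool = True
    run_extended_models: bool = True
    run_emm: bool = True
    make_plots: bool = True
    hwe_midp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        out = Path(self.out_dir).resolve()
        for p in (self.genotypes, self.weights, self.phenotypes):
            if Path(p).resolve() == out:
                raise ValidationError("output dir must differ from input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = QCThresholds(**raw.pop("thresholds", {}))
        if "field_preference" in raw:
            raw["field_preference"] = tuple(raw["field_preference"])
        return cls(thresholds=thresholds, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def describe_cohort(
    cohort: pd.DataFrame, scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptive table per stage and overall: n, age mean/SD and
    median [min, max], sex counts with percentages (one decimal), score
    means/SDs, and biomarker counts with prevalences where flags are
    observed. SD is reported as NaN (blank) for single-sample groups."""
    if cohort.empty:
        raise ValidationError("describe_cohort: empty cohort")
    data = cohort
    if scores is not None:
        data = cohort.merge(scores, on="sample_id", how="left")
    stages = [
        s
        for s in ("none", "early", "intermediate", "late")
        if (data["stage"].astype(str) == s).any()
    ]
    rows = []
    for label in stages + ["overall"]:
        sub = data if label == "overall" else data[data["stage"].astype(str) == label]
        n = len(sub)
        row: dict = {"stage": label, "n": n}
        age = sub["age"].astype(float)
        row["age_mean"] = age.mean()
        row["age_sd"] = age.std(ddof=1) if n > 1 else np.nan
        row["age_median"] = age.median()
        row["age_min"] = age.min()
        row["age_max"] = age.max()
        for sex in ("female", "male"):
            cnt = int((sub["sex"].astype(str) == sex).sum())
            row[f"n_{sex}"] = cnt
            row[f"pct_{sex}"] = round(100.0 * cnt / n, 1)
        for col in SCORE_COLUMNS:
            if col in sub.columns:
                row[f"{col}_mean"] = sub[col].mean()
                row[f"{col}_sd"] = sub[col].std(ddof=1) if n > 1 else np.nan
        for b in BIOMARKERS:
            obs = sub[b].dropna()
            if len(obs):
                cnt = int(obs.sum())
                row[f"n_{b}"] = cnt
                row[f"pct_{b}"] = round(100.0 * cnt / len(obs), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis and write every artifact under out_dir.

    Returns the run manifest (also written as ``manifest.json``). Any
    stage failure propagates as a :class:`PathPRSError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pathprs_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "r2_min": config.thresholds.r2_min,
            "maf_min": config.thresholds.maf_min,
            "missing_max": config.thresholds.missing_max,
            "hwe_p_min": config.thresholds.hwe_p_min,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("genotypes", config.genotypes),
                ("weights", config.weights),
                ("phenotypes", config.phenotypes),
            )
        },
        "outputs": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        return name

    def emit(df: pd.DataFrame, filename: str) -> None:
        path = out / filename
        df.to_csv(path, index=False)
        manifest["outputs"].append(filename)

    current = stage("read")
    try:
        matrix = read_genotypes(config.genotypes, config.field_preference)
        weights = read_scoring_file(config.weights)
        cohort = read_phenotypes(config.phenotypes)

        current = stage("qc")
        filtered, report = apply_variant_qc(
            matrix, config.thresholds, hwe_midp=config.hwe_midp
        )
        emit(report.table, "qc_report.csv")
        manifest["qc_counts"] = report.counts
        log.info("QC: %s", report.counts)

        current = stage("score")
        aligned = align_effect_alleles(weights, filtered, config.ambiguity_policy)
        aligned = impute_missing_dosage(aligned)
        scores = compute_all_scores(aligned, weights)
        emit(scores, "scores.csv")
        manifest["alignment_counts"] = (
            aligned.table["action"].value_counts().to_dict()
        )

        current = stage("describe")
        emit(describe_cohort(cohort, scores), "descriptives.csv")

        stages_present = set(cohort["stage"].astype(str))
        if config.run_stage_model and len(stages_present) >= 2 and "none" in stages_present:
            current = stage("stage_model")
            stage_fit = fit_stage_model(cohort, scores)
            emit(results_frame([stage_fit]), "stage_model.csv")
            if config.run_emm:
                current = stage("emm")
                emit(
                    contrasts_frame(emm_pairwise_contrasts(stage_fit, cohort)),
                    "emm_contrasts.csv",
                )
        if config.run_biomarker_models and (
            cohort["stage"].astype(str) == "intermediate"
        ).any():
            current = stage("biomarker_models")
            fits = fit_biomarker_models(cohort, scores)
            emit(results_frame(fits), "biomarker_models.csv")
            if config.run_extended_models:
                current = stage("extended_models")
                ext = []
                for score_name in ALL_SCORES:
                    for include_atrophy in (False, True):
                        try:
                            ext.append(
                                fit_extended_models(
                                    cohort, scores, score_name, include_atrophy
                                )
                            )
                        except PathPRSError as exc:
                            log.warning("extended model skipped: %s", exc)
                if ext:
                    emit(results_frame(ext), "extended_models.csv")
        if config.make_plots:
            current = stage("plot")
            plot_path = out / "prs_by_stage.png"
            plot_scores_by_stage(scores, cohort, plot_path, seed=config.seed)
            manifest["outputs"].append("prs_by_stage.png")
    except PathPRSError as exc:
        raise type(exc)(f"[stage {current}] {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
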