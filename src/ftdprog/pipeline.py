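"""End-to-end orchestration: simulate -> adjust -> compare -> DEBM -> cross-lag.

Every stage writes a plain CSV/JSON artifact into the output directory, and a
manifest records the configuration hash, all seeds, exclusion counts, and the
package version, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CLINICAL_SCORES, SUBCORTICAL, CohortConfig,
                     LongitudinalConfig, default_cohort_config,
                     generate_cohort, generate_longitudinal, ground_truth,
                     write_cohort_csv)
from .crosslag import association_matrix, t_statistic_matrix
from .debm import (BiomarkerTable, bootstrap_ordering, clinical_correlation,
                   confound_adjust, default_manifest, estimate_ordering,
                   event_probabilities, fit_all_gmms, stage_subjects,
                   validate_auc, biomarker_screen)
from .errors import SchemaError
from .wmh import REGION_COLUMNS, regional_analysis

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "subject_id", "genotype", "status", "sex", "age", "education", "visit_time",
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str = "results/run"
    input_csv: str | None = None        # None => simulate
    seed: int = 17
    alpha: float = 0.05
    bootstrap_replicates: int = 100
    cv_folds: int = 10
    mse_threshold: float = 0.01
    run_group_comparison: bool = True
    run_debm: bool = True
    run_crosslag: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.bootstrap_replicates <= 0 or self.cv_folds <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def canonical(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class SchemaReport:
    passed: bool
    missing_columns: list[str] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)


def validate_input(table: pd.DataFrame) -> SchemaReport:
    """Schema and plausibility checks on a cohort table (report only).

    Checks: required columns present; ICV-normalised volumes inside (0, 1);
    WMH volumes strictly positive; non-carriers labelled control;
    non-negative visit times with a baseline visit at 0 for every subject.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    issues = []
    if missing:
        return SchemaReport(False, missing, [f"missing columns: {missing}"])

    volume_cols = [c for c in table.columns
                   if c in SUBCORTICAL or c in ("gm_frontal", "gm_temporal",
                                                "cerebellum", "ventricles")]
    for c in volume_cols:
        v = table[c].to_numpy(float)
        bad = np.flatnonzero(np.isfinite(v) & ((v <= 0) | (v >= 1)))
        if bad.size:
            issues.append(f"{c}: {bad.size} values outside (0, 1) "
                          f"(first at row {bad[0]}); expected ICV-normalised fractions")
    for c in [c for c in table.columns if c.startswith("wmh")]:
        v = table[c].to_numpy(float)
        bad = np.flatnonzero(np.isfinite(v) & (v <= 0))
        if bad.size:
            issues.append(f"{c}: {bad.size} non-positive WMH volumes "
                          f"(first at row {bad[0]})")
    nc = table[(table["genotype"] == "noncarrier") & (table["status"] != "control")]
    if len(nc):
        issues.append(f"{len(nc)} non-carrier rows not labelled control "
                      f"(first subject {nc.iloc[0]['subject_id']})")
    if (table["visit_time"].to_numpy(float) < 0).any():
        issues.append("negative visit_time values present")
    no_baseline = [sid for sid, g in table.groupby("subject_id")
                   if (g["visit_time"] != 0).all()]
    if no_baseline:
        issues.append(f"{len(no_baseline)} subjects lack a baseline visit "
                      f"(first: {no_baseline[0]})")
    return SchemaReport(not issues, [], issues)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages run in a fixed order; each failure halts the run with an error
    naming the stage. Artifacts and a ``manifest.json`` land in
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": yaml.safe_load(config.canonical()),
        "seeds": {"cohort": config.seed, "longitudinal": config.seed + 1,
                  "bootstrap": config.seed + 2, "cv": config.seed + 3},
        "stages": [],
        "exclusions": {},
    }

    # --- stage: cohort -----------------------------------------------------
    if config.input_csv is None:
        cohort_cfg = default_cohort_config(seed=config.seed)
        baseline = generate_cohort(cohort_cfg)
        long_cfg = LongitudinalConfig(seed=config.seed + 1)
        cohort = generate_longitudinal(long_cfg, baseline)
        manifest["ground_truth_ordering"] = list(ground_truth(cohort_cfg).sequence)
    else:
        cohort = pd.read_csv(config.input_csv)
        baseline = cohort[cohort["visit_time"] == 0.0]
    report = validate_input(cohort)
    if report.missing_columns:
        raise SchemaError("input table missing required columns",
                          report.missing_columns)
    manifest["schema_issues"] = report.issues
    write_cohort_csv(cohort, out / "cohort.csv")
    manifest["stages"].append("cohort")

    base = cohort[cohort["visit_time"] == 0.0].reset_index(drop=True)

    # --- stage: WMH group comparison --------------------------------------
    if config.run_group_comparison:
        grouping = base["genotype"].str.cat(base["status"], sep=":")
        regions = [r for r in REGION_COLUMNS
                   if REGION_COLUMNS[r] in base.columns]
        comparisons = regional_analysis(base, grouping, regions)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)
        manifest["stages"].append("group_comparison")
        manifest["group_comparison_family"] = int(comparisons["family_size"].iloc[0])

    # --- stage: DEBM -------------------------------------------------------
    if config.run_debm:
        debm_rows = base[((base["genotype"] == "GRN")
                          | (base["status"] == "control"))]
        manifest["debm_n_subjects"] = int(len(debm_rows))
        table = BiomarkerTable.from_cohort(debm_rows, default_manifest())
        table = confound_adjust(table, debm_rows)
        screen = biomarker_screen(table, alpha=config.alpha)
        fits = fit_all_gmms(table, screen, mse_threshold=config.mse_threshold)
        P = event_probabilities(table, fits)
        ordering = estimate_ordering(P, seed=config.seed)
        pvd = bootstrap_ordering(table, fits, refit=True,
                                 n_replicates=config.bootstrap_replicates,
                                 seed=config.seed + 2,
                                 row_order=ordering.sequence,
                                 mse_threshold=config.mse_threshold)
        stages = stage_subjects(P, ordering)
        labels = table.labels
        auc_mean, auc_sd = validate_auc(stages, labels, folds=config.cv_folds,
                                        seed=config.seed + 3)
        score_cols = [c for c in CLINICAL_SCORES if c in debm_rows.columns]
        corr = clinical_correlation(
            stages, debm_rows.set_index("subject_id")[score_cols])

        debm_report = {
            "admitted": [n for n, f in fits.items() if f.admitted],
            "central_ordering": list(ordering.sequence),
            "ordering_cost": ordering.cost,
            "bootstrap_replicates": pvd.n_replicates,
            "cv_folds": config.cv_folds,
            "auc_mean": auc_mean,
            "auc_sd": auc_sd,
            "gmm": {n: {"normal_mean": f.normal_mean, "normal_sd": f.normal_sd,
                        "abnormal_mean": f.abnormal_mean,
                        "abnormal_sd": f.abnormal_sd, "mse": f.mse,
                        "mixing_fractions": f.mixing_fractions,
                        "admitted": f.admitted}
                    for n, f in fits.items()},
        }
        (out / "debm_report.json").write_text(json.dumps(debm_report, indent=2))
        pvd.to_frame().to_csv(out / "positional_variance.csv")
        stages.to_csv(out / "stages.csv")
        corr.to_csv(out / "clinical_correlations.csv", index=False)
        manifest["stages"].append("debm")
        manifest["bootstrap_replicates"] = pvd.n_replicates
        manifest["cv_folds"] = config.cv_folds
        manifest["debm_auc"] = [auc_mean, auc_sd]

    # --- stage: cross-lag --------------------------------------------------
    if config.run_crosslag:
        multi = cohort.groupby("subject_id")["visit_time"].nunique()
        eligible = multi[multi >= 2].index
        long_rows = cohort[cohort["subject_id"].isin(eligible)
                           & (cohort["genotype"] == "GRN")]
        results = association_matrix(long_rows, alpha=config.alpha)
        results.to_csv(out / "crosslag_results.csv", index=False)
        t_statistic_matrix(results).to_csv(out / "crosslag_t_matrix.csv")
        manifest["stages"].append("crosslag")
        manifest["crosslag_tests"] = int(len(results))
        manifest["crosslag_significant"] = int(results["significant"].sum())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
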