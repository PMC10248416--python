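"""End-to-end study orchestration: simulate → summarize → analyze → report.

``run_study`` reproduces the study's analysis flow on a synthetic cohort:
draw patients, average the two raters, compute per-marker ICC and group
comparisons, gate markers at p < 0.05, combine the significant ones by
binary logistic regression, run ROC/Youden analyses for each significant
marker and for the combined score, and compare AUCs pairwise with the DeLong
test. Everything is deterministic for a fixed seed; when an output directory
is given, the report tables are written as CSV together with a YAML config
echo sufficient to reproduce the bundle.

``screen_cohort`` reproduces the patient-screening arithmetic (recruited
minus ordered exclusions) as a flow table.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, PhantomSpec, cohort_frame, generate_phantom, sample_patients
from .exceptions import ConfigError
from .fitting import fit_volume
from .models import MODEL_MARKERS
from .stats import (
    chi_square_categorical,
    delong_test,
    fit_logistic,
    roc_analysis,
    select_and_compare,
)
from .voi import average_raters, cohort_icc_table, voi_mean

logger = logging.getLogger("vetcdiff")

__all__ = ["ScreeningCriteria", "screen_cohort", "StudyConfig", "StudyReport",
           "run_study", "DEFAULT_SCREENING"]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Ordered named exclusion rules with per-rule counts."""

    rules: Tuple[Tuple[str, int], ...]

    def __post_init__(self):
        for name, count in self.rules:
            if count < 0:
                raise ConfigError(f"negative exclusion count for {name!r}")


#: the study's screening: 159 recruited, six exclusion rules, 86 included
DEFAULT_SCREENING = ScreeningCriteria(rules=(
    ("prior treatment (TACE/RFA etc.)", 20),
    ("not eligible for / no surgery here", 25),
    ("MRI-surgery interval > 1 month", 5),
    ("lesion < 1 cm", 6),
    ("non-HCC pathology", 14),
    ("inadequate image quality", 3),
))


def screen_cohort(recruited: int, criteria: ScreeningCriteria) -> pd.DataFrame:
    """Sequential exclusion flow; raises if exclusions exceed the remainder.

    Returns a table with one row per rule (rule, excluded, remaining) and a
    final "included" row.
    """
    if recruited < 0:
        raise ConfigError("recruited must be non-negative")
    remaining = recruited
    rows = []
    for name, count in criteria.rules:
        remaining -= count
        if remaining < 0:
            raise ConfigError(
                f"exclusions exceed the cohort at rule {name!r}"
            )
        rows.append({"rule": name, "excluded": count, "remaining": remaining})
    rows.append({"rule": "included", "excluded": 0, "remaining": remaining})
    return pd.DataFrame(rows)


@dataclass
class StudyConfig:
    """Configuration of a full synthetic-study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    significance_alpha: float = 0.05
    normality_alpha: float = 0.05
    screening_recruited: Optional[int] = 159
    screening: ScreeningCriteria = DEFAULT_SCREENING
    categorical_tables: Dict[str, list] = field(default_factory=dict)
    phantom: Optional[PhantomSpec] = None
    phantom_model: str = "DKI"
    seed: int = 0

    def resolved_cohort(self) -> CohortConfig:
        """The cohort config with the study seed folded in."""
        return dataclasses.replace(self.cohort, seed=self.seed)


@dataclass
class StudyReport:
    """Bundle of all report tables produced by :func:`run_study`."""

    config: StudyConfig
    screening: Optional[pd.DataFrame]
    categorical: Optional[pd.DataFrame]
    cohort: pd.DataFrame
    comparisons: pd.DataFrame
    icc: pd.DataFrame
    significant_markers: List[str]
    logistic_summary: Optional[pd.DataFrame]
    roc: pd.DataFrame
    delong: pd.DataFrame
    voi_summary: Optional[pd.DataFrame] = None
    warnings: List[str] = field(default_factory=list)

    def tables(self) -> Dict[str, pd.DataFrame]:
        out = {"cohort": self.cohort, "comparisons": self.comparisons,
               "icc": self.icc, "roc": self.roc, "delong": self.delong}
        if self.screening is not None:
            out["screening"] = self.screening
        if self.categorical is not None:
            out["categorical"] = self.categorical
        if self.logistic_summary is not None:
            out["logistic"] = self.logistic_summary
        if self.voi_summary is not None:
            out["voi_summary"] = self.voi_summary
        return out


def _comparison_table(records, normality_alpha) -> pd.DataFrame:
    markers = list(records[0].markers_rater1)
    means = [average_raters(r) for r in records]
    status = np.array([r.vetc_status for r in records])
    rows = []
    for m in markers:
        vals = np.array([mm[m] for mm in means])
        res = select_and_compare(vals[status == "negative"],
                                 vals[status == "positive"], marker=m,
                                 normality_alpha=normality_alpha)
        rows.append({
            "marker": m, "test": res.test_used, "p_value": res.p_value,
            "mean_negative": res.mean_neg, "sd_negative": res.sd_neg,
            "mean_positive": res.mean_pos, "sd_positive": res.sd_pos,
        })
    return pd.DataFrame(rows).set_index("marker")


def run_study(config: StudyConfig, out_dir: Optional[str] = None) -> StudyReport:
    """Run the whole synthetic study; deterministic for a fixed config.seed."""
    warnings_log: List[str] = []

    screening = None
    if config.screening_recruited is not None:
        screening = screen_cohort(config.screening_recruited, config.screening)
        logger.info("screening: %d recruited -> %d included",
                    config.screening_recruited,
                    int(screening["remaining"].iloc[-1]))

    categorical = None
    if config.categorical_tables:
        rows = []
        for name, table in config.categorical_tables.items():
            stat, p, corr = chi_square_categorical(table)
            rows.append({"characteristic": name, "chi2": stat, "p_value": p,
                         "yates_correction": corr})
        categorical = pd.DataFrame(rows).set_index("characteristic")

    records = sample_patients(config.resolved_cohort())
    cohort_df = cohort_frame(records)

    icc_df = cohort_icc_table(records)
    comp_df = _comparison_table(records, config.normality_alpha)

    significant = [m for m in comp_df.index
                   if comp_df.loc[m, "p_value"] < config.significance_alpha]

    means = [average_raters(r) for r in records]
    labels = np.array([1 if r.vetc_status == "positive" else 0 for r in records])

    roc_rows = []
    scores_by_model: Dict[str, np.ndarray] = {}
    for m in significant:
        scores = np.array([mm[m] for mm in means])
        # orient so that higher score predicts VETC-positive
        if np.mean(scores[labels == 1]) < np.mean(scores[labels == 0]):
            scores = -scores
        scores_by_model[m] = scores
        r = roc_analysis(scores, labels)
        roc_rows.append({
            "model": m, "auc": r.auc, "auc_ci_low": r.auc_ci_low,
            "auc_ci_high": r.auc_ci_high, "accuracy": r.accuracy_at_cutoff,
            "sensitivity": r.sens_at_cutoff, "specificity": r.spec_at_cutoff,
            "youden_index": r.youden_index, "cutoff": r.youden_cutoff,
        })

    logistic_summary = None
    if len(significant) >= 2:
        x = np.column_stack([np.array([mm[m] for mm in means])
                             for m in significant])
        lm = fit_logistic(x, labels, names=significant)
        logistic_summary = pd.DataFrame({
            "term": ["intercept"] + list(significant),
            "coefficient": [lm.intercept] + list(lm.coefficients),
        }).set_index("term")
        if lm.separation:
            warnings_log.append("logistic model: complete separation flagged")
        combined = lm.probabilities
        scores_by_model["combined"] = combined
        r = roc_analysis(combined, labels)
        roc_rows.append({
            "model": " + ".join(significant), "auc": r.auc,
            "auc_ci_low": r.auc_ci_low, "auc_ci_high": r.auc_ci_high,
            "accuracy": r.accuracy_at_cutoff, "sensitivity": r.sens_at_cutoff,
            "specificity": r.spec_at_cutoff, "youden_index": r.youden_index,
            "cutoff": r.youden_cutoff,
        })

    roc_df = pd.DataFrame(roc_rows).set_index("model") if roc_rows else \
        pd.DataFrame(columns=["auc"])

    delong_rows = []
    keys = list(scores_by_model)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = delong_test(scores_by_model[keys[i]], scores_by_model[keys[j]],
                            labels)
            delong_rows.append({
                "model_a": keys[i], "model_b": keys[j],
                "auc_a": d.auc_a, "auc_b": d.auc_b,
                "auc_difference": d.auc_difference, "p_value": d.p_value,
            })
    delong_df = pd.DataFrame(delong_rows)

    voi_summary = None
    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, seed=config.seed)
        dwi, mask1, mask2 = generate_phantom(spec)
        maps = fit_volume(config.phantom_model, dwi, mask1)
        rows = []
        for name in MODEL_MARKERS[config.phantom_model]:
            rows.append({
                "marker": name,
                "voi_mean_rater1": voi_mean(maps[name], mask1),
                "voi_mean_rater2": voi_mean(maps[name], mask2),
                "n_voxels_rater1": mask1.n_voxels,
                "n_voxels_rater2": mask2.n_voxels,
                "n_nonconverged": maps[name].n_fitted - maps[name].n_converged,
            })
        voi_summary = pd.DataFrame(rows).set_index("marker")

    report = StudyReport(
        config=config, screening=screening, categorical=categorical,
        cohort=cohort_df, comparisons=comp_df, icc=icc_df,
        significant_markers=significant, logistic_summary=logistic_summary,
        roc=roc_df, delong=delong_df, voi_summary=voi_summary,
        warnings=warnings_log,
    )

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _config_echo(config: StudyConfig) -> dict:
    cohort = config.resolved_cohort()
    return {
        "seed": config.seed,
        "significance_alpha": config.significance_alpha,
        "normality_alpha": config.normality_alpha,
        "cohort": {
            "n_negative": cohort.n_negative,
            "n_positive": cohort.n_positive,
            "rater_noise_scale": cohort.rater_noise_scale,
            "distributions": {k: list(v) for k, v in cohort.distributions.items()},
            "correlated": cohort.correlation is not None,
        },
        "screening_recruited": config.screening_recruited,
        "phantom": None if config.phantom is None else {
            "shape": list(config.phantom.shape),
            "noise_sigma": config.phantom.noise_sigma,
            "model": config.phantom_model,
        },
    }


def _write_report(report: StudyReport, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables().items():
        df.to_csv(out_dir / f"{name}.csv")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_echo(report.config), fh, sort_keys=True)
    with open(out_dir / "log.txt", "w") as fh:
        fh.write(f"seed: {report.config.seed}\n")
        fh.write(f"significant markers: {report.significant_markers}\n")
        for w in report.warnings:
            fh.write(f"warning: {w}\n")
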