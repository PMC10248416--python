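"""VOI summaries, inter-rater agreement (ICC) and rater averaging.

The study's measurement chain: each rater's volume of interest is applied to
every parametric map, the mean over VOI voxels is the patient's marker value,
agreement between the two raters is quantified with an intraclass correlation
coefficient, and the two raters' values are averaged for all further
analysis.

The ICC form is ICC(2,1): two-way random effects, absolute agreement, single
measure — the raters are treated as a random interchangeable pair. Quality
bands: poor < 0.50, moderate 0.50–0.75, good 0.75–0.90, excellent > 0.90.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParameterMap, VoiMask
from .cohort import PatientRecord
from .exceptions import AlignmentError, DomainError

__all__ = ["IccResult", "voi_mean", "icc_two_raters", "average_raters",
           "icc_band", "cohort_icc_table"]


def icc_band(icc: float) -> str:
    """Map an ICC point estimate to the study's quality band."""
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_raters: int = 2
    degenerate: bool = False


def voi_mean(pmap: ParameterMap, mask: VoiMask) -> float:
    """Mean map value over the mask, excluding non-converged voxels.

    Raises on an empty mask; returns NaN (missing-value contract) when every
    masked voxel failed to converge.
    """
    if mask.n_voxels == 0:
        raise DomainError("empty mask")
    if mask.data.shape != pmap.values.shape:
        raise AlignmentError("mask and map are on different grids")
    use = mask.data & pmap.mask & pmap.converged
    if not use.any():
        return float("nan")
    return float(np.nanmean(pmap.values[use]))


def icc_two_raters(values_r1, values_r2) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The 95% CI follows the standard F-based construction (McGraw & Wong):
    with MSR/MSC/MSE the subject, rater and residual mean squares of the
    two-way layout,

        ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)

    Zero between-subject variance makes the coefficient undefined; the result
    is flagged degenerate with icc = 0.
    """
    x = np.column_stack([np.asarray(values_r1, float),
                         np.asarray(values_r2, float)])
    n, k = x.shape
    if n < 5:
        raise DomainError("need at least 5 subjects for an ICC")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0) and np.isclose(mse, 0) and np.isclose(msc, 0):
        return IccResult(icc=0.0, ci_low=float("nan"), ci_high=float("nan"),
                         band="poor", n_subjects=n, degenerate=True)
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement: CI collapses
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, band="excellent",
                         n_subjects=n)

    # F-based CI with Satterthwaite degrees of freedom (McGraw & Wong case 2)
    alpha = 0.05
    fj = msc / mse
    c0 = n * (1 + (k - 1) * icc) - k * icc
    vn = (n - 1) * (k - 1) * (k * icc * fj + c0) ** 2
    vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + c0 ** 2
    v = vn / vd
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return IccResult(icc=float(icc), ci_low=lower, ci_high=upper,
                     band=icc_band(float(icc)), n_subjects=n)


def average_raters(record: PatientRecord) -> Dict[str, float]:
    """Element-wise mean of the two raters' marker values."""
    r1, r2 = record.markers_rater1, record.markers_rater2
    if r1 is None or r2 is None or set(r1) != set(r2):
        raise DomainError("both raters must report the same markers")
    return {m: 0.5 * (r1[m] + r2[m]) for m in r1}


def cohort_icc_table(records: List[PatientRecord]) -> pd.DataFrame:
    """Per-marker ICC across the whole cohort (both groups pooled)."""
    markers = list(records[0].markers_rater1)
    rows = []
    for m in markers:
        r1 = [r.markers_rater1[m] for r in records]
        r2 = [r.markers_rater2[m] for r in records]
        res = icc_two_raters(r1, r2)
        rows.append({"marker": m, "icc": res.icc, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "band": res.band})
    return pd.DataFrame(rows).set_index("marker")
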