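"""Per-section summaries and cohort-level statistics.

QCC-P is the fraction of tumor cells in a section called QCC; QCC-D is
the same fraction computed per field of view.  Sample groups are compared
with a classical unpaired t-test (pooled variance by default, Welch by
flag); associations use Pearson correlation; the post-hoc power of a
two-group comparison uses a normal-approximation formula on the
standardized mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cell_table import SectionTable, ValidationError
from .qcc_calling import QCCLabels

__all__ = [
    "SectionSummary",
    "PowerSpec",
    "GroupComparison",
    "qcc_percentage",
    "qcc_density",
    "group_compare",
    "pearson_r",
    "posthoc_power",
    "summarize_section",
    "cohort_table",
]


@dataclass
class SectionSummary:
    """One row of the cohort table."""

    section_id: str
    sample_type: str | None
    n_tumor_cells: int
    qcc_p: float
    qcc_d: pd.Series  # per-FOV fraction, NaN where a FOV has no tumor cells
    qcc_ci: float | None = None
    ci_p_value: float | None = None


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the post-hoc power computation.

    ``se_difference`` is read as the standard error of the group mean
    difference; ``delta/se`` is the standardized noncentrality.
    """

    mean_difference: float
    se_difference: float
    n1: int
    n2: int
    alpha: float = 0.05
    sidedness: str = "one"  # {"one", "two"}

    def __post_init__(self) -> None:
        if self.se_difference <= 0:
            raise ValidationError("se_difference must be > 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sidedness not in ("one", "two"):
            raise ValidationError("sidedness must be 'one' or 'two'")


@dataclass(frozen=True)
class GroupComparison:
    mean_difference: float
    t_statistic: float
    p_value: float
    df: float
    zero_variance: bool = False


def qcc_percentage(labels: QCCLabels) -> float:
    """QCC-P: called QCCs over all tumor cells in the reference population."""
    if labels.n_cells == 0:
        raise ValidationError("QCC-P undefined for zero tumor cells")
    return labels.n_qcc / labels.n_cells


def qcc_density(labels: QCCLabels, section: SectionTable) -> pd.Series:
    """QCC-D: per-FOV QCC fraction over that FOV's tumor cells.

    Every retained FOV gets an entry; FOVs with zero tumor cells are NaN
    (undefined), not zero.
    """
    tumor = section.cells[section.cells["tissue_class"] == "tumor"]
    merged = tumor.merge(labels.table[["cell_id", "qcc"]], on="cell_id", how="inner")
    per_fov = merged.groupby("fov_id")["qcc"].mean()
    out = pd.Series(np.nan, index=pd.Index(section.fovs["fov_id"], name="fov_id"))
    out.loc[per_fov.index] = per_fov
    return out


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> GroupComparison:
    """Unpaired two-sample t-test (pooled variance; Welch via equal_var=False)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate pooled variance: identical constants -> no evidence,
        # different constants -> infinitely strong evidence; flag either way
        if diff == 0:
            return GroupComparison(0.0, 0.0, 1.0, a.size + b.size - 2, zero_variance=True)
        t = float("inf") if diff > 0 else float("-inf")
        return GroupComparison(diff, t, 0.0, a.size + b.size - 2, zero_variance=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_difference=diff,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_r needs equal-length inputs of size >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def posthoc_power(spec: PowerSpec) -> float:
    """Normal-approximation power at noncentrality delta/SE.

    One-sided: ``Phi(delta/SE - z_alpha)``.  Two-sided:
    ``Phi(delta/SE - z_{alpha/2}) + Phi(-delta/SE - z_{alpha/2})``.
    Strictly increasing in the noncentrality; equals alpha at delta = 0.
    """
    ncp = spec.mean_difference / spec.se_difference
    norm = stats.norm
    if spec.sidedness == "one":
        return float(norm.cdf(ncp - norm.ppf(1 - spec.alpha)))
    z = norm.ppf(1 - spec.alpha / 2)
    return float(norm.cdf(ncp - z) + norm.cdf(-ncp - z))


def summarize_section(
    section: SectionTable,
    labels: QCCLabels,
    qcc_ci: float | None = None,
    ci_p_value: float | None = None,
) -> SectionSummary:
    return SectionSummary(
        section_id=section.section_id,
        sample_type=section.sample_type,
        n_tumor_cells=labels.n_cells,
        qcc_p=qcc_percentage(labels),
        qcc_d=qcc_density(labels, section),
        qcc_ci=qcc_ci,
        ci_p_value=ci_p_value,
    )


def cohort_table(summaries: Sequence[SectionSummary]) -> pd.DataFrame:
    """Cohort overview: one row per section with QCC-P, QCC-CI and its p."""
    return pd.DataFrame(
        {
            "section_id": [s.section_id for s in summaries],
            "sample_type": [s.sample_type for s in summaries],
            "n_tumor_cells": [s.n_tumor_cells for s in summaries],
            "qcc_p": [s.qcc_p for s in summaries],
            "qcc_ci": [s.qcc_ci for s in summaries],
            "ci_p_value": [s.ci_p_value for s in summaries],
        }
    )
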