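"""Cohort evaluation statistics.

Covers the evaluation design used for single-slice body-composition
studies: subjects are classified into a sarcopenic-obesity group
(BMI >= 25.0 kg/m² with elevated ALT >= 35 IU/L, the Korean obesity
cut-off combined with a liver-enzyme criterion) or a healthy-control
group (BMI 18.0-23.0 kg/m², ALT < 35 IU/L); per-measure group
differences are tested with an independent two-sample t-test; and
two-observer reliability is quantified with the intraclass correlation
coefficient ICC(2,1) — two-way random effects, absolute agreement,
single rater — with its F-based 95% confidence interval and the
conventional poor/moderate/good/excellent banding.

The t statistic and p-value are delegated to scipy; the ICC point
estimate and confidence interval are computed directly from the two-way
ANOVA mean squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateDataError
from .quantify import RATIO_NAMES, CompartmentAreas, RatioSet

GROUP_SARCOPENIC = "sarcopenic-obesity"
GROUP_HEALTHY = "healthy"
GROUP_UNCLASSIFIED = "unclassified"

AREA_NAMES = ("MA", "SA", "VA")
MEASURE_NAMES = AREA_NAMES + RATIO_NAMES

RELIABILITY_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class TTestResult:
    """Independent two-sample t-test result with group summaries."""

    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    variant: str = "student"  # "student" (pooled) or "welch"


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) estimate with 95% CI, significance and reliability band."""

    icc: float
    ci_lower: float
    ci_upper: float
    p: float
    category: str
    n_subjects: int
    n_raters: int
    model: str = "ICC(2,1) two-way random, absolute agreement, single rater"


@dataclass
class SubjectRecord:
    """One subject: anthropometrics, group label, areas and ratios."""

    subject_id: str
    bmi: float
    alt: float
    group: str
    areas: CompartmentAreas
    ratios: RatioSet

    def measures(self) -> dict:
        out = {"MA": self.areas.MA, "SA": self.areas.SA, "VA": self.areas.VA}
        out.update(self.ratios.as_dict())
        return out


def classify_group(bmi: float, alt: float) -> str:
    """Assign the study group from BMI (kg/m²) and serum ALT (IU/L).

    sarcopenic-obesity: BMI >= 25.0 and ALT >= 35;
    healthy: 18.0 <= BMI <= 23.0 and ALT < 35; otherwise unclassified.
    """
    for name, value in (("BMI", bmi), ("ALT", alt)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise DataError(f"missing {name} value; cannot classify subject")
    if bmi >= 25.0 and alt >= 35.0:
        return GROUP_SARCOPENIC
    if 18.0 <= bmi <= 23.0 and alt < 35.0:
        return GROUP_HEALTHY
    return GROUP_UNCLASSIFIED


def two_sample_ttest(group_a, group_b, welch: bool = False) -> TTestResult:
    """Independent two-sample t-test between two groups of values.

    Default is Student's pooled-variance test with nA + nB - 2 degrees
    of freedom and a two-sided p-value; ``welch=True`` switches to the
    unequal-variance variant.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError(
            f"each group needs >= 2 values, got {a.size} and {b.size}")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / (a.size + b.size - 2)
    if pooled == 0:
        raise DegenerateDataError(
            "zero pooled variance: all values identical within groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        variant="welch" if welch else "student",
    )


def classify_reliability(icc: float) -> str:
    """Reliability band for an ICC estimate.

    < 0.5 poor; [0.5, 0.75) moderate; [0.75, 0.9] good; > 0.9 excellent.
    Exactly 0.5 and 0.75 go to the higher band; exactly 0.9 stays good.
    """
    if icc > 1:
        raise DataError(f"ICC cannot exceed 1, got {icc}")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc_2_1(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects × k raters) array with no missing
    cells. From the two-way ANOVA decomposition with mean squares for
    rows/subjects (MSR), columns/raters (MSC) and error (MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The 95% CI is the F-based interval with a Satterthwaite
    approximation for the denominator degrees of freedom; the p-value
    tests ICC = 0 via F = MSR/MSE on (n-1, (n-1)(k-1)) df.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DataError("ratings must be an (n subjects x k>=2 raters) grid")
    if np.isnan(x).any():
        raise DataError("ratings contain missing cells")
    n, k = x.shape
    if n < 5:
        raise DataError(
            f"need >= 5 subjects for a usable ICC confidence interval, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise DegenerateDataError(
            "zero between-subject variance: ICC is undefined for constant ratings")

    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    # guard against cancellation pushing an exact-agreement SSE below 0
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # significance of the subject effect
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        p = float(sps.f.sf(msr / mse, df1, df2))
    else:
        p = 0.0  # perfect agreement

    # F-based CI (two-way random, absolute agreement, single rater)
    if mse > 0 and icc < 1:
        fj = msc / mse
        vn = df2 * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = df1 * k ** 2 * icc ** 2 * fj ** 2 + (
            n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = sps.f.ppf(1 - alpha / 2, df1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, df1)
        lower = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        lower = upper = icc  # exact agreement: degenerate interval at 1

    return IccResult(
        icc=float(icc), ci_lower=float(lower), ci_upper=float(upper), p=p,
        category=classify_reliability(float(icc)), n_subjects=n, n_raters=k,
    )


def cohort_summary(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-group and overall mean ± SD for areas and ratio indexes.

    Returns a tidy DataFrame indexed by (group, measure) with columns
    n/mean/sd; the ``overall`` rows pool every record, so for equal
    group sizes the overall mean is the average of the group means. SD
    uses the n-1 denominator; a single record reports SD = 0.0.
    """
    if not records:
        raise DataError("need at least one subject record")
    rows = []
    for rec in records:
        row = {"group": rec.group, **rec.measures()}
        rows.append(row)
    df = pd.DataFrame(rows)

    def block(sub: pd.DataFrame, label: str):
        out = []
        for measure in MEASURE_NAMES:
            vals = sub[measure].dropna()
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out.append({"group": label, "measure": measure, "n": int(len(vals)),
                        "mean": float(vals.mean()) if len(vals) else float("nan"),
                        "sd": sd})
        return out

    parts = []
    for label, sub in df.groupby("group", sort=True):
        parts.extend(block(sub, label))
    parts.extend(block(df, "overall"))
    return pd.DataFrame(parts).set_index(["group", "measure"])
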