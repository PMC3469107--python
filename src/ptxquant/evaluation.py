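"""Agreement statistics between two sets of relative pneumothorax volumes.

Compares automated measurements against a reference (e.g. manual expert
contours) case by case: per-case absolute errors and their mean, the
Pearson product-moment correlation, a two-sided paired t-test on the
differences (automated - reference, n-1 degrees of freedom), and an
ordinary least-squares trendline of automated on reference values.

A bundled preset carries the printed per-case percentages of the 8-case
validation cohort (automated vs manual) so the summary statistics can be
recomputed without the original CT data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Printed per-case relative pneumothorax sizes (%) of the validation
#: cohort: automated method vs manual segmentation.
TABLE1_AUTO_PCT = (8.10, 0.38, 19.73, 17.29, 5.34, 38.54, 3.04, 19.92)
TABLE1_MANUAL_PCT = (7.93, 0.00, 20.11, 18.44, 6.52, 35.26, 3.97, 19.45)
TABLE1_CASE_IDS = tuple(f"case {i}" for i in range(1, 9))


@dataclass
class MethodComparison:
    """Per-case errors and summary agreement statistics (percent scale)."""

    case_ids: tuple[str, ...]
    auto_pct: tuple[float, ...]
    ref_pct: tuple[float, ...]
    abs_errors: tuple[float, ...]
    mean_abs_error: float
    pearson_r: float
    t_statistic: float
    t_pvalue: float
    slope: float
    intercept: float
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "case_ids": list(self.case_ids),
            "auto_pct": list(self.auto_pct),
            "ref_pct": list(self.ref_pct),
            "abs_errors": [round(e, 4) for e in self.abs_errors],
            "mean_abs_error": self.mean_abs_error,
            "pearson_r": self.pearson_r,
            "t_statistic": self.t_statistic,
            "t_pvalue": self.t_pvalue,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


def compare(auto_pct, ref_pct, case_ids=None) -> MethodComparison:
    """Full agreement comparison of two equal-length percentage series."""
    auto = np.asarray(auto_pct, dtype=np.float64)
    ref = np.asarray(ref_pct, dtype=np.float64)
    if auto.shape != ref.shape or auto.ndim != 1:
        raise ValueError("auto and reference series must be 1D of equal length")
    n = auto.size
    if n < 2:
        raise ValueError(f"need at least 2 cases, got {n}")
    if not (np.isfinite(auto).all() and np.isfinite(ref).all()):
        raise ValueError("percentages must be finite")
    if case_ids is None:
        case_ids = tuple(f"case {i}" for i in range(1, n + 1))
    elif len(case_ids) != n:
        raise ValueError("case_ids length mismatch")

    abs_errors = np.abs(auto - ref)
    d = auto - ref

    if np.ptp(auto) == 0 or np.ptp(ref) == 0:
        warnings.warn("zero variance in a series: Pearson r undefined", stacklevel=2)
        pearson_r = float("nan")
    else:
        pearson_r = float(stats.pearsonr(auto, ref).statistic)

    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences: paired t reported as 0", stacklevel=2)
        t_stat, t_p = 0.0, 1.0
    else:
        res = stats.ttest_rel(auto, ref)
        t_stat, t_p = float(res.statistic), float(res.pvalue)

    if np.ptp(ref) == 0:
        slope, intercept, r_squared = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(ref, auto)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue) ** 2

    return MethodComparison(
        case_ids=tuple(case_ids),
        auto_pct=tuple(auto.tolist()),
        ref_pct=tuple(ref.tolist()),
        abs_errors=tuple(abs_errors.tolist()),
        mean_abs_error=float(abs_errors.mean()),
        pearson_r=pearson_r,
        t_statistic=t_stat,
        t_pvalue=t_p,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
    )


def compare_preset_table1() -> MethodComparison:
    """Agreement statistics of the bundled 8-case validation preset."""
    return compare(TABLE1_AUTO_PCT, TABLE1_MANUAL_PCT, TABLE1_CASE_IDS)


def tabulate(mc: MethodComparison) -> pd.DataFrame:
    """Render a comparison as a per-case table (values at 2 decimals).

    One column per case plus a summary column; rows are the automated
    percentage, the reference percentage and the absolute error.
    """
    if not mc.case_ids:
        raise ValueError("cannot tabulate an empty comparison")
    data = {
        cid: [round(a, 2), round(r, 2), round(e, 2)]
        for cid, a, r, e in zip(mc.case_ids, mc.auto_pct, mc.ref_pct, mc.abs_errors)
    }
    data["summary"] = [np.nan, np.nan, round(mc.mean_abs_error, 2)]
    return pd.DataFrame(
        data, index=["auto PTX % size", "reference PTX % size", "absolute error"]
    )
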