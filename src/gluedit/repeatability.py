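"""Test-retest statistics for repeated concentration measurements.

Implements the classical one-way random-effects, single-measures
intraclass correlation ICC(1,1) with its exact-F 95 % confidence interval,
the coefficient of variation, and per-subject absolute scan-to-scan
differences — the summary statistics used to characterize measurement
repeatability in scan/rescan designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RetestTable",
    "icc_oneway",
    "cov_percent",
    "abs_scan_differences",
    "summarize",
]


@dataclass
class RetestTable:
    """An n-subjects x k-scans concentration matrix (mM), no missing cells."""

    values: np.ndarray
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x scans) array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 scans")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite cells are not allowed")
        if not self.subjects:
            self.subjects = tuple(str(i + 1) for i in range(n))
        elif len(self.subjects) != n:
            raise ValueError("subject label count does not match row count")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_col: str = "subject") -> "RetestTable":
        """Build from a wide table: one subject column, one column per scan."""
        scans = [c for c in df.columns if c != subject_col]
        return cls(
            values=df[scans].to_numpy(dtype=float),
            subjects=tuple(map(str, df[subject_col])),
        )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]


def _anova_oneway(values: np.ndarray) -> tuple[float, float]:
    """Between- and within-subject mean squares of the subjects-as-groups
    one-way ANOVA."""
    n, k = values.shape
    grand = values.mean()
    subj_means = values.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((values - subj_means[:, None]) ** 2) / (n * (k - 1))
    return float(msb), float(msw)


def icc_oneway(table: RetestTable, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(1,1) with its two-sided exact-F confidence interval.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW); the (1 - alpha) CI comes from
    F quantiles with (n-1, n(k-1)) degrees of freedom:
    FL = F_obs / F(1-alpha/2; n-1, n(k-1)),  low = (FL-1)/(FL+k-1), and the
    upper bound symmetrically with the reversed degrees of freedom.

    Degenerate all-equal tables (zero variance both between and within) are
    defined as perfect agreement: ICC 1 with a collapsed CI.
    """
    values = table.values
    n, k = values.shape
    msb, msw = _anova_oneway(values)
    if msw == 0 and msb == 0:
        return 1.0, 1.0, 1.0
    if msw == 0:
        return 1.0, 1.0, 1.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    low = (fl - 1) / (fl + k - 1)
    high = (fu - 1) / (fu + k - 1)
    return float(icc), float(low), float(high)


def icc_pvalue(table: RetestTable) -> float:
    """p-value of the one-way ANOVA F test (H0: ICC = 0)."""
    values = table.values
    n, k = values.shape
    msb, msw = _anova_oneway(values)
    if msw == 0:
        return 0.0
    return float(stats.f.sf(msb / msw, n - 1, n * (k - 1)))


def cov_percent(values) -> float:
    """Coefficient of variation, 100 * SD / mean with the sample (n-1) SD."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero; CoV undefined")
    return float(100.0 * v.std(ddof=1) / mean)


def abs_scan_differences(table: RetestTable) -> tuple[np.ndarray, float]:
    """Per-subject |scan1 - scan2| and their maximum (two-scan tables only)."""
    if table.n_scans != 2:
        raise ValueError("absolute scan differences require exactly two scans")
    d = np.abs(table.values[:, 0] - table.values[:, 1])
    return d, float(d.max())


def summarize(table: RetestTable, alpha: float = 0.05) -> dict:
    """Aggregate repeatability report: mean, SD, CoV, ICC with CI and p,
    and (for two-scan tables) the per-subject absolute differences."""
    v = table.values.ravel()
    icc, lo, hi = icc_oneway(table, alpha=alpha)
    out = {
        "n_subjects": table.n_subjects,
        "n_scans": table.n_scans,
        "mean_mM": float(v.mean()),
        "sd_mM": float(v.std(ddof=1)),
        "cov_percent": cov_percent(v),
        "icc": icc,
        "icc_ci_low": lo,
        "icc_ci_high": hi,
        "icc_p": icc_pvalue(table),
    }
    if table.n_scans == 2:
        diffs, dmax = abs_scan_differences(table)
        out["abs_differences_mM"] = diffs.tolist()
        out["max_abs_difference_mM"] = dmax
    return out
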