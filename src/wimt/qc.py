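"""Quantitative QC statistics: lognormal CV, replicate correlation,
dilution-median linearity and abundance-decile grouping."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv_lognormal",
    "replicate_correlation",
    "dilution_median_linearity",
    "abundance_groups",
    "qc_report",
    "QCReport",
]


def cv_lognormal(replicate_intensities) -> float:
    """Coefficient of variation (%) under a lognormal error model.

    ``CV% = 100 * sqrt(exp(s^2) - 1)`` with ``s`` the sample SD (n-1
    denominator) of the natural-log intensities -- appropriate when
    measurement error is multiplicative. Input is linear-scale and must be
    positive with at least two replicates.
    """
    x = np.asarray(replicate_intensities, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 replicate values")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intensities must be positive and finite")
    s = np.log(x).std(ddof=1)
    return 100.0 * np.sqrt(np.expm1(s * s))


def cv_lognormal_rows(matrix: pd.DataFrame) -> pd.Series:
    """Row-wise lognormal CV% over replicate columns (NaN-aware, >=2 values)."""
    ln = np.log(matrix.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanstd(ln, axis=1, ddof=1)
    n = np.isfinite(ln).sum(axis=1)
    cv = 100.0 * np.sqrt(np.expm1(s * s))
    cv[n < 2] = np.nan
    return pd.Series(cv, index=matrix.index, name="cv_percent")


def replicate_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson R of log2 intensities over proteins present in both replicates."""
    df = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 shared proteins")
    x, y = np.log2(df.iloc[:, 0]), np.log2(df.iloc[:, 1])
    return float(stats.pearsonr(x, y).statistic)


def dilution_median_linearity(matrix: pd.DataFrame, amounts: Sequence[float]):
    """Pearson R of per-dilution medians of log2 intensity vs log2 amount.

    ``matrix`` is proteins x dilution points of log2 intensities; each
    column's median is regressed (OLS) on the log2 loaded amount. Returns
    ``(R, slope, medians)``.
    """
    amounts = np.asarray(list(amounts), dtype=float)
    if matrix.shape[1] != len(amounts):
        raise ValueError("one amount per matrix column required")
    if len(amounts) < 3:
        raise ValueError("need >= 3 dilution points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(matrix.to_numpy(dtype=float), axis=0)
    if np.any(~np.isfinite(medians)):
        raise ValueError("a dilution column is entirely missing")
    x = np.log2(amounts)
    res = stats.linregress(x, medians)
    return float(res.rvalue), float(res.slope), pd.Series(medians, index=matrix.columns)


def abundance_groups(intensities: pd.Series, n_groups: int = 10) -> pd.Series:
    """Rank proteins by intensity and split into ``n_groups`` balanced groups.

    Proteins are sorted by descending intensity (ties broken by accession)
    and partitioned contiguously into groups whose sizes differ by at most
    one, larger groups first; group 1 is the most abundant. If there are
    fewer proteins than groups, ``n_groups`` is reduced with a warning so
    that no group is empty.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    n = len(intensities)
    if n == 0:
        raise ValueError("no proteins to group")
    if n < n_groups:
        warnings.warn(f"only {n} proteins; reducing n_groups from {n_groups} to {n}")
        n_groups = n
    order = sorted(intensities.index, key=lambda p: (-intensities[p], p))
    base, extra = divmod(n, n_groups)
    sizes = [base + 1] * extra + [base] * (n_groups - extra)
    labels = np.repeat(np.arange(1, n_groups + 1), sizes)
    return pd.Series(labels, index=order, name="abundance_group").reindex(intensities.index)


@dataclass
class QCReport:
    """Per-protein CV table plus summary statistics of one condition."""

    cv: pd.Series
    median_cv: float
    frac_cv_below_25: float
    replicate_r: float
    abundance_group: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat([self.cv, self.abundance_group], axis=1)
        df.attrs.update(
            median_cv=self.median_cv,
            frac_cv_below_25=self.frac_cv_below_25,
            replicate_r=self.replicate_r,
        )
        return df


def qc_report(replicate_matrix: pd.DataFrame, n_groups: int = 10) -> QCReport:
    """QC of one condition's replicate columns (linear-scale intensities).

    Reports the per-protein lognormal CV, the median CV, the fraction of
    proteins with CV < 25%, the log2 Pearson R of the first two replicate
    columns, and the abundance group (1..n_groups) from the mean intensity.
    """
    cv = cv_lognormal_rows(replicate_matrix)
    mean_int = replicate_matrix.mean(axis=1)
    groups = abundance_groups(mean_int.dropna(), n_groups=n_groups)
    rep_r = (
        replicate_correlation(replicate_matrix.iloc[:, 0], replicate_matrix.iloc[:, 1])
        if replicate_matrix.shape[1] >= 2 else float("nan")
    )
    valid = cv.dropna()
    return QCReport(
        cv=cv,
        median_cv=float(valid.median()),
        frac_cv_below_25=float((valid < 25.0).mean()),
        replicate_r=rep_r,
        abundance_group=groups,
    )
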