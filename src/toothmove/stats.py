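"""Cohort statistics for prediction differences.

One-sample t tests of each tooth-type x measure cell against zero with a
Bonferroni correction over the whole family (default: all 4 types x 6
measures = 24 simultaneous tests, the most conservative reading;
configurable to per-measure or per-type families), Bonferroni-adjusted
simultaneous confidence intervals (dual to the adjusted tests: the
adjusted CI excludes 0 exactly when the adjusted p falls below alpha),
and measurement-agreement statistics: two-way absolute-agreement
single-measure ICC — ICC(A,1) — and Bland–Altman limits of agreement.

Teeth within a patient are treated as independent observations; no
clustering correction is applied (a known limitation of the design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crownprep import TOOTH_TYPES

__all__ = [
    "MEASURE_ORDER",
    "TestResult",
    "AgreementResult",
    "one_sample_t",
    "bonferroni",
    "adjusted_ci",
    "family_size",
    "run_cohort_tests",
    "icc_agreement",
    "bland_altman",
]

#: Column order of the six measures in every report (angles then translations).
MEASURE_ORDER = ("phi", "theta", "psi", "x", "y", "z")

_MEASURE_COLUMNS = {
    "phi": "phi_deg", "theta": "theta_deg", "psi": "psi_deg",
    "x": "x_mm", "y": "y_mm", "z": "z_mm",
}


@dataclass(frozen=True)
class TestResult:
    tooth_type: str
    measure: str
    n: int
    mean: float
    sd: float
    t_stat: float
    p_raw: float
    p_adj: float
    ci_low: float
    ci_high: float
    m_family: int


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float, float, float]:
    """Classical one-sample t test of H0: mean = mu0 (two-sided).

    Returns (t, p, mean, sd); sd uses the n-1 denominator.  Degenerate
    samples with sd = 0 return p = 1 if the mean equals mu0 and p = 0
    (with a warning) otherwise.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("one-sample t requires n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        if mean == mu0:
            return 0.0, 1.0, mean, sd
        warnings.warn("zero variance with mean != mu0: p set to 0", stacklevel=2)
        return float(np.inf if mean > mu0 else -np.inf), 0.0, mean, sd
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return float(t), p, mean, sd


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, m * p)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def adjusted_ci(values, alpha: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Bonferroni-adjusted simultaneous CI: mean +/- t_{1-(alpha/m)/2, n-1} * se.

    With m = 1 this is the textbook (1 - alpha) CI.  Dual to the adjusted
    test: the interval excludes 0 iff min(1, m*p) < alpha.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("CI requires n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return mean, mean
    tcrit = float(sps.t.ppf(1.0 - (alpha / m) / 2.0, df=n - 1))
    half = tcrit * sd / np.sqrt(n)
    return mean - half, mean + half


def family_size(family: str, n_types: int = len(TOOTH_TYPES),
                n_measures: int = len(MEASURE_ORDER)) -> int:
    """Number of simultaneous tests for the chosen Bonferroni family."""
    if family == "all":
        return n_types * n_measures
    if family == "per-measure":
        return n_types
    if family == "per-type":
        return n_measures
    raise ValueError(f"unknown family {family!r}; use all|per-measure|per-type")


def run_cohort_tests(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "all",
) -> pd.DataFrame:
    """One-sample t tests of every tooth-type x measure cell against zero.

    ``cohort`` must carry columns tooth_type and the six measure columns
    (phi_deg … z_mm).  Rows are ordered type-major, measures in
    (Phi, Theta, Psi, X, Y, Z) order.  Cells with n < 2 are reported as
    untestable (NaN statistics), never silently dropped.
    """
    m = family_size(family)
    rows = []
    for tooth_type in TOOTH_TYPES:
        sub = cohort[cohort["tooth_type"] == tooth_type]
        for measure in MEASURE_ORDER:
            col = _MEASURE_COLUMNS[measure]
            v = sub[col].to_numpy(dtype=float) if len(sub) else np.array([])
            if v.size < 2:
                rows.append(TestResult(tooth_type, measure, int(v.size),
                                       np.nan, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, np.nan, m))
                continue
            t, p, mean, sd = one_sample_t(v)
            p_adj = float(bonferroni([p], m)[0])
            lo, hi = adjusted_ci(v, alpha=alpha, m=m)
            rows.append(TestResult(tooth_type, measure, int(v.size),
                                   mean, sd, t, p, p_adj, lo, hi, m))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["significant"] = df["p_adj"] < alpha
    return df


def icc_agreement(ratings_a, ratings_b) -> float:
    """Two-way, single-measure, absolute-agreement ICC — ICC(A,1).

    From the two-way ANOVA mean squares with n subjects and k = 2 raters::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the rows (subjects), columns (raters) and
    residual mean squares.  Undefined (raises) when there is no
    between-subject variance.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("ICC requires at least 3 paired ratings")
    data = np.column_stack([a, b])  # n subjects x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-300 and mse <= 1e-300:
        raise ValueError("ICC undefined: no between-subject variance")
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


def bland_altman(a, b, loa_multiplier: float = 1.96) -> AgreementResult:
    """Bland–Altman agreement of paired measurements.

    Differences d = a - b; limits of agreement = mean(d) +/- 1.96 sd(d)
    (sd with n-1 denominator).  The (mean, difference) points are returned
    for plotting.  ICC is not computed here; the field is NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        icc=float("nan"),
        ba_mean_diff=mean_diff,
        ba_loa_low=mean_diff - loa_multiplier * sd,
        ba_loa_high=mean_diff + loa_multiplier * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )
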