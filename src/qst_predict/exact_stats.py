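"""Exact and rank-based statistics shared across the pipeline.

Small-sample clinical cohorts (n ≈ 30 per arm) rule out asymptotic-only
tests, so the significance machinery here is exact wherever feasible:

* two-sided Fisher's exact test on 2x2 tables, using the point-probability
  ("Irwin") rule — the p-value sums the hypergeometric probabilities of all
  tables sharing the observed margins whose probability does not exceed the
  observed table's (within a relative tolerance of 1e-7).  This convention
  is pinned because the alternative ("double the one tail") gives different
  p-values on asymmetric tables.
* Mann-Whitney U with an exact null distribution for small untied samples
  and a tie-corrected, continuity-corrected normal approximation otherwise;
  the result records which path ran.
* median / interquartile-range summaries using inclusive linear
  interpolation between closest ranks.  The quartile definition is pinned
  here because the synthetic-cohort calibration depends on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "MedianIQR",
    "Table2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "median_iqr",
    "compare_groups",
]

#: upper quartile of the standard normal; converts an IQR on the (possibly
#: log-transformed) axis into a normal scale parameter.
Z_UPPER_QUARTILE = float(_sps.norm.ppf(0.75))

#: relative tolerance used when deciding whether a table's probability
#: "does not exceed" the observed one in the two-sided Fisher rule.
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class MedianIQR:
    """A median with its interquartile range, the summary used throughout.

    ``q1 <= median <= q3`` is enforced; strict positivity is *not* — pain
    thresholds are positive but percent-change quantities (CPM effect) may
    straddle zero, so positivity is checked by consumers that need it.
    """

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"quartiles must satisfy q1 <= median <= q3, got "
                f"({self.q1}, {self.median}, {self.q3})"
            )

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.median, self.q1, self.q3)


@dataclass(frozen=True)
class Table2x2:
    """2x2 count table; rows index truth, columns prediction (or group).

    Layout: ``[[a, b], [c, d]]``.  For a responder confusion matrix the
    convention is a = true positives, b = false negatives, c = false
    positives, d = true negatives.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test with its significance flag.

    ``significant`` is evaluated against the alpha the caller declared
    (0.05 by default; 0.01 once the multiplicity rule applies).
    """

    statistic: float
    p_value: float
    method: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_two_sided(table: Table2x2, alpha: float = 0.05) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The statistic reported is the sample odds ratio (``inf`` when the
    denominator is zero, ``nan`` for 0/0).  The p-value follows the
    point-probability rule: enumerate every table with the observed
    margins, via log-factorials for numerical safety, and sum the
    hypergeometric probabilities that are <= the observed table's
    probability up to a relative tolerance of 1e-7.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_denom = _log_choose(n, c1)

    def log_p(x: int) -> float:
        return _log_choose(r1, x) + _log_choose(r2, c1 - x) - log_denom

    log_p_obs = log_p(a)
    cutoff = log_p_obs + math.log1p(_FISHER_REL_TOL)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= cutoff:
            p += math.exp(lp)
    p = min(p, 1.0)

    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return TestResult(statistic=odds, p_value=p, method="fisher_exact_two_sided", alpha=alpha)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: combined sample size at or below which the exact null distribution is
#: used (provided the data carry no ties).
EXACT_MWU_MAX_N = 20


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    The statistic is U for the first sample with midrank handling of ties
    (so two identical samples give U = n_x * n_y / 2).  When the combined
    sample size is at most ``EXACT_MWU_MAX_N`` and there are no ties the
    p-value comes from the exact permutation null; otherwise a normal
    approximation with tie correction and continuity correction is used.
    ``method`` records which path ran.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("samples must not contain NaN")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MWU_MAX_N and not has_ties:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact_enumeration"
    else:
        res = _sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx_tie_corrected"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Summaries and group comparison tables
# ---------------------------------------------------------------------------

def median_iqr(sample: Iterable[float]) -> MedianIQR:
    """Median and quartiles by inclusive linear interpolation between ranks."""
    arr = np.asarray(list(sample), dtype=float)
    if arr.size == 0:
        raise ValueError("sample must be non-empty")
    if np.isnan(arr).any():
        raise ValueError("sample must not contain NaN")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return MedianIQR(median=float(med), q1=float(q1), q3=float(q3))


#: more than this many simultaneous comparisons triggers the stricter
#: alpha of 0.01 instead of 0.05.
MULTIPLICITY_VARIABLE_LIMIT = 5


def compare_groups(
    data: pd.DataFrame,
    groups: Sequence[bool],
    group_names: tuple[str, str] = ("responder", "nonresponder"),
) -> pd.DataFrame:
    """Compare every column of ``data`` between two groups.

    Continuous columns are tested with Mann-Whitney U and summarised as
    median (IQR) per group; binary/categorical columns are cross-tabulated
    and tested with Fisher's exact test.  Missing values are dropped per
    variable.  When more than ``MULTIPLICITY_VARIABLE_LIMIT`` variables are
    tested the significance flag uses alpha = 0.01, otherwise 0.05 — a
    fixed stricter threshold rather than a p-value adjustment.

    Parameters
    ----------
    data:
        One row per patient, one column per variable.
    groups:
        Boolean group membership aligned with ``data`` rows (True = first
        group of ``group_names``).

    Returns
    -------
    DataFrame with one row per variable: group summaries, the test p-value,
    the method used and the significance flag.
    """
    groups = np.asarray(groups, dtype=bool)
    if groups.shape[0] != len(data):
        raise ValueError("groups must align with data rows")
    if groups.all() or (~groups).all():
        raise ValueError("grouping variable must have two levels")

    alpha = 0.01 if data.shape[1] > MULTIPLICITY_VARIABLE_LIMIT else 0.05
    rows = []
    for col in data.columns:
        series = data[col]
        mask = series.notna().to_numpy()
        vals = series[mask]
        g = groups[mask]
        if vals.empty or g.all() or not g.any():
            continue
        if pd.api.types.is_numeric_dtype(series) and vals.nunique() > 2:
            res = mann_whitney_u(vals[g].to_numpy(float), vals[~g].to_numpy(float), alpha=alpha)
            s1, s2 = median_iqr(vals[g]), median_iqr(vals[~g])
            fmt = "{0.median:.3g} ({0.q1:.3g}-{0.q3:.3g})"
            sum1, sum2 = fmt.format(s1), fmt.format(s2)
        else:
            levels = sorted(vals.unique().tolist())
            if len(levels) != 2:
                raise ValueError(
                    f"categorical variable {col!r} must be binary for the exact test, "
                    f"has levels {levels}"
                )
            a = int(((vals == levels[0]) & g).sum())
            b = int(((vals == levels[1]) & g).sum())
            c = int(((vals == levels[0]) & ~g).sum())
            d = int(((vals == levels[1]) & ~g).sum())
            res = fisher_exact_two_sided(Table2x2(a, b, c, d), alpha=alpha)
            sum1 = f"{a}/{a + b} {levels[0]}"
            sum2 = f"{c}/{c + d} {levels[0]}"
        rows.append(
            {
                "variable": col,
                group_names[0]: sum1,
                group_names[1]: sum2,
                "p_value": res.p_value,
                "method": res.method,
                "alpha": alpha,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
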