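"""Small-cohort comparative statistics.

Every procedure a two-group clinical comparison of this kind calls for:
exact and asymptotic contingency-table tests, pooled-variance Student t
(from raw samples or from printed mean +/- SD summaries), Mann-Whitney U,
Pearson and Spearman correlation, and Kaplan-Meier survival with the
log-rank test.  All tests are two-sided; the conventional significance
level is alpha = 0.05.  No multiple-testing correction is applied — each
table row is reported at its nominal level, and reports say so.

Notable conventions, chosen to match how clinical tables of this kind are
produced: the t test pools variances (Student, not Welch); the two-sided
Fisher p is the small-p-values sum (all tables with the same margins whose
hypergeometric probability does not exceed the observed one), not the
doubled one-tail; the chi-square statistic carries no continuity
correction; 2x2 categorical comparisons route to Fisher when any expected
count is below 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "ALPHA",
    "ContingencyTable",
    "SummaryStat",
    "TestResult",
    "CorrelationResult",
    "KmCurve",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "choose_categorical_test",
    "t_test_from_summary",
    "t_test_raw",
    "mann_whitney_u",
    "pearson_r",
    "spearman_rho",
    "km_estimate",
    "logrank",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """r x c counts with row (group) and column (category) labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need an r x c table with r >= 2 and c >= 2")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @classmethod
    def from_counts(cls, counts: Sequence[Sequence[int]], **kw) -> "ContingencyTable":
        return cls(tuple(tuple(int(c) for c in row) for row in counts), **kw)


@dataclass(frozen=True)
class SummaryStat:
    """A printed mean +/- SD cell with its group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2")


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: float | None
    p_two_sided: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Fisher's exact test for a 2x2 table, two-sided.

    The two-sided p sums the hypergeometric probabilities of every table
    with the observed margins that is no more probable than the observed
    one.  A zero margin makes the table degenerate: p = 1 with a warning.
    """
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (a zero margin); p set to 1")
        return TestResult("fisher_exact", float("nan"), None, 1.0)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), None, float(p))


def chi_square_rxc(table: ContingencyTable) -> TestResult:
    """Pearson chi-square without continuity correction; df = (r-1)(c-1)."""
    arr = table.array
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected == 0):
        raise ValueError("zero expected count; chi-square undefined")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult("chi_square", float(chi2), float(df), float(p))


def choose_categorical_test(table: ContingencyTable) -> TestResult:
    """Route a categorical comparison the way clinical tables do.

    2x2 tables go to Fisher's exact test when any expected count is below 5,
    otherwise to the chi-square test; larger tables always use chi-square.
    """
    arr = table.array
    if arr.shape == (2, 2):
        expected = stats.contingency.expected_freq(arr)
        if (expected < 5).any():
            return fisher_exact_2x2(table)
    return chi_square_rxc(table)


def _degenerate_t(mean_a: float, mean_b: float) -> TestResult:
    if mean_a == mean_b:
        return TestResult("student_t_pooled", 0.0, None, 1.0)
    warnings.warn("zero variance with unequal means; p set to 0")
    return TestResult("student_t_pooled", float("inf"), None, 0.0)


def t_test_from_summary(a: SummaryStat, b: SummaryStat) -> TestResult:
    """Pooled-variance Student t from two mean +/- SD / n summaries.

    s^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2);
    t = (mean_a - mean_b) / (s sqrt(1/n_a + 1/n_b)); df = n_a + n_b - 2.
    """
    if a.sd == 0 and b.sd == 0:
        return _degenerate_t(a.mean, b.mean)
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TestResult("student_t_pooled", float(t), float(a.n + b.n - 2), float(p))


def t_test_raw(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> TestResult:
    """Student's t on raw samples: pooled-variance unpaired, or paired."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        if len(x) < 2:
            raise ValueError("need at least two pairs")
        d = x - y
        if np.ptp(d) == 0:
            res = _degenerate_t(float(d[0]), 0.0)
            return TestResult("student_t_paired", res.statistic, None, res.p_two_sided)
        t, p = stats.ttest_rel(x, y)
        return TestResult("student_t_paired", float(t), float(len(x) - 1), float(p))
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return _degenerate_t(float(x[0]), float(y[0]))
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult("student_t_pooled", float(t), float(len(x) + len(y) - 2), float(p))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U with midranks for ties.

    The exact null distribution is enumerated for small tie-free samples
    (n_x * n_y <= 400); otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # everything tied: midranks make U its null mean, no evidence either way
        return TestResult("mann_whitney_u_normal", 0.5 * len(x) * len(y), None, 1.0)
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    exact = not has_ties and len(x) * len(y) <= 400
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        "mann_whitney_u" + ("_exact" if exact else "_normal"),
        float(res.statistic),
        None,
        float(min(1.0, res.pvalue)),
    )


def _check_corr_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a vector has zero variance")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t transform (df = n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    _check_corr_inputs(x, y)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult("pearson", float(r), float(p), len(x))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (midranks, then Pearson; t-transform p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    _check_corr_inputs(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), len(x))


def km_estimate(
    times: Sequence[float], events: Sequence[bool]
) -> KmCurve:
    """Kaplan-Meier product-limit estimate.

    Ties between deaths and censorings at the same time follow the standard
    convention: deaths are processed first, so a subject censored at an
    event time is still at risk for that event.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KmCurve(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    events = np.concatenate([np.asarray(events_a, bool), np.asarray(events_b, bool)])
    if not events.any():
        raise ValueError("log-rank undefined: no events in either group")
    res = _lifelines_logrank(
        np.asarray(times_a, float),
        np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, bool),
        event_observed_B=np.asarray(events_b, bool),
    )
    return TestResult("logrank", float(res.test_statistic), 1.0, float(res.p_value))


def summarize_continuous(values: pd.Series) -> SummaryStat:
    """Mean +/- SD / n summary of one group's raw values."""
    v = values.dropna().to_numpy(float)
    return SummaryStat(float(v.mean()), float(v.std(ddof=1)), len(v))
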