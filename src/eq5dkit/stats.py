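"""Contingency-table tests and summary statistics.

All procedures are implemented directly from their definitions (only
reference distribution functions come from :mod:`scipy.stats`):

* :func:`chi_square` -- Pearson chi-square for r x c tables, with the
  Yates continuity correction available for 2 x 2 tables;
* :func:`fisher_exact` -- the Freeman-Halton exact conditional test for
  r x c tables by full enumeration of the fixed-margin table space;
* :func:`welch_t` -- two-sample t from summary statistics with the
  Welch-Satterthwaite degrees of freedom;
* :func:`median_iqr` -- median and quartiles under a configurable
  quantile convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

__all__ = [
    "StatError",
    "EnumerationLimitError",
    "ContingencyTable",
    "TestResult",
    "SummaryStats",
    "chi_square",
    "fisher_exact",
    "welch_t",
    "median_iqr",
    "summarize",
]


class StatError(ValueError):
    """Raised for invalid statistical inputs."""


class EnumerationLimitError(StatError):
    """Raised when exact-test enumeration would exceed the table bound."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labels.

    Requires r >= 2 and c >= 2 and a grand total of at least 1.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise StatError("counts must be a 2-d array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise StatError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise StatError(f"table must be at least 2 x 2, got {counts.shape}")
        if (counts < 0).any():
            raise StatError("counts must be non-negative")
        if counts.sum() < 1:
            raise StatError("table grand total must be at least 1")
        object.__setattr__(self, "counts", counts)
        r, c = counts.shape
        rows = tuple(self.row_labels) or tuple(f"r{i}" for i in range(r))
        cols = tuple(self.col_labels) or tuple(f"c{j}" for j in range(c))
        if len(rows) != r or len(cols) != c:
            raise StatError("label lengths must match table shape")
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def drop_empty(self) -> "ContingencyTable":
        """Drop all-zero rows and columns (shape must stay >= 2 x 2)."""
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            self.counts[np.ix_(keep_r, keep_c)],
            tuple(np.asarray(self.row_labels, dtype=object)[keep_r]),
            tuple(np.asarray(self.col_labels, dtype=object)[keep_c]),
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` and ``df`` are ``None`` for exact tests, which are
    characterised by the p-value alone.
    """

    method: str
    p_value: float
    statistic: float | None = None
    df: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        out = {"method": self.method, "p_value": float(self.p_value)}
        if self.statistic is not None:
            out["statistic"] = float(self.statistic)
        if self.df is not None:
            out["df"] = float(self.df) if self.df % 1 else int(self.df)
        out.update(self.detail)
        return out


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and size of one sample."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatError("summary statistics require n >= 2")
        if self.sd < 0:
            raise StatError("standard deviation must be non-negative")


def summarize(values: Sequence[float]) -> SummaryStats:
    """Summary statistics (mean, sample SD, n) of raw values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatError("need at least two values")
    return SummaryStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


def chi_square(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    The statistic is ``sum((O - E)^2 / E)`` with ``(r-1)(c-1)`` degrees
    of freedom.  With ``yates=True`` (legal only for 2 x 2 tables) each
    ``|O - E|`` is reduced by 0.5, floored at 0, before squaring.

    Raises
    ------
    StatError
        If any expected count is zero (use :func:`fisher_exact`), or if
        the Yates correction is requested for a table larger than 2 x 2.
    """
    counts = table.counts.astype(float)
    r, c = counts.shape
    if yates and (r, c) != (2, 2):
        raise StatError("the Yates continuity correction applies only to 2 x 2 tables")
    n = counts.sum()
    expected = np.outer(table.row_totals, table.col_totals) / n
    if (expected == 0).any():
        raise StatError(
            "zero expected count (an empty row or column); "
            "drop it or use fisher_exact"
        )
    diff = np.abs(counts - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    statistic = float((diff**2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(chi2_dist.sf(statistic, df))
    method = "pearson_chi2_yates" if yates else "pearson_chi2"
    return TestResult(method=method, statistic=statistic, df=df, p_value=p)


def _row_compositions(total: int, caps: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """Yield tuples of non-negative ints summing to ``total``, bounded by ``caps``."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    tail_cap = sum(caps[1:])
    lo = max(0, total - tail_cap)
    hi = min(total, caps[0])
    for v in range(lo, hi + 1):
        for rest in _row_compositions(total - v, caps[1:]):
            yield (v, *rest)


def fisher_exact(
    table: ContingencyTable,
    *,
    max_tables: int = 2_000_000,
    tie_tol: float = 1e-7,
) -> TestResult:
    """Freeman-Halton exact conditional test of independence.

    Enumerates every table with the observed row and column margins,
    computes each table's multivariate hypergeometric probability, and
    sums the probabilities of tables no more probable than the observed
    one (ties admitted within relative tolerance ``tie_tol``).  For
    2 x 2 tables this reduces to the two-sided Fisher exact test.

    Raises
    ------
    EnumerationLimitError
        When more than ``max_tables`` fixed-margin tables would need to
        be visited; use :func:`chi_square` instead for such tables.
    """
    counts = table.counts
    r, c = counts.shape
    row_sums = tuple(int(v) for v in table.row_totals)
    col_sums = tuple(int(v) for v in table.col_totals)
    n = table.n
    logfact = gammaln(np.arange(n + 1) + 1.0)
    log_margin = float(
        logfact[list(row_sums)].sum() + logfact[list(col_sums)].sum() - logfact[n]
    )
    log_p_obs = log_margin - float(logfact[counts.ravel()].sum())
    threshold = log_p_obs + np.log1p(tie_tol)

    visited = 0
    p_total = 0.0

    def recurse(row_idx: int, col_rem: tuple[int, ...], log_cells: float) -> None:
        nonlocal visited, p_total
        if row_idx == r - 1:
            # last row is forced by the remaining column margins
            visited += 1
            if visited > max_tables:
                raise EnumerationLimitError(
                    f"more than {max_tables} tables with these margins; "
                    "use chi_square instead"
                )
            log_p = log_margin - log_cells - float(logfact[list(col_rem)].sum())
            if log_p <= threshold:
                p_total += float(np.exp(log_p))
            return
        for comp in _row_compositions(row_sums[row_idx], col_rem):
            recurse(
                row_idx + 1,
                tuple(a - b for a, b in zip(col_rem, comp)),
                log_cells + float(logfact[list(comp)].sum()),
            )

    recurse(0, col_sums, 0.0)
    return TestResult(
        method="fisher_exact",
        p_value=min(p_total, 1.0),
        detail={"tables_enumerated": visited},
    )


def welch_t(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Two-sample t test from summary statistics, unequal variances.

    ``t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)`` with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    The pooled-variance degrees of freedom ``n_a + n_b - 2`` are also
    reported in ``detail["pooled_df"]`` since some reports print those
    alongside the unequal-variance statistic.
    """
    if a.sd == 0 and b.sd == 0:
        raise StatError("both standard deviations are zero")
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    se = np.sqrt(va + vb)
    t = float((a.mean - b.mean) / se)
    df = float((va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1)))
    p = float(2.0 * t_dist.sf(abs(t), df))
    return TestResult(
        method="welch_t",
        statistic=t,
        df=df,
        p_value=min(p, 1.0),
        detail={"pooled_df": a.n + b.n - 2},
    )


_QUANTILE_METHODS = {"linear": "linear", "nearest_rank": "inverted_cdf"}


def median_iqr(
    values: Sequence[float], method: str = "linear"
) -> tuple[float, float, float]:
    """Median and quartiles ``(median, q1, q3)`` of ``values``.

    ``method`` selects the quantile convention: ``"linear"`` (linear
    interpolation between order statistics, the default) or
    ``"nearest_rank"`` (the smallest value with cumulative frequency at
    least the target).  When more than half of the values are identical
    the median equals that value under either convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise StatError("median_iqr requires a non-empty sequence")
    if method not in _QUANTILE_METHODS:
        raise StatError(f"unknown quantile method {method!r}")
    np_method = _QUANTILE_METHODS[method]
    q1, med, q3 = (
        float(v) for v in np.quantile(arr, [0.25, 0.5, 0.75], method=np_method)
    )
    return med, q1, q3
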