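"""Rank-based tests and helpers for paired concentration-response data.

Implements the within-unit testing chain used for MEA spike counts — the
tie-corrected Friedman test, Conover's rank-based many-to-one post hoc, and
Benjamini–Hochberg step-up adjustment — plus the exact Mann–Whitney U test
used for small two-group comparisons and the linear-interpolation sample
quantile behind the unit-inclusion window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "friedman_test",
    "conover_many_to_one",
    "bh_adjust",
    "mann_whitney_exact",
    "sample_quantile",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    sample_sizes: tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "df": None if self.df is None else float(self.df),
            "sample_sizes": self.sample_sizes,
            **({"extra": self.extra} if self.extra else {}),
        }


def _rank_matrix(matrix: np.ndarray) -> np.ndarray:
    """Midranks within each row (block)."""
    return np.apply_along_axis(stats.rankdata, 1, matrix)


def _validate_block_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D blocks x conditions matrix")
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 complete blocks")
    if not np.isfinite(m).all():
        raise ValueError("missing or non-finite cells: complete-block design required")
    return m


def friedman_test(matrix) -> TestResult:
    """Friedman test for paired data on a blocks x conditions matrix.

    Uses within-block midranks and the tie-corrected chi-square statistic

        Q = (k-1) * [sum_j R_j^2 - n^2 k (k+1)^2 / 4] / [sum_ij r_ij^2 - n k (k+1)^2 / 4]

    with df = k-1; reduces to the textbook 12/(nk(k+1)) form when tie-free.
    If every block is internally constant the statistic is 0 and p = 1.
    """
    m = _validate_block_matrix(matrix)
    n, k = m.shape
    r = _rank_matrix(m)
    col_sums = r.sum(axis=0)
    c = n * k * (k + 1) ** 2 / 4.0
    denom = (r**2).sum() - c
    if denom <= 0:  # all blocks constant: no information
        return TestResult(0.0, 1.0, "friedman", df=k - 1, sample_sizes=(n, k))
    q = (k - 1) * ((col_sums**2).sum() - n**2 * k * (k + 1) ** 2 / 4.0) / denom
    p = float(stats.chi2.sf(q, k - 1))
    return TestResult(float(q), p, "friedman", df=k - 1, sample_sizes=(n, k))


def friedman_statistic(matrix) -> float:
    """The tie-corrected Friedman chi-square statistic alone (0 if degenerate)."""
    return friedman_test(matrix).statistic


def conover_many_to_one(
    matrix, control_index: int = 0, two_sided: bool = True
) -> list[TestResult]:
    """Conover rank post hoc: each condition versus a designated control.

    After a Friedman layout (blocks x conditions, within-block midranks), the
    statistic for condition j versus the control is

        t = (R_j - R_c) / sqrt(2 (n A1 - sum_j R_j^2) / ((n-1)(k-1)))

    with A1 the sum of squared midranks; equivalently the denominator is
    2 n (A1 - C1)(1 - Q/(n(k-1))) / ((n-1)(k-1)) with C1 = n k (k+1)^2 / 4
    and Q the tie-corrected Friedman statistic.  Referred to a t
    distribution on (n-1)(k-1) df.  Returns one :class:`TestResult` per
    non-control condition, in column order.
    """
    m = _validate_block_matrix(matrix)
    n, k = m.shape
    if not (0 <= control_index < k):
        raise ValueError(f"control_index {control_index} outside 0..{k - 1}")
    r = _rank_matrix(m)
    col_sums = r.sum(axis=0)
    a1 = (r**2).sum()
    df = (n - 1) * (k - 1)
    var = 2.0 * (n * a1 - (col_sums**2).sum()) / df
    results: list[TestResult] = []
    for j in range(k):
        if j == control_index:
            continue
        diff = col_sums[j] - col_sums[control_index]
        if var <= 0:
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            t = diff / np.sqrt(var)
            p = 2.0 * stats.t.sf(abs(t), df) if two_sided else stats.t.sf(t, df)
        results.append(
            TestResult(
                float(t),
                float(min(p, 1.0)),
                "conover-many-to-one",
                df=df,
                sample_sizes=(n, k),
                extra={"condition": j, "control": control_index},
            )
        )
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} min(1, p_(j) * m / j) over sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U for group x (midrank convention for ties)."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return ranks[:n1].sum() - n1 * (n1 + 1) / 2.0


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U over all C(n1+n2, n1) arrangements.

    Dynamic program over the number of arrangements of n1 'x' labels among
    n1+n2 tie-free values producing each rank-sum.
    """
    max_u = n1 * n2
    # f[i, u]: arrangements of the first `pos` order statistics with i x-labels
    # and U contribution u; the value at `pos` exceeds all earlier ones, so
    # labelling it 'x' adds (pos - i) y-values below it to U.
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    for pos in range(n1 + n2):
        g = np.zeros_like(f)
        for used in range(min(pos, n1), -1, -1):
            row = f[used]
            nz = np.nonzero(row)[0]
            if nz.size == 0:
                continue
            if used < n1:
                g[used + 1, nz + (pos - used)] += row[nz]
            if pos - used < n2:
                g[used, nz] += row[nz]
        f = g
    return f[n1]


def mann_whitney_exact(group_a, group_b, two_sided: bool = True) -> TestResult:
    """Mann–Whitney U test, exact by enumeration for small tie-free samples.

    The exact two-sided p is the proportion of the C(n1+n2, n1) label
    arrangements with |U - n1*n2/2| at least as large as observed; used when
    n1 + n2 <= 20 and the pooled data are tie-free.  Otherwise a midrank
    normal approximation with tie-corrected variance is used.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    mean_u = n1 * n2 / 2.0

    if n1 + n2 <= 20 and not has_ties:
        counts = _exact_u_pmf(n1, n2)
        total = comb(n1 + n2, n1)
        dev = abs(u - mean_u)
        us = np.arange(counts.size)
        if two_sided:
            p = counts[np.abs(us - mean_u) >= dev - 1e-9].sum() / total
        else:
            p = counts[us >= u - 1e-9].sum() / total
        return TestResult(
            float(u), float(min(p, 1.0)), "mann-whitney-exact", sample_sizes=(n1, n2)
        )

    ties = np.unique(pooled, return_counts=True)[1]
    n = n1 + n2
    tie_term = (ties**3 - ties).sum() / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return TestResult(float(u), 1.0, "mann-whitney-normal", sample_sizes=(n1, n2))
    z = (u - mean_u) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z)) if two_sided else stats.norm.sf(z)
    return TestResult(
        float(u),
        float(min(p, 1.0)),
        "mann-whitney-normal",
        sample_sizes=(n1, n2),
        extra={"z": float(z)},
    )


def sample_quantile(values, q) -> float:
    """Sample quantile with plotting position p(k) = (k-1)/(n-1) (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.isscalar(q) or np.ndim(q) == 0:
        if not (0.0 <= float(q) <= 1.0):
            raise ValueError("q must lie in [0, 1]")
        return float(np.quantile(v, float(q), method="linear"))
    qs = np.asarray(q, dtype=float)
    if np.any((qs < 0) | (qs > 1)):
        raise ValueError("q must lie in [0, 1]")
    return np.quantile(v, qs, method="linear")
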