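"""2×2 contingency comparisons for succeed/not-succeed counts.

Used to compare success proportions between studies or groups: a Pearson
chi-square (no continuity correction) alongside a Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, fisher_exact as _scipy_fisher, hypergeom

from .selection import TestResult


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = succeed / not."""

    counts: np.ndarray

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("need a 2x2 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def pearson_chi_square_2x2(table) -> TestResult:
    """Pearson chi-square for a 2×2 table, df = 1, *without* Yates
    continuity correction: n·(ad − bc)² / (r1·r2·c1·c2)."""
    t = ContingencyTable2x2(table).counts
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a margin is zero")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(g2=float(stat), df=1, p_value=float(chi2.sf(stat, 1)))


def fisher_exact_2x2(table, convention: str = "min-likelihood") -> float:
    """Two-sided Fisher exact p-value for a 2×2 table.

    ``min-likelihood`` (default): sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than the
    observed table — the convention of most statistical software.
    ``doubling``: twice the smaller one-sided tail, capped at 1.
    Degenerate margins give p = 1.
    """
    t = ContingencyTable2x2(table).counts
    (a, b), (c, d) = t
    n = t.sum()
    r1, c1 = a + b, a + c
    if n == 0 or min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    if convention == "min-likelihood":
        return float(_scipy_fisher(t, alternative="two-sided")[1])
    if convention == "doubling":
        dist = hypergeom(n, r1, c1)
        lower = float(dist.cdf(a))
        upper = float(dist.sf(a - 1))
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown convention {convention!r}")
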