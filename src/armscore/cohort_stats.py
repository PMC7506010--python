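"""Group-comparison statistics for cohort characteristics tables.

The standard presentation of a two-diagnosis rehabilitation cohort
(e.g. stroke vs. TBI) compares categorical characteristics with Pearson
chi-square tests (no continuity correction) and continuous ones with
pooled-variance independent t tests computed from group summaries, with
Holm step-down adjustment for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "chi_square",
    "independent_t",
    "holm_adjust",
]


@dataclass
class ContingencyTable:
    """Counts of a categorical variable by group (rows = groups)."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be nonnegative integers")


@dataclass
class GroupSummary:
    """n / mean / SD of a continuous variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int]:
    """Pearson chi-square statistic and df, without continuity correction."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sstats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof)


def independent_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled-variance Student t from group summaries.

    Sign convention: ``(mean_a − mean_b)``, df = n_a + n_b − 2.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    return float(t), int(df)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
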