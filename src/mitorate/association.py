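"""Association tests for heteroplasmy carriage, implemented from first
principles.

Carriage of point heteroplasmy can be cross-tabulated against sample
covariates (sex, haplogroup) as an r x 2 contingency table.  Two tests are
provided:

* Pearson's chi-square test of independence (no continuity correction by
  default);
* Fisher's exact test by full enumeration of tables with the observed
  margins, two-sided by the point-probability rule (sum the probabilities of
  all tables no more probable than the one observed).

Both are written out explicitly rather than delegated to a stats library so
the counting conventions are transparent; library implementations serve as
cross-checks in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["ContingencyTable", "chi_square_test", "fisher_exact"]

#: Guard on the enumeration size for the exact test.
_MAX_TABLES = 2_000_000
#: Relative tolerance when comparing table probabilities (standard practice
#: so ties are not broken by floating-point noise).
_P_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """An r x 2 table of non-negative integer counts.

    Rows are covariate categories (e.g. female/male or haplogroups), the two
    columns are heteroplasmic yes/no.
    """

    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("contingency table must be r x 2")
        if arr.shape[0] < 2:
            raise ValueError("need at least two rows to test association")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")

    @classmethod
    def from_array(cls, counts) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=int)
        return cls(tuple(tuple(int(v) for v in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def _as_array(t) -> np.ndarray:
    if isinstance(t, ContingencyTable):
        return t.array
    return ContingencyTable.from_array(t).array


def chi_square_test(
    t, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x 2 table.

    Returns ``(statistic, df, p)``.  Expected counts come from the row and
    column margins; ``df = (r - 1)(c - 1)``.  Yates continuity correction is
    available for 2 x 2 tables but off by default.
    """
    obs = _as_array(t)
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    n = obs.sum()
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError("zero row or column margin: test undefined")
    expected = np.outer(row_tot, col_tot) / n
    diff = np.abs(obs - expected)
    if continuity_correction and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def _log_table_prob(table: np.ndarray, row_tot: np.ndarray, n: int, k: int) -> float:
    """Log probability of an r x 2 table under fixed margins.

    With column-1 total ``k``, the first column is a multivariate
    hypergeometric draw: P = prod_i C(R_i, a_i) / C(N, k).
    """
    a = table[:, 0]
    log_c = gammaln(row_tot + 1) - gammaln(a + 1) - gammaln(row_tot - a + 1)
    log_denom = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(log_c.sum() - log_denom)


def fisher_exact(t) -> float:
    """Two-sided Fisher exact test on an r x 2 table.

    Enumerates every table with the observed margins; the p-value is the sum
    of the (multivariate-hypergeometric) probabilities of tables no more
    probable than the observed one.  Raises when the enumeration would be
    infeasibly large (use the chi-square test instead).
    """
    obs = _as_array(t)
    row_tot = obs.sum(axis=1)
    n = int(obs.sum())
    k = int(obs[:, 0].sum())
    if k == 0 or k == n:
        return 1.0  # single admissible table

    n_tables = np.prod([min(r, k) + 1 for r in row_tot], dtype=float)
    if n_tables > _MAX_TABLES:
        raise ValueError(
            f"~{n_tables:.0f} candidate tables: enumeration infeasible, "
            "use chi_square_test"
        )

    log_p_obs = _log_table_prob(obs, row_tot, n, k)
    threshold = log_p_obs + np.log1p(_P_REL_TOL)

    total = 0.0
    r = len(row_tot)
    ranges = [range(min(int(ri), k) + 1) for ri in row_tot[:-1]]
    for alloc in product(*ranges):
        last = k - sum(alloc)
        if not 0 <= last <= row_tot[-1]:
            continue
        a = np.array(alloc + (last,))
        table = np.column_stack([a, row_tot - a])
        log_p = _log_table_prob(table, row_tot, n, k)
        if log_p <= threshold:
            total += np.exp(log_p)
    return float(min(total, 1.0))
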