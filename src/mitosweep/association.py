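"""Association tests between infection status and categorical phenotypes.

The exact test enumerates every non-negative integer r x c table with the
observed margins; under the null of independence each table has
multivariate hypergeometric probability

    P(T) = (prod_i R_i!)(prod_j C_j!) / (N! prod_ij T_ij!)

and the two-sided p-value sums the probabilities of all tables no more
probable than the observed one.  The chi-square test is the usual Pearson
statistic; ``select_test`` applies the textbook rule of switching to the
exact test whenever any expected count falls below five.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "chi_square",
    "select_test",
    "compare_proportions",
    "enumerate_tables",
]

#: Relative tolerance when comparing point probabilities to the observed
#: table's probability (absorbs floating-point ties).
TIE_RTOL = 1e-7

#: Guard on the enumeration size (number of candidate tables).
MAX_TABLES = 10_000_000


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError(f"table must be at least 2x2, got {r}x{c}")
        if (self.counts < 0).any():
            raise ValueError("negative cell counts")
        if self.counts.sum() == 0:
            raise ValueError("empty table")
        if self.row_labels is None:
            self.row_labels = [f"r{i + 1}" for i in range(r)]
        if self.col_labels is None:
            self.col_labels = [f"c{j + 1}" for j in range(c)]

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_margins, self.col_margins) / self.total


def _as_table(table: ContingencyTable | Sequence[Sequence[int]]) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def enumerate_tables(
    row_margins: Sequence[int], col_margins: Sequence[int]
) -> Iterator[np.ndarray]:
    """Yield every non-negative integer table with the given margins.

    Rows are filled depth-first; the final row and the final cell of each
    row are forced by the margins, so only genuinely free cells branch.
    """
    rows = [int(x) for x in row_margins]
    cols = np.asarray(col_margins, dtype=np.int64)
    r = len(rows)
    table = np.zeros((r, len(cols)), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray) -> Iterator[np.ndarray]:
        if i == r - 1:
            # last row forced by the column margins
            if (remaining_cols >= 0).all() and remaining_cols.sum() == rows[i]:
                table[i] = remaining_cols
                yield table.copy()
            return
        yield from fill_cell(i, 0, rows[i], remaining_cols)

    def fill_cell(i: int, j: int, left_in_row: int, remaining_cols: np.ndarray) -> Iterator[np.ndarray]:
        if j == len(cols) - 1:
            if left_in_row <= remaining_cols[j]:
                table[i, j] = left_in_row
                rc = remaining_cols.copy()
                rc[j] -= left_in_row
                yield from fill_row(i + 1, rc)
            return
        hi = min(left_in_row, int(remaining_cols[j]))
        for v in range(hi + 1):
            table[i, j] = v
            rc = remaining_cols.copy()
            rc[j] -= v
            yield from fill_cell(i, j + 1, left_in_row - v, rc)

    yield from fill_row(0, cols.copy())


def _enumeration_size(row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    """Upper bound on the number of candidate tables (product of cell ranges)."""
    size = 1.0
    for ri in row_margins[:-1]:
        for cj in col_margins[:-1]:
            size *= min(int(ri), int(cj)) + 1
            if size > MAX_TABLES:
                return size
    return size


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for an r x c table, by enumeration.

    Sums the null probabilities of all margin-compatible tables whose
    point probability does not exceed the observed one (with relative
    tie tolerance ``TIE_RTOL``).  Log-factorials keep the arithmetic
    stable at totals of a few hundred.
    """
    t = _as_table(table)
    rm, cm = t.row_margins, t.col_margins
    if (rm == 0).any() or (cm == 0).any():
        raise ValueError("fisher_exact: zero row or column margin")
    if _enumeration_size(rm, cm) > MAX_TABLES:
        raise ValueError(
            "fisher_exact: enumeration guard exceeded "
            f"({MAX_TABLES} candidate tables); use chi_square instead"
        )
    log_margins = sum(math.lgamma(x + 1) for x in rm) + sum(
        math.lgamma(x + 1) for x in cm
    )
    log_n = math.lgamma(t.total + 1)

    def log_prob(counts: np.ndarray) -> float:
        lg = 0.0
        for v in counts.flat:
            lg += math.lgamma(v + 1)
        return log_margins - log_n - lg

    lp_obs = log_prob(t.counts)
    cutoff = lp_obs + math.log1p(TIE_RTOL)
    p = 0.0
    for cand in enumerate_tables(rm, cm):
        lp = log_prob(cand)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def chi_square(table: ContingencyTable | Sequence[Sequence[int]]) -> dict[str, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``{"X2": ..., "df": ..., "p": ...}``.
    """
    t = _as_table(table)
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise ValueError("chi_square: zero row or column margin")
    expected = t.expected()
    x2 = float(((t.counts - expected) ** 2 / expected).sum())
    r, c = t.counts.shape
    df = (r - 1) * (c - 1)
    return {"X2": x2, "df": df, "p": float(stats.chi2.sf(x2, df))}


def select_test(table: ContingencyTable | Sequence[Sequence[int]]) -> dict[str, object]:
    """Choose and run the appropriate test for a table.

    Any expected count below five triggers the exact test; otherwise the
    chi-square test is used.  Returns the chosen test's name alongside
    its result.
    """
    t = _as_table(table)
    if (t.expected() < 5).any():
        return {"test": "fisher", "p": fisher_exact(t)}
    result = chi_square(t)
    return {"test": "chi_square", "p": result["p"], "X2": result["X2"], "df": result["df"]}


def compare_proportions(
    x1: int, n1: int, x2: int, n2: int, method: str = "fisher"
) -> float:
    """Two-sided comparison of two binomial proportions x1/n1 vs x2/n2.

    Default is the Fisher exact test on the implied 2x2 table; a
    normal-approximation two-proportion z-test is available with
    ``method="z"``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    if method == "fisher":
        return fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
    if method == "z":
        p_pool = (x1 + x2) / (n1 + n2)
        if p_pool in (0.0, 1.0):
            return 1.0
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        z = (x1 / n1 - x2 / n2) / se
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")
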