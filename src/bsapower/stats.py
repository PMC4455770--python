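"""G-tests (likelihood-ratio tests) on allele count tables.

Two flavours are used in bulk segregant mapping:

- a 2x2 test of independence comparing mutant/reference read counts
  between the low- and high-phenotype bulks (one test per variable site);
- a goodness-of-fit test of a single pool's allele counts against a null
  frequency (0.5 for a pool of segregants expected to show Mendelian
  segregation).

Both report G = 2 * sum O * ln(O/E), chi-square distributed with 1 df
under the null; empty cells contribute 0 (the 0*ln(0) convention).  No
Williams or continuity correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["CountTable2x2", "GTestResult", "g_test_2x2", "g_test_vs_null"]


@dataclass(frozen=True)
class CountTable2x2:
    """Mutant/reference read counts in the low and high bulks at one site."""

    mut_low: int
    ref_low: int
    mut_high: int
    ref_high: int

    def __post_init__(self) -> None:
        for name in ("mut_low", "ref_low", "mut_high", "ref_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def depth_low(self) -> int:
        return self.mut_low + self.ref_low

    @property
    def depth_high(self) -> int:
        return self.mut_high + self.ref_high


@dataclass(frozen=True)
class GTestResult:
    """Likelihood-ratio statistic, degrees of freedom and p-value."""

    G: float
    df: int
    p_value: float


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def g_test_tables(
    mut_low, ref_low, mut_high, ref_high
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2x2 G statistic and chi-square(1) p-value.

    Accepts arrays of the four cell counts (broadcast together).  Tables
    with a zero margin (a bulk with no reads, or no mutant / no reference
    reads overall) get G = 0, p = 1: such tables carry no evidence of a
    frequency difference and callers treat them as non-significant.
    """
    a = np.asarray(mut_low, dtype=float)
    b = np.asarray(ref_low, dtype=float)
    c = np.asarray(mut_high, dtype=float)
    d = np.asarray(ref_high, dtype=float)
    n = a + b + c + d
    row_low = a + b
    row_high = c + d
    col_mut = a + c
    col_ref = b + d
    ok = (row_low > 0) & (row_high > 0) & (col_mut > 0) & (col_ref > 0)
    n_safe = np.where(n > 0, n, 1.0)

    def term(obs, e_row, e_col):
        exp = e_row * e_col / n_safe
        with np.errstate(divide="ignore", invalid="ignore"):
            t = obs * np.log(np.where(obs > 0, obs, 1.0) / np.where(exp > 0, exp, 1.0))
        return np.where(obs > 0, t, 0.0)

    g = 2.0 * (
        term(a, row_low, col_mut)
        + term(b, row_low, col_ref)
        + term(c, row_high, col_mut)
        + term(d, row_high, col_ref)
    )
    g = np.where(ok, np.maximum(g, 0.0), 0.0)
    p = np.where(ok, chi2.sf(g, df=1), 1.0)
    return g, p


def g_test_2x2(table: CountTable2x2) -> GTestResult:
    """Two-sided G-test of independence on a 2x2 bulk-comparison table.

    Expected counts come from the product of margins over the grand
    total; the chi-square(1) upper tail gives a direction-free p-value.

    Raises
    ------
    ValueError
        If a row or column margin is zero (the test is undefined; such
        sites must be filtered out or counted as non-significant by the
        caller).
    """
    a, b, c, d = table.mut_low, table.ref_low, table.mut_high, table.ref_high
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError(
            "G-test undefined for a table with a zero margin: "
            f"({a}, {b}, {c}, {d})"
        )
    obs = np.array([a, b, c, d], dtype=float)
    exp = np.array(
        [
            (a + b) * (a + c) / n,
            (a + b) * (b + d) / n,
            (c + d) * (a + c) / n,
            (c + d) * (b + d) / n,
        ]
    )
    g = max(_g_statistic(obs, exp), 0.0)
    return GTestResult(G=g, df=1, p_value=float(chi2.sf(g, df=1)))


def g_test_vs_null(mut_count: int, total: int, p_null: float = 0.5) -> GTestResult:
    """Goodness-of-fit G-test of a pool's mutant count against a null frequency.

    Compares the observed (mutant, reference) counts with expectations
    (total * p_null, total * (1 - p_null)); 1 degree of freedom.
    """
    if not 0.0 < p_null < 1.0:
        raise ValueError(f"p_null must be in (0, 1), got {p_null}")
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= mut_count <= total:
        raise ValueError("mut_count must be in [0, total]")
    obs = np.array([mut_count, total - mut_count], dtype=float)
    exp = np.array([total * p_null, total * (1.0 - p_null)])
    g = max(_g_statistic(obs, exp), 0.0)
    return GTestResult(G=g, df=1, p_value=float(chi2.sf(g, df=1)))
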