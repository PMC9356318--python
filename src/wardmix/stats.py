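"""Significance testing for distributional comparisons.

Contingency tables are tested with a chi-squared test of independence
(no continuity correction), falling back to an exact test when any
expected cell count is below 5 (Cochran's rule): Fisher's exact test for
2x2 tables, and a seeded conditional Monte Carlo permutation test (fixed
row margins, chi-squared statistic) for larger tables.  All tests are
two-sided, at a default significance threshold of alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateMarginError(ValueError):
    """A row or column margin of the contingency table is zero."""


@dataclass(frozen=True)
class ContingencyTestResult:
    method: str  # "chi2" | "fisher_exact" | "permutation_mc"
    statistic: float | None  # chi2 statistic; None for Fisher
    p_value: float
    significant: bool
    min_expected: float


def _as_array(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy()
    else:
        arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be nonnegative")
    if arr.sum() <= 0:
        raise ValueError("contingency table total must be positive")
    return arr.astype(np.int64)


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence: outer(rows, cols) / total."""
    arr = _as_array(table)
    r = arr.sum(axis=1)
    c = arr.sum(axis=0)
    return np.outer(r, c) / arr.sum()


def contingency_test(
    table,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    mc_seed: int = 0,
) -> ContingencyTestResult:
    """Test independence of rows and columns in a contingency table.

    Chi-squared without continuity correction when every expected cell is
    at least 5; otherwise Fisher's exact test (2x2) or a conditional Monte
    Carlo permutation test with ``n_mc`` resamples (larger tables; the
    resampling stream is seeded so results are reproducible).
    """
    arr = _as_array(table)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateMarginError("a row or column margin is zero")

    exp = expected_counts(arr)
    min_exp = float(exp.min())

    if min_exp >= 5:
        chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
        method, stat = "chi2", float(chi2)
    elif arr.shape == (2, 2):
        _, p = sps.fisher_exact(arr, alternative="two-sided")
        method, stat = "fisher_exact", None
    else:
        stat, p = _permutation_chi2(arr, n_mc=n_mc, seed=mc_seed)
        method = "permutation_mc"

    p = float(min(p, 1.0))
    return ContingencyTestResult(
        method=method,
        statistic=stat,
        p_value=p,
        significant=p < alpha,
        min_expected=min_exp,
    )


def _chi2_stat(arr: np.ndarray) -> float:
    exp = expected_counts(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (arr - exp) ** 2 / exp, 0.0)
    return float(terms.sum())


def _permutation_chi2(arr: np.ndarray, n_mc: int, seed: int) -> tuple[float, float]:
    """Conditional Monte Carlo p-value: shuffle column labels of the
    individual observations, keeping both margins' data-generating row
    structure, and compare the chi-squared statistic."""
    observed = _chi2_stat(arr)
    rng = np.random.default_rng(seed)
    row_sizes = arr.sum(axis=1)
    col_labels = np.repeat(np.arange(arr.shape[1]), arr.sum(axis=0))
    hits = 0
    k = arr.shape[1]
    row_edges = np.cumsum(row_sizes)[:-1]
    for _ in range(n_mc):
        rng.shuffle(col_labels)
        perm = np.zeros_like(arr)
        for i, chunk in enumerate(np.split(col_labels, row_edges)):
            perm[i] = np.bincount(chunk, minlength=k)
        if _chi2_stat(perm) >= observed - 1e-12:
            hits += 1
    # add-one estimator keeps the p-value valid
    return observed, (hits + 1) / (n_mc + 1)


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p for a 2x2 table by exhaustive enumeration.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed the observed table's.  Kept
    as an independent cross-check of the exact test.
    """
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError("enumeration oracle is for 2x2 tables")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: sps.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))
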