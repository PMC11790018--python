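"""Shared statistical primitives.

Small wrappers used across modules: exact 2x2 testing (probability-mass
two-sided convention), Benjamini-Hochberg adjustment, Pearson correlation
that is defined (r = 0, p = 1) for constant inputs, and the half-up integer
percentage used for display.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FisherResult:
    """Two-sided exact test on a 2x2 table.

    ``odds_ratio`` is the sample odds ratio (a*d)/(b*c); it is ``inf`` when
    only the denominator vanishes and undefined (NaN, ``odds_ratio_defined``
    False) when numerator and denominator are both zero.
    """

    p_value: float
    odds_ratio: float
    odds_ratio_defined: bool


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test with the probability-mass convention.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of tables whose point probability does not exceed that
    of the observed table.

    Parameters
    ----------
    table : array-like of shape (2, 2)
        Nonnegative integer counts with a positive grand total.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.number) or np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    if np.any(t != np.floor(t)):
        raise ValueError("table entries must be integers")
    t = t.astype(np.int64)
    if t.sum() <= 0:
        raise ValueError("table grand total must be positive")
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    num, den = a * d, b * c
    if num == 0 and den == 0:
        return FisherResult(p, float("nan"), False)
    if den == 0:
        return FisherResult(p, float("inf"), True)
    return FisherResult(p, num / den, True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_with_p(x, y) -> tuple[float, float, bool]:
    """Pearson r with a two-sided t-distribution p-value.

    Returns ``(r, p, defined)``; a zero-variance input yields ``(0.0, 1.0,
    False)`` rather than NaN so that ranking code downstream stays total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0, False
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), True


def percent_display(k: int, n: int) -> int:
    """Integer percentage of ``k / n`` rounded half-up (93.5% -> 94)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(k) * 100 / Decimal(n)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
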