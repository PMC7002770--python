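"""Spearman rank correlation with AS 89 tail probabilities.

The correlation itself uses average ranks (tie-aware). Two-sided p-values
come from the exact permutation distribution of the sum-of-squared rank
differences S for n <= 9, and from the AS 89 Edgeworth series otherwise.
S is recovered from rho via S = (1 - rho) * (n^3 - n) / 6, which is exact
in the absence of ties and the usual surrogate when ties are present.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, CohortSizeError

__all__ = ["SpearmanResult", "spearman_as89"]

EXACT_N_MAX = 9

# Edgeworth series coefficients of algorithm AS 89 (Best & Roberts 1975).
_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
      0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.04567)


class SpearmanResult(NamedTuple):
    rho: float
    pvalue: float
    n: int
    statistic: float  # S, the sum of squared rank differences


@lru_cache(maxsize=8)
def _exact_s_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of S over all n! equally likely rank permutations."""
    base = np.arange(1, n + 1)
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(1, n + 1)):
        s = int(np.sum((base - np.asarray(perm)) ** 2))
        counts[s] = counts.get(s, 0) + 1
    values = np.array(sorted(counts))
    freq = np.array([counts[v] for v in values], dtype=float)
    return values, freq / freq.sum()


def _exact_tails(n: int, s: float) -> tuple[float, float]:
    values, probs = _exact_s_distribution(n)
    lower = float(probs[values <= s + 1e-9].sum())
    upper = float(probs[values >= s - 1e-9].sum())
    return lower, upper


def _edgeworth_upper(n: int, s: float) -> float:
    """AS 89 Edgeworth-series approximation of Pr(S >= s)."""
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * math.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (_C[0] + b * (_C[1] + _C[2] * b)
                 + y * (-_C[3] + b * (_C[4] + _C[5] * b)
                        - y * b * (_C[6] + _C[7] * b
                                   - y * (_C[8] - _C[9] * b
                                          + y * b * (_C[10] - _C[11] * y)))))
    p = u / math.exp(y / 2.0) + stats.norm.sf(x)
    return min(1.0, max(0.0, p))


def _tail_probabilities(n: int, s: float) -> tuple[float, float]:
    if n <= EXACT_N_MAX:
        return _exact_tails(n, s)
    mean_s = n * (n * n - 1.0) / 6.0  # S is symmetric about its mean
    upper = _edgeworth_upper(n, s)
    lower = _edgeworth_upper(n, 2.0 * mean_s - s)
    return lower, upper


def spearman_as89(x, y) -> SpearmanResult:
    """Spearman rho with a two-sided AS 89 p-value.

    Raises
    ------
    CohortSizeError
        Fewer than 4 paired observations.
    DegenerateDataError
        Either vector is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise CohortSizeError(f"need >= 4 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    s = (1.0 - rho) * (n ** 3 - n) / 6.0
    lower, upper = _tail_probabilities(n, s)
    p = min(1.0, 2.0 * min(lower, upper))
    return SpearmanResult(rho=rho, pvalue=p, n=n, statistic=s)
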