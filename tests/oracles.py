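"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def chi2_sf_even_df(x: float, df: int) -> float:
    """Upper-tail chi-square probability for even df via the closed-form
    Poisson series: ``exp(-x/2) * sum_{j<df/2} (x/2)^j / j!``."""
    assert df % 2 == 0 and df > 0
    half = x / 2.0
    term = 1.0
    total = 1.0
    for j in range(1, df // 2):
        term *= half / j
        total += term
    return math.exp(-half) * total


def samples_with_moments(n: int, mean: float, sd: float) -> np.ndarray:
    """A deterministic sample of size n with exactly the given mean and
    (ddof=1) standard deviation."""
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def power_two_sided_z(delta: float, alpha: float) -> float:
    """Power of the two-sided level-alpha z-test at noncentrality delta,
    evaluated with erf only."""
    z_crit = _norm_isf(alpha / 2.0)
    return _norm_sf(z_crit - delta) + _norm_cdf(-z_crit - delta)


def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def _norm_isf(q: float) -> float:
    # bisection; only used at test time so speed is irrelevant
    lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _norm_sf(mid) > q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
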