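"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and libraries) they check:
Fisher's exact test by direct hypergeometric enumeration with integer
combinatorics, chi-square p-values by Monte-Carlo simulation under the
null, and exact partition arithmetic with :class:`fractions.Fraction`.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by summing hypergeometric point masses.

    All tables with the observed margins whose probability does not exceed
    the observed table's probability contribute to p.  Exact rational
    arithmetic; no distribution object involved.
    """
    r1, r2, k = a + b, c + d, a + c
    n_total = r1 + r2
    denom = comb(n_total, k)
    lo, hi = max(0, k - r2), min(k, r1)
    masses = {x: Fraction(comb(r1, x) * comb(r2, k - x), denom) for x in range(lo, hi + 1)}
    observed = masses[a]
    return float(sum(m for m in masses.values() if m <= observed))


def _chi2_stat_2x2(a, b, c, d):
    """Vectorized Pearson statistic for 2x2 tables (no continuity correction)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    return stat


def chi2_null_pvalue_mc(
    observed: tuple[int, int], control: tuple[int, int], n_sim: int, seed: int
) -> float:
    """Monte-Carlo p for the 2x2 Pearson test under equal row distributions.

    Both rows are redrawn binomially at the pooled column proportion and the
    fraction of simulated statistics at least as large as the observed one
    is returned.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = sum(observed), sum(control)
    pooled = (observed[0] + control[0]) / (n1 + n2)
    stat_obs = float(_chi2_stat_2x2(observed[0], observed[1], control[0], control[1]))
    a = rng.binomial(n1, pooled, size=n_sim)
    c = rng.binomial(n2, pooled, size=n_sim)
    stats = _chi2_stat_2x2(a, n1 - a, c, n2 - c)
    return float(np.mean(stats >= stat_obs - 1e-12))


def partition_half_up_fraction(total: int, fractions: tuple) -> list[int]:
    """Half-up integer partition via exact rational arithmetic.

    Independent route for the compartment rounding used by the risk
    reconstruction: each quota ``total * f`` is rounded half away from zero
    with Fraction comparisons, then the largest compartment absorbs the
    discrepancy.
    """
    parts = []
    for f in fractions:
        quota = Fraction(f).limit_denominator(10**12) * total
        floor = quota.numerator // quota.denominator
        parts.append(int(floor + (1 if (quota - floor) >= Fraction(1, 2) else 0)))
    parts[parts.index(max(parts))] += total - sum(parts)
    return parts
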