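"""Heterozygote-excess testing in genetically-unexplained patient cohorts.

Patients who satisfy clinical criteria for FMF but do not carry two mutated
*MEFV* alleles ("genetically unexplained") may simply have a clinically
similar disease unrelated to the locus.  Under that hypothesis the ratio of
heterozygous carriers to non-carriers (R) among them should match the
origin-matched general population.  This module reproduces that comparison:
the observed R from a patient genotype tally, the expected heterozygote and
non-carrier counts in a same-size sample of the general population, and a
2x2 test of observed vs expected.

Expected-count construction (the published convention):

1. ``R`` is the Hardy-Weinberg carrier ratio ``2pq/p**2`` rounded half-up to
   two decimals,
2. ``expected_het = round_half_up(n * R / (1 + R), 2)``,
3. ``expected_none = n - expected_het`` (exact by subtraction).

This is the unique order of operations that reproduces the published
expected pairs (5.74/38.26 at q=0.07, n=44; 11/55 at q=0.09, n=66;
10.07/125.93 at q=0.04, n=136; 3.86/35.14 at q=0.05, n=39) simultaneously.
An "unrounded" variant (R kept at full precision, no count rounding) is
computed alongside, because for borderline tables the two variants fall on
opposite sides of a printed p-value bound.

The comparison group is the carrier/non-carrier universe: individuals with
two mutated alleles are excluded from the population side, mirroring the R
construction.  An ``exact_universe`` option retains them for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .hwe import AlleleFrequency, UndefinedRatioError, _as_q, carrier_ratio, round_half_up
from .prevalence import ConfigError, PopulationParams

__all__ = [
    "CarrierExcessResult",
    "DegenerateTableError",
    "GenotypeTally",
    "expected_counts",
    "fisher_exact_2x2",
    "observed_ratio",
    "pearson_chi2_2x2",
    "run_carrier_excess",
]


class DegenerateTableError(ValueError):
    """The 2x2 table has an all-zero column; no test is defined."""


@dataclass(frozen=True)
class GenotypeTally:
    """Counts of individuals carrying two / one / zero mutated alleles."""

    n_two_mut: int
    n_het: int
    n_none: int
    group_label: str = ""

    def __post_init__(self) -> None:
        for field in ("n_two_mut", "n_het", "n_none"):
            value = getattr(self, field)
            if not isinstance(value, (int,)) or isinstance(value, bool) or value < 0:
                raise ValueError(f"{field} must be a non-negative integer, got {value!r}")

    @property
    def total(self) -> int:
        return self.n_two_mut + self.n_het + self.n_none


@dataclass(frozen=True)
class CarrierExcessResult:
    """Observed vs expected heterozygote:non-carrier comparison for one population."""

    group_label: str
    n: int
    n_het_observed: int
    n_none_observed: int
    r_observed: float
    r_expected: float  # carrier ratio rounded per policy (2 decimals)
    r_expected_unrounded: float
    expected_het: float
    expected_none: float
    statistic: float
    p_value: float
    method: str
    # same test run with full-precision expected counts (no R rounding)
    expected_het_unrounded: float
    expected_none_unrounded: float
    statistic_unrounded: float
    p_value_unrounded: float


def observed_ratio(tally: GenotypeTally) -> float:
    """Observed heterozygotes per non-carrier, ``n_het / n_none``, unrounded."""
    if tally.n_none == 0:
        raise UndefinedRatioError(f"{tally.group_label or 'tally'}: no non-carriers observed")
    return tally.n_het / tally.n_none


def expected_counts(
    n: float,
    q: "float | AlleleFrequency",
    r_digits: int | None = 2,
    exact_universe: bool = False,
) -> tuple[float, float]:
    """Expected (heterozygote, non-carrier) counts in a size-``n`` population sample.

    With the default ``r_digits=2`` the published rounding convention is
    applied (see module docstring); ``r_digits=None`` keeps everything at
    full precision.  ``exact_universe=True`` draws the sample from the full
    population including two-mutation carriers, so the pair sums to
    ``n * (1 - q**2)`` rather than ``n``.
    """
    if n <= 0:
        raise ValueError(f"group size must be positive, got {n!r}")
    qv = _as_q(q)
    if exact_universe:
        p = 1.0 - qv
        e_het, e_none = n * 2.0 * p * qv, n * p * p
        if r_digits is not None:
            e_het, e_none = round_half_up(e_het, 2), round_half_up(e_none, 2)
        return e_het, e_none
    ratio = carrier_ratio(qv)
    if r_digits is not None:
        ratio = round_half_up(ratio, r_digits)
        e_het = round_half_up(n * ratio / (1.0 + ratio), 2)
    else:
        e_het = n * ratio / (1.0 + ratio)
    return e_het, n - e_het


def _check_table(row_obs: tuple[float, float], row_exp: tuple[float, float]) -> None:
    values = [*row_obs, *row_exp]
    if any(v < 0 for v in values):
        raise ValueError("2x2 table entries must be non-negative")
    if sum(row_obs) == 0 or sum(row_exp) == 0:
        raise DegenerateTableError("a row of the 2x2 table is all zero")
    if row_obs[0] + row_exp[0] == 0 or row_obs[1] + row_exp[1] == 0:
        raise DegenerateTableError("a column of the 2x2 table is all zero")


def pearson_chi2_2x2(
    observed: tuple[float, float], expected_group: tuple[float, float]
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [observed; expected_group].

    The expected pair plays the role of an equal-size pseudo-control sample;
    no continuity correction; p is the upper tail of chi-square with 1 df.
    """
    _check_table(observed, expected_group)
    statistic, p_value, _, _ = stats.chi2_contingency(
        [list(observed), list(expected_group)], correction=False
    )
    return float(statistic), float(p_value)


def fisher_exact_2x2(
    observed: tuple[float, float], expected_group: tuple[float, float]
) -> float:
    """Two-sided Fisher exact p for [observed; expected_group].

    The expected pair is rounded half-up to the nearest integers first (the
    exact test is defined on counts).
    """
    _check_table(observed, expected_group)
    table = [
        [int(round_half_up(observed[0])), int(round_half_up(observed[1]))],
        [int(round_half_up(expected_group[0])), int(round_half_up(expected_group[1]))],
    ]
    _check_table(tuple(table[0]), tuple(table[1]))
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return float(p_value)


def run_carrier_excess(
    tallies: list[GenotypeTally],
    params: list[PopulationParams],
    method: str = "pearson_chi2",
    exact_universe: bool = False,
) -> list[CarrierExcessResult]:
    """Carrier-excess test for each patient tally against its matched population.

    Tallies must contain genetically-unexplained patients only
    (``n_two_mut == 0``) and each ``group_label`` must match a population
    name in ``params``.  Returns one result per tally, in input order.
    """
    if method not in ("pearson_chi2", "fisher_exact"):
        raise ConfigError(f"unknown method {method!r}")
    by_name = {p.name: p for p in params}
    results: list[CarrierExcessResult] = []
    for tally in tallies:
        if tally.n_two_mut != 0:
            raise ConfigError(
                f"{tally.group_label}: carrier-excess tallies must exclude "
                f"two-mutation patients (n_two_mut={tally.n_two_mut})"
            )
        pop = by_name.get(tally.group_label)
        if pop is None:
            raise ConfigError(f"no population parameters for group {tally.group_label!r}")
        n = tally.total
        observed = (tally.n_het, tally.n_none)
        exp = expected_counts(n, pop.q_strict, r_digits=2, exact_universe=exact_universe)
        exp_u = expected_counts(n, pop.q_strict, r_digits=None, exact_universe=exact_universe)
        if method == "pearson_chi2":
            statistic, p_value = pearson_chi2_2x2(observed, exp)
            statistic_u, p_value_u = pearson_chi2_2x2(observed, exp_u)
        else:
            statistic, statistic_u = float("nan"), float("nan")
            p_value = fisher_exact_2x2(observed, exp)
            p_value_u = fisher_exact_2x2(observed, exp_u)
        results.append(
            CarrierExcessResult(
                group_label=tally.group_label,
                n=n,
                n_het_observed=tally.n_het,
                n_none_observed=tally.n_none,
                r_observed=observed_ratio(tally),
                r_expected=round_half_up(carrier_ratio(pop.q_strict), 2),
                r_expected_unrounded=carrier_ratio(pop.q_strict),
                expected_het=exp[0],
                expected_none=exp[1],
                statistic=statistic,
                p_value=p_value,
                method=method,
                expected_het_unrounded=exp_u[0],
                expected_none_unrounded=exp_u[1],
                statistic_unrounded=statistic_u,
                p_value_unrounded=p_value_u,
            )
        )
    return results
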