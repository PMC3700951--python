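"""Absolute and relative risk of FMF per genotype class.

A closed population of ``population_size`` individuals is reconstructed from
three published quantities: the observed disease prevalence, the genotype
distribution among patients, and the Hardy-Weinberg carrier ratio R of the
matched general population.  Patients are split across genotype classes by
the patient fractions; healthy individuals are split between heterozygotes
and non-carriers by R taken at the precision at which it was published
(one decimal by default — the precision that reproduces the published
healthy compartments, e.g. 9,082 heterozygotes among 99,900 healthy Turks
from R = 0.1).  The genotype-specific risks are then simple compartment
ratios:

    risk_het  = patients_het  / (patients_het  + healthy_het)
    risk_none = patients_none / (patients_none + healthy_none)
    RR        = risk_het / risk_none

These are "rough estimates": point reconstructions without sampling error,
deliberately mirroring the published back-of-envelope calculation.
Uncertainty quantification lives in the simulator (:mod:`mefvrisk.simulate`),
not here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hwe import AlleleFrequency, _as_q, carrier_ratio, round_half_up, round_sig_half_up
from .prevalence import ConfigError

__all__ = [
    "PatientGenotypeFractions",
    "RiskTable",
    "build_risk_table",
    "prevalence_sensitivity",
    "risk_range",
]


@dataclass(frozen=True)
class PatientGenotypeFractions:
    """Fractions of patients carrying two / one / zero mutated alleles."""

    frac_two_mut: float
    frac_het: float
    frac_none: float

    def __post_init__(self) -> None:
        values = (self.frac_two_mut, self.frac_het, self.frac_none)
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ConfigError(f"patient genotype fractions must lie in [0, 1]: {values}")
        if abs(sum(values) - 1.0) > 1e-9:
            raise ConfigError(f"patient genotype fractions must sum to 1: {values}")


@dataclass(frozen=True)
class RiskTable:
    """A closed-population reconstruction partitioned by affected x genotype."""

    name: str
    prevalence: float
    q: float
    r_used: float
    population_size: int
    n_patients: int
    n_healthy: int
    patients_by_genotype: tuple[int, int, int]  # (two_mut, het, none)
    healthy_by_genotype: tuple[int, int]  # (het, none); see exact mode for two_mut
    healthy_two_mut: int | None
    risk_het: float
    risk_none: float
    relative_risk: float
    penetrance_two_mut: float | None

    @property
    def risk_het_display(self) -> float:
        """Risk at two significant figures (e.g. 0.0021 for 2.1e-3)."""
        return round_sig_half_up(self.risk_het, 2)

    @property
    def relative_risk_display(self) -> float:
        return round_half_up(self.relative_risk, 1)


def _round_partition(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Split ``total`` by ``fractions`` into integers (half-up, sum-preserving).

    Any rounding discrepancy is absorbed by the largest compartment so the
    partition always sums to ``total`` exactly.
    """
    parts = [int(round_half_up(total * f)) for f in fractions]
    parts[parts.index(max(parts))] += total - sum(parts)
    if any(p < 0 for p in parts):
        raise ConfigError(f"partition of {total} by {fractions} went negative: {parts}")
    return parts


def build_risk_table(
    prevalence: float,
    population_size: int,
    fractions: PatientGenotypeFractions,
    q: "float | AlleleFrequency",
    name: str = "",
    carrier_ratio_digits: int = 1,
    exact_universe: bool = False,
) -> RiskTable:
    """Reconstruct the affected x genotype compartments and per-genotype risks.

    ``carrier_ratio_digits`` controls the precision at which the population
    carrier ratio is taken before splitting the healthy group (default 1,
    the published precision).  With ``exact_universe=True`` a healthy
    two-mutation compartment is carved out (``q**2 * population_size`` minus
    the two-mutation patients) before the het/none split, and the implied
    penetrance of the two-mutation genotype is reported.
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigError(f"prevalence must lie in (0, 1), got {prevalence!r}")
    qv = _as_q(q)
    n_patients = int(round_half_up(prevalence * population_size))
    if n_patients < 1:
        raise ConfigError(
            f"degenerate population: prevalence {prevalence} x size {population_size} "
            "yields no patients"
        )
    n_healthy = population_size - n_patients
    p_two, p_het, p_none = _round_partition(
        n_patients, (fractions.frac_two_mut, fractions.frac_het, fractions.frac_none)
    )
    ratio = round_half_up(carrier_ratio(qv), carrier_ratio_digits)

    healthy_two: int | None = None
    penetrance_two: float | None = None
    pool = n_healthy
    if exact_universe:
        total_two = int(round_half_up(qv * qv * population_size))
        healthy_two = max(total_two - p_two, 0)
        penetrance_two = p_two / total_two if total_two > 0 else None
        pool = n_healthy - healthy_two
    h_het = int(round_half_up(pool * ratio / (1.0 + ratio)))
    h_none = pool - h_het

    risk_het = p_het / (p_het + h_het) if (p_het + h_het) > 0 else 0.0
    risk_none = p_none / (p_none + h_none) if (p_none + h_none) > 0 else 0.0
    relative_risk = 0.0 if risk_het == 0.0 else risk_het / risk_none
    return RiskTable(
        name=name,
        prevalence=prevalence,
        q=qv,
        r_used=ratio,
        population_size=population_size,
        n_patients=n_patients,
        n_healthy=n_healthy,
        patients_by_genotype=(p_two, p_het, p_none),
        healthy_by_genotype=(h_het, h_none),
        healthy_two_mut=healthy_two,
        risk_het=risk_het,
        risk_none=risk_none,
        relative_risk=relative_risk,
        penetrance_two_mut=penetrance_two,
    )


def risk_range(tables: list[RiskTable]) -> tuple[float, float, float, float]:
    """Element-wise (risk_low, risk_high, rr_low, rr_high) across scenarios."""
    if not tables:
        raise ConfigError("risk_range requires at least one scenario")
    risks = [t.risk_het for t in tables]
    rrs = [t.relative_risk for t in tables]
    return (min(risks), max(risks), min(rrs), max(rrs))


def prevalence_sensitivity(
    prevalences: list[float],
    population_size: int,
    fractions: PatientGenotypeFractions,
    q: "float | AlleleFrequency",
    name: str = "",
    carrier_ratio_digits: int = 1,
    exact_universe: bool = False,
) -> list[RiskTable]:
    """One :class:`RiskTable` per prevalence, everything else held fixed."""
    return [
        build_risk_table(
            prevalence,
            population_size,
            fractions,
            q,
            name=name,
            carrier_ratio_digits=carrier_ratio_digits,
            exact_universe=exact_universe,
        )
        for prevalence in prevalences
    ]
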