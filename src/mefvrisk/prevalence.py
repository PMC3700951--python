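"""Population-prevalence bounds under recessive vs heterozygote-causal models.

If FMF were strictly recessive the population prevalence would be
``P = q**2``.  If heterozygosity were fully causal, every carrier of at
least one mutated allele could be affected, giving the upper bound
``P = 2pq + q**2 = 1 - p**2``.  A detectable contribution of heterozygosity
to disease prevalence would place the observed prevalence strictly between
those two values; observing it at or below ``q**2`` instead argues that
heterozygosity does not drive prevalence at the population level.

The table builder reproduces that comparison for a list of populations, under
two classifications of the frequent-but-debated E148Q variant (polymorphism
vs disease-causing mutation, which toggles the effective ``q``).  Verdicts
compare *unrounded* calculated values against the observed range so that
presentation rounding can never flip a qualitative conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hwe import AlleleFrequency, _as_q, round_half_up

__all__ = [
    "PopulationParams",
    "build_prevalence_table",
    "classify_observed",
    "prevalence_het_causal_bound",
    "prevalence_recessive",
]


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


@dataclass(frozen=True)
class PopulationParams:
    """A named population's allele frequency and observed prevalence range.

    ``q_strict`` counts unambiguous mutations only; ``q_inclusive``
    additionally counts E148Q as a mutation and may be absent.  Observed
    prevalence is a range (point estimates use ``low == high``) and may be
    absent for populations with no published clinical prevalence report.
    """

    name: str
    q_strict: float
    q_inclusive: float | None = None
    prevalence_observed_low: float | None = None
    prevalence_observed_high: float | None = None
    source_note: str = ""

    def __post_init__(self) -> None:
        _as_q(self.q_strict)
        if self.q_inclusive is not None:
            _as_q(self.q_inclusive)
            if self.q_inclusive < self.q_strict:
                raise ConfigError(
                    f"{self.name}: q_inclusive ({self.q_inclusive}) must be >= "
                    f"q_strict ({self.q_strict})"
                )
        lo, hi = self.prevalence_observed_low, self.prevalence_observed_high
        if (lo is None) != (hi is None):
            raise ConfigError(f"{self.name}: observed prevalence range must give both endpoints")
        if lo is not None and not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError(f"{self.name}: invalid observed prevalence range [{lo}, {hi}]")

    @property
    def has_observed(self) -> bool:
        return self.prevalence_observed_low is not None


def prevalence_recessive(q: "float | AlleleFrequency") -> float:
    """Calculated prevalence under strict recessive transmission, ``q**2``."""
    qv = _as_q(q)
    return qv * qv


def prevalence_het_causal_bound(q: "float | AlleleFrequency") -> float:
    """Upper prevalence bound if heterozygosity were causal, ``2pq + q**2``."""
    qv = _as_q(q)
    # q*(2-q) == 1-(1-q)**2 but avoids catastrophic cancellation at tiny q
    return qv * (2.0 - qv)


def classify_observed(low: float, high: float, q: "float | AlleleFrequency") -> str:
    """Place an observed prevalence range relative to ``[q**2, 2pq + q**2]``.

    Uses unrounded model values.  Returns one of ``below_recessive``,
    ``within_band``, ``above_band`` or ``straddles_band``.
    """
    rec = prevalence_recessive(q)
    bound = prevalence_het_causal_bound(q)
    if high < rec:
        return "below_recessive"
    if low > bound:
        return "above_band"
    if rec <= low and high <= bound:
        return "within_band"
    return "straddles_band"


def build_prevalence_table(
    populations: list[PopulationParams],
    recessive_digits: int = 3,
    bound_digits: int = 1,
) -> pd.DataFrame:
    """One row per population: observed prevalence vs calculated models.

    Four calculated cells per row (recessive vs heterozygote-causal bound,
    E148Q as polymorphism vs mutation); the E148Q columns are NA when
    ``q_inclusive`` was not supplied.  Display columns use half-up rounding
    at the given precisions; the ``verdict`` column is computed from the
    unrounded values.
    """
    if not populations:
        raise ConfigError("at least one population is required")
    rows = []
    for pop in populations:
        rec = prevalence_recessive(pop.q_strict)
        bound = prevalence_het_causal_bound(pop.q_strict)
        row: dict[str, object] = {
            "population": pop.name,
            "observed_low": pop.prevalence_observed_low,
            "observed_high": pop.prevalence_observed_high,
            "recessive": rec,
            "recessive_display": round_half_up(rec, recessive_digits),
            "het_causal_bound": bound,
            "het_causal_bound_display": round_half_up(bound, bound_digits),
        }
        if pop.q_inclusive is not None:
            rec_i = prevalence_recessive(pop.q_inclusive)
            bound_i = prevalence_het_causal_bound(pop.q_inclusive)
            row.update(
                recessive_e148q=rec_i,
                recessive_e148q_display=round_half_up(rec_i, recessive_digits),
                het_causal_bound_e148q=bound_i,
                het_causal_bound_e148q_display=round_half_up(bound_i, bound_digits),
            )
        else:
            row.update(
                recessive_e148q=None,
                recessive_e148q_display=None,
                het_causal_bound_e148q=None,
                het_causal_bound_e148q_display=None,
            )
        if pop.has_observed:
            row["verdict"] = classify_observed(
                pop.prevalence_observed_low, pop.prevalence_observed_high, pop.q_strict
            )
        else:
            row["verdict"] = "no_observed_prevalence"
        rows.append(row)
    return pd.DataFrame(rows)
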