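"""Hardy-Weinberg genotype algebra at a single biallelic locus.

For a mutated-allele frequency ``q`` (normal-allele frequency ``p = 1 - q``)
the random-mating genotype frequencies are ``q**2`` (two mutated alleles),
``2*p*q`` (heterozygous carriers) and ``p**2`` (non-carriers).  The ratio of
heterozygous carriers to non-carriers,

    R = 2pq / p**2 = 2q / p,

is the comparison statistic used throughout the package: it is the number of
heterozygotes one expects per non-carrier in a population sample from which
individuals carrying two mutated alleles have been removed.

Because the downstream analyses are validated against published tables, the
presentation rounding used there is part of the contract: decimal rounding
with ties away from zero (``round_half_up``), never Python's default
banker's rounding.  All internal arithmetic is carried at full precision;
rounding is applied only at explicit presentation or expected-count
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "AlleleFrequency",
    "GenotypeFrequencies",
    "UndefinedRatioError",
    "carrier_ratio",
    "genotype_frequencies",
    "round_half_up",
    "round_sig_half_up",
]


class UndefinedRatioError(ZeroDivisionError):
    """The heterozygote:non-carrier ratio is undefined (no non-carriers)."""


def _as_q(q: "float | AlleleFrequency") -> float:
    value = float(getattr(q, "q", q))
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"allele frequency q must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class AlleleFrequency:
    """Frequency of the mutated allele; the normal allele has frequency ``p = 1 - q``."""

    q: float

    def __post_init__(self) -> None:
        _as_q(self.q)

    @property
    def p(self) -> float:
        return 1.0 - self.q


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Hardy-Weinberg genotype class frequencies (two mutated / one / none)."""

    f_two_mut: float
    f_het: float
    f_none: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_two_mut, self.f_het, self.f_none)


def genotype_frequencies(q: "float | AlleleFrequency") -> GenotypeFrequencies:
    """Return the Hardy-Weinberg genotype frequencies ``(q**2, 2pq, p**2)``."""
    qv = _as_q(q)
    p = 1.0 - qv
    return GenotypeFrequencies(qv * qv, 2.0 * p * qv, p * p)


def carrier_ratio(q: "float | AlleleFrequency") -> float:
    """Heterozygotes per non-carrier, ``R = 2pq/p**2 = 2q/p``, unrounded.

    Raises :class:`UndefinedRatioError` at ``q = 1`` (no non-carriers exist).
    """
    qv = _as_q(q)
    p = 1.0 - qv
    if p == 0.0:
        raise UndefinedRatioError("carrier ratio undefined at q = 1 (p = 0)")
    return 2.0 * qv / p


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal rounding with ties away from zero.

    ``round_half_up(0.0025, 3) == 0.003`` and ``round_half_up(2.5, 0) == 3``,
    where banker's rounding would give 0.002 and 2.  Operates on the shortest
    decimal representation of ``x`` so that values that *print* as exact ties
    round as ties.
    """
    if digits < 0:
        raise ValueError("digits must be >= 0")
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def round_sig_half_up(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, ties away from zero.

    Used for risk figures quoted like 2.1e-3 (two significant figures).
    """
    if sig < 1:
        raise ValueError("sig must be >= 1")
    xv = float(x)
    if xv == 0.0 or not math.isfinite(xv):
        return xv
    exponent = math.floor(math.log10(abs(xv)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(xv)).quantize(quantum, rounding=ROUND_HALF_UP))
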