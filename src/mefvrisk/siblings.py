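"""Segregation of *MEFV* genotypes in affected siblings of two-mutation probands.

In typical Mendelian-recessive familial forms, an affected sibling of a
proband who carries two mutated alleles should itself carry two mutated
alleles.  Families are ascertained on an affected two-mutation proband with
at least one affected sibling; this module tabulates the affected siblings'
genotypes, compares them with Mendelian expectations for a given parental
mating type, and tests whether heterozygous affected siblings are in excess
of what a genotype-specific penetrance model predicts.

The expected fraction of *affected* siblings that are heterozygous, given
sibling genotype probabilities ``(P_mm, P_het, P_none)`` from the mating
type and penetrances ``(f_hom, f_het, f_non)``, is the conditional

    E[het | affected] = P_het*f_het / (P_mm*f_hom + P_het*f_het + P_none*f_non),

against which the observed heterozygous count among affected siblings is
tested with an exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .hwe import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyMember",
    "FamilyRecord",
    "SiblingSummary",
    "het_sib_excess_test",
    "mendelian_sib_genotype_distribution",
    "summarize_families",
]

GENOTYPES = ("two_mut", "het", "none")

#: Offspring genotype distributions (two_mut, het, none) by parental mating type.
MENDELIAN = {
    "het_x_het": (0.25, 0.5, 0.25),
    "het_x_two_mut": (0.5, 0.5, 0.0),
    "two_mut_x_two_mut": (1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class FamilyMember:
    individual_id: str
    role: str  # "proband" | "sibling"
    genotype: str  # "two_mut" | "het" | "none"
    affected: bool
    diagnosis_retained: bool | None = None  # meaningful only for affected members

    def __post_init__(self) -> None:
        if self.role not in ("proband", "sibling"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class FamilyRecord:
    """A nuclear family ascertained on an affected two-mutation proband."""

    family_id: str
    members: list[FamilyMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        probands = [m for m in self.members if m.role == "proband"]
        if len(probands) != 1:
            raise ValueError(f"family {self.family_id}: exactly one proband required")
        proband = probands[0]
        if proband.genotype != "two_mut" or not proband.affected:
            raise ValueError(
                f"family {self.family_id}: proband must be affected with two mutated alleles"
            )

    @property
    def siblings(self) -> list[FamilyMember]:
        return [m for m in self.members if m.role == "sibling"]

    @property
    def affected_siblings(self) -> list[FamilyMember]:
        return [m for m in self.siblings if m.affected]


@dataclass(frozen=True)
class SiblingSummary:
    n_families: int
    n_affected_sibs: int
    affected_by_genotype: tuple[int, int, int]  # (two_mut, het, none)
    n_diagnosis_not_retained_het: int
    n_unaffected_het_sibs: int

    def genotype_percent(self, genotype: str, digits: int = 0) -> float:
        """Percentage of affected siblings in a genotype class (half-up)."""
        idx = GENOTYPES.index(genotype)
        if self.n_affected_sibs == 0:
            return 0.0
        return round_half_up(
            100.0 * self.affected_by_genotype[idx] / self.n_affected_sibs, digits
        )


def summarize_families(families: list[FamilyRecord]) -> SiblingSummary:
    """Tally affected-sibling genotypes across families.

    Families without any affected sibling violate the ascertainment rule and
    are excluded with a logged warning rather than failing the whole run.
    """
    kept = []
    for family in families:
        if not family.affected_siblings:
            logger.warning(
                "family %s has no affected sibling; excluded from summary", family.family_id
            )
            continue
        kept.append(family)
    by_genotype = {g: 0 for g in GENOTYPES}
    not_retained_het = 0
    unaffected_het = 0
    n_affected = 0
    for family in kept:
        for sib in family.siblings:
            if sib.affected:
                n_affected += 1
                by_genotype[sib.genotype] += 1
                if sib.genotype == "het" and sib.diagnosis_retained is False:
                    not_retained_het += 1
            elif sib.genotype == "het":
                unaffected_het += 1
    return SiblingSummary(
        n_families=len(kept),
        n_affected_sibs=n_affected,
        affected_by_genotype=(by_genotype["two_mut"], by_genotype["het"], by_genotype["none"]),
        n_diagnosis_not_retained_het=not_retained_het,
        n_unaffected_het_sibs=unaffected_het,
    )


def mendelian_sib_genotype_distribution(parental_mating: str) -> tuple[float, float, float]:
    """Offspring genotype probabilities (two_mut, het, none) for a mating type.

    Only matings able to produce a two-mutation proband are valid.
    """
    try:
        return MENDELIAN[parental_mating]
    except KeyError:
        raise ValueError(
            f"mating type {parental_mating!r} cannot produce a two-mutation proband "
            f"(valid: {sorted(MENDELIAN)})"
        ) from None


def het_sib_excess_test(
    summary: SiblingSummary,
    f_het: float,
    f_non: float,
    parental_mating: str = "het_x_het",
    f_hom: float = 1.0,
    strict_diagnosis: bool = False,
) -> tuple[float, float]:
    """Expected heterozygous fraction among affected sibs, and a binomial p.

    ``strict_diagnosis=True`` drops heterozygous affected siblings whose FMF
    diagnosis was not retained from both numerator and denominator before
    testing.  Returns ``(expected_het_fraction, p_value)``; the p-value is a
    two-sided exact binomial test of the observed heterozygous count.
    """
    for label, value in (("f_hom", f_hom), ("f_het", f_het), ("f_non", f_non)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1], got {value!r}")
    p_mm, p_het, p_none = mendelian_sib_genotype_distribution(parental_mating)
    denominator = p_mm * f_hom + p_het * f_het + p_none * f_non
    if denominator == 0.0:
        raise ValueError("all penetrances are zero: no sibling can be affected")
    expected_fraction = p_het * f_het / denominator

    k = summary.affected_by_genotype[1]
    n = summary.n_affected_sibs
    if strict_diagnosis:
        k -= summary.n_diagnosis_not_retained_het
        n -= summary.n_diagnosis_not_retained_het
    if expected_fraction == 0.0:
        # boundary: any observed heterozygote is incompatible with the model
        return 0.0, (1.0 if k == 0 else 0.0)
    p_value = stats.binomtest(k, n, expected_fraction, alternative="two-sided").pvalue
    return expected_fraction, float(p_value)
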