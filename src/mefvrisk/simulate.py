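"""Forward simulation of populations and families under genotype-specific penetrance.

The generative model is the minimal formalization of the analysis
assumptions: genotypes at a single biallelic locus drawn from Hardy-Weinberg
proportions at mutated-allele frequency ``q``, and disease assigned per
individual as a Bernoulli draw with a genotype-specific penetrance
``(f_hom, f_het, f_non)`` — ``f_non`` being the phenocopy rate.  Setting
``f_het = f_non`` expresses the null model in which heterozygosity carries
no disease risk beyond background.

Populations are simulated at the tally level (multinomial genotype counts,
binomial affected counts per genotype class), which keeps multi-million-
individual runs in constant memory; a per-individual stream is available on
request.  Families are simulated by drawing parental mating types from HWE
conditional on the mating being able to produce a two-mutation child,
transmitting alleles by Mendelian segregation, assigning phenotypes by
penetrance, and rejection-sampling until the family satisfies the study
ascertainment rule (an affected two-mutation proband plus at least one
affected sibling; ascertainment is single, through a fixed proband slot).

All entry points require an explicit seed; a single :class:`numpy.random.
Generator` drives each run, so identical seeds give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .carrier_excess import GenotypeTally
from .hwe import UndefinedRatioError, _as_q, genotype_frequencies
from .siblings import FamilyMember, FamilyRecord, mendelian_sib_genotype_distribution

__all__ = [
    "PenetranceModel",
    "RiskEstimates",
    "SimulatedPopulation",
    "ascertain_cohort",
    "calibrate_penetrance",
    "recover_risk",
    "simulate_families",
    "simulate_population",
    "turkish_penetrance",
]

#: Mutated-allele frequency of the default (Turkish-calibrated) scenario.
DEFAULT_Q = 0.05
#: Population prevalence the default scenario is calibrated to.
DEFAULT_PREVALENCE = 0.001


@dataclass(frozen=True)
class PenetranceModel:
    """Probability of disease for each genotype class.

    ``f_hom``: two mutated alleles; ``f_het``: one; ``f_non``: none (the
    phenocopy rate).  A susceptibility model has ``f_hom >= f_het >= f_non``;
    violating that ordering is allowed (the null model must be expressible,
    and so must pathological orderings for testing) but draws a warning.
    """

    f_hom: float
    f_het: float
    f_non: float

    def __post_init__(self) -> None:
        values = (self.f_hom, self.f_het, self.f_non)
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ValueError(f"penetrances must lie in [0, 1]: {values}")
        if not (self.f_hom >= self.f_het >= self.f_non):
            warnings.warn(
                f"penetrance ordering f_hom >= f_het >= f_non violated: {values}",
                stacklevel=2,
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_hom, self.f_het, self.f_non)


def calibrate_penetrance(
    prevalence: float, q: float, f_het: float, f_non: float
) -> PenetranceModel:
    """Choose ``f_hom`` so the model's net prevalence equals ``prevalence``.

    Solves ``q**2*f_hom + 2pq*f_het + p**2*f_non = prevalence`` for ``f_hom``.
    """
    g = genotype_frequencies(q)
    if g.f_two_mut == 0.0:
        raise ValueError("cannot calibrate f_hom at q = 0 (no two-mutation class)")
    f_hom = (prevalence - g.f_het * f_het - g.f_none * f_non) / g.f_two_mut
    if not 0.0 <= f_hom <= 1.0:
        raise ValueError(
            f"calibration infeasible: implied f_hom = {f_hom:.4g} outside [0, 1]"
        )
    return PenetranceModel(f_hom=f_hom, f_het=f_het, f_non=f_non)


def turkish_penetrance() -> PenetranceModel:
    """The Turkish-calibrated ground truth used as the default study condition.

    Heterozygote risk 19/9,101 ≈ 2.1e-3 and phenocopy rate 30/90,848 ≈
    3.3e-4 are the maximum-likelihood estimates from the closed-population
    risk reconstruction at prevalence 0.001 and q = 0.05; ``f_hom`` ≈ 0.20
    is calibrated so the net prevalence is exactly 0.001.
    """
    return calibrate_penetrance(
        DEFAULT_PREVALENCE, DEFAULT_Q, f_het=19 / 9101, f_non=30 / 90848
    )


@dataclass(frozen=True)
class SimulatedPopulation:
    """Genotype x affected tallies of one simulated population."""

    seed: int
    q: float
    size: int
    genotype_counts: tuple[int, int, int]  # (two_mut, het, none)
    affected_counts: tuple[int, int, int]  # affected within each genotype class
    genotypes: np.ndarray | None = None  # per-individual stream (0/1/2 mutated-allele codes)
    affected: np.ndarray | None = None


class RiskEstimates(NamedTuple):
    risk_het: float
    risk_none: float
    relative_risk: float


def simulate_population(
    size: int,
    q: float,
    penetrance: PenetranceModel,
    seed: int,
    keep_individuals: bool = False,
) -> SimulatedPopulation:
    """Simulate ``size`` individuals under HWE(``q``) and the penetrance model.

    Genotype counts are multinomial in ``(q**2, 2pq, p**2)``; affected counts
    are binomial per genotype class.  ``keep_individuals=True`` additionally
    materializes per-individual genotype/affected arrays (genotype classes in
    tally order; within each class affected individuals come first — class
    membership, not individual order, is the random object).
    """
    if size < 1:
        raise ValueError(f"population size must be >= 1, got {size!r}")
    if seed is None:
        raise ValueError("an explicit seed is required")
    qv = _as_q(q)
    rng = np.random.default_rng(seed)
    g = genotype_frequencies(qv)
    counts = rng.multinomial(size, g.as_tuple())
    affected = np.array(
        [rng.binomial(int(n), f) for n, f in zip(counts, penetrance.as_tuple())]
    )
    individuals = None
    affected_stream = None
    if keep_individuals:
        individuals = np.repeat(np.array([2, 1, 0], dtype=np.int8), counts)
        flags = np.concatenate(
            [
                np.concatenate([np.ones(int(a), bool), np.zeros(int(n - a), bool)])
                for n, a in zip(counts, affected)
            ]
        )
        affected_stream = flags
    return SimulatedPopulation(
        seed=seed,
        q=qv,
        size=size,
        genotype_counts=tuple(int(n) for n in counts),
        affected_counts=tuple(int(a) for a in affected),
        genotypes=individuals,
        affected=affected_stream,
    )


def ascertain_cohort(pop: SimulatedPopulation) -> tuple[GenotypeTally, GenotypeTally]:
    """Partition the population into (patients, healthy) genotype tallies."""
    two, het, none = pop.genotype_counts
    a_two, a_het, a_none = pop.affected_counts
    patients = GenotypeTally(a_two, a_het, a_none, group_label="affected")
    healthy = GenotypeTally(two - a_two, het - a_het, none - a_none, group_label="healthy")
    return patients, healthy


def recover_risk(patients: GenotypeTally, healthy: GenotypeTally) -> RiskEstimates:
    """Genotype-specific risk estimates from full-population tallies.

    ``risk_het = patients.het / (patients.het + healthy.het)`` etc.; under
    the Bernoulli penetrance model these are the maximum-likelihood
    estimates of ``f_het`` and ``f_non``, and their ratio estimates the
    relative risk.
    """
    het_total = patients.n_het + healthy.n_het
    none_total = patients.n_none + healthy.n_none
    if het_total == 0 or none_total == 0:
        raise UndefinedRatioError("empty genotype compartment; risk undefined")
    risk_het = patients.n_het / het_total
    risk_none = patients.n_none / none_total
    if risk_none == 0.0:
        raise UndefinedRatioError("no affected non-carriers; relative risk undefined")
    return RiskEstimates(risk_het, risk_none, risk_het / risk_none)


#: (mating label, per-child genotype distribution) eligible to produce a
#: two-mutation proband, with HWE pair weights computed at run time.
_ELIGIBLE_MATINGS = ("two_mut_x_two_mut", "het_x_two_mut", "het_x_het")


def _mating_weights(q: float) -> np.ndarray:
    g = genotype_frequencies(q)
    weights = np.array(
        [
            g.f_two_mut * g.f_two_mut,
            2.0 * g.f_two_mut * g.f_het,
            g.f_het * g.f_het,
        ]
    )
    total = weights.sum()
    if total == 0.0:
        raise ValueError(f"no mating can produce a two-mutation child at q = {q}")
    return weights / total


def simulate_families(
    n_families: int,
    q: float,
    penetrance: PenetranceModel,
    seed: int,
    sibship_sizes: Sequence[int] = (2, 3, 4),
    mating: str = "hwe",
    max_attempts_per_family: int = 10**6,
) -> list[FamilyRecord]:
    """Simulate families passing the affected-sib ascertainment filter.

    Parental matings are drawn from HWE conditional on being able to produce
    a two-mutation child (or fixed to one mating type via ``mating``);
    children's genotypes follow Mendelian segregation, phenotypes the
    penetrance model.  Ascertainment is single (through a fixed proband
    slot): a family is rejection-sampled until its first child is an
    affected two-mutation proband and at least one later-born sibling is
    affected — so the siblings remain an iid draw and conditional
    closed forms hold exactly.  Exactly ``n_families`` accepted families
    are returned.

    Raises ``RuntimeError`` if a family is not accepted within
    ``max_attempts_per_family`` draws (acceptance probability too low).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if any(s < 2 for s in sibship_sizes):
        raise ValueError("sibship sizes must be >= 2 (proband plus at least one sibling)")
    qv = _as_q(q)
    rng = np.random.default_rng(seed)
    if mating == "hwe":
        weights = _mating_weights(qv)
    elif mating in _ELIGIBLE_MATINGS:
        weights = np.array([1.0 if m == mating else 0.0 for m in _ELIGIBLE_MATINGS])
    else:
        raise ValueError(f"unknown mating {mating!r} (valid: 'hwe' or {_ELIGIBLE_MATINGS})")
    sizes = np.asarray(list(sibship_sizes))
    penetrances = np.array(penetrance.as_tuple())  # indexed by (two_mut, het, none)

    families: list[FamilyRecord] = []
    for index in range(n_families):
        for attempt in range(1, max_attempts_per_family + 1):
            mating_type = _ELIGIBLE_MATINGS[rng.choice(3, p=weights)]
            child_dist = mendelian_sib_genotype_distribution(mating_type)
            n_children = int(sizes[rng.integers(len(sizes))])
            genotype_idx = rng.choice(3, size=n_children, p=child_dist)
            affected = rng.random(n_children) < penetrances[genotype_idx]
            if genotype_idx[0] == 0 and affected[0] and affected[1:].any():
                break
        else:
            raise RuntimeError(
                f"family {index}: no acceptable family in {max_attempts_per_family} "
                f"draws (q={qv}, penetrance={penetrance.as_tuple()}, mating={mating}); "
                "acceptance probability too low"
            )
        proband_pos = 0
        genotype_names = ("two_mut", "het", "none")
        members = []
        for child in range(n_children):
            members.append(
                FamilyMember(
                    individual_id=f"F{index:04d}-{child + 1}",
                    role="proband" if child == proband_pos else "sibling",
                    genotype=genotype_names[genotype_idx[child]],
                    affected=bool(affected[child]),
                    diagnosis_retained=True if affected[child] else None,
                )
            )
        families.append(FamilyRecord(family_id=f"F{index:04d}", members=members))
    return families
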