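"""Forward population/family simulation and parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from mefvrisk import (
    PenetranceModel,
    ascertain_cohort,
    calibrate_penetrance,
    carrier_ratio,
    genotype_frequencies,
    pearson_chi2_2x2,
    recover_risk,
    simulate_families,
    simulate_population,
    summarize_families,
    turkish_penetrance,
)
from mefvrisk.hwe import UndefinedRatioError


def test_penetrance_model_validation_and_warning():
    with pytest.raises(ValueError):
        PenetranceModel(1.2, 0.0, 0.0)
    with pytest.warns(UserWarning):
        PenetranceModel(0.1, 0.5, 0.0)  # non-monotone allowed but flagged
    null = PenetranceModel(1.0, 2e-3, 2e-3)  # null model expressible silently
    assert null.f_het == null.f_non


def test_calibration_hits_target_prevalence():
    model = turkish_penetrance()
    g = genotype_frequencies(0.05)
    net = (
        g.f_two_mut * model.f_hom + g.f_het * model.f_het + g.f_none * model.f_non
    )
    assert net == pytest.approx(0.001, rel=1e-12)
    assert model.f_hom == pytest.approx(0.2015, abs=1e-3)
    with pytest.raises(ValueError):
        calibrate_penetrance(0.9, 0.05, 0.0, 0.0)  # would need f_hom > 1


def test_simulation_is_deterministic_given_seed():
    model = turkish_penetrance()
    a = simulate_population(10_000, 0.05, model, seed=42)
    b = simulate_population(10_000, 0.05, model, seed=42)
    assert a == b
    c = simulate_population(10_000, 0.05, model, seed=43)
    assert a.genotype_counts != c.genotype_counts or a.affected_counts != c.affected_counts


@pytest.mark.parametrize(
    "penetrance, q",
    [(PenetranceModel(0.0, 0.0, 0.0), 0.05), (PenetranceModel(1.0, 0.0, 0.0), 0.0)],
)
def test_trivial_penetrance_and_frequency_limits(penetrance, q):
    pop = simulate_population(50_000, q, penetrance, seed=1)
    if penetrance.f_hom == 0.0:
        assert pop.affected_counts == (0, 0, 0)
    if q == 0.0:
        assert pop.genotype_counts == (0, 0, 50_000)


def test_strict_recessive_prevalence_converges_to_q_squared():
    pop = simulate_population(1_000_000, 0.05, PenetranceModel(1.0, 0.0, 0.0), seed=5)
    affected_fraction = sum(pop.affected_counts) / pop.size
    se = np.sqrt(0.0025 * 0.9975 / pop.size)
    assert abs(affected_fraction - 0.0025) < 3 * se


def test_individual_stream_consistent_with_tallies():
    pop = simulate_population(5_000, 0.1, turkish_penetrance(), seed=9, keep_individuals=True)
    assert len(pop.genotypes) == len(pop.affected) == pop.size
    for code, count in zip((2, 1, 0), pop.genotype_counts):
        assert int((pop.genotypes == code).sum()) == count
    assert int(pop.affected.sum()) == sum(pop.affected_counts)


def test_seed_is_mandatory():
    with pytest.raises(ValueError):
        simulate_population(100, 0.05, turkish_penetrance(), seed=None)
    with pytest.raises(ValueError):
        simulate_families(1, 0.05, turkish_penetrance(), seed=None)


def test_hwe_recovery_calibration():
    """Goodness-of-fit vs (p^2, 2pq, q^2) rejects at alpha=0.001 in <1% of runs."""
    g = genotype_frequencies(0.05)
    expected = np.array(g.as_tuple())[::-1]  # (none, het, two) order irrelevant
    model = PenetranceModel(0.0, 0.0, 0.0)
    rejections = 0
    n_runs, size = 1_000, 100_000
    for seed in range(n_runs):
        pop = simulate_population(size, 0.05, model, seed=seed)
        observed = np.array(pop.genotype_counts)[::-1]
        p = stats.chisquare(observed, expected * size).pvalue
        rejections += p < 0.001
    assert rejections / n_runs <= 0.01


def test_ascertainment_bias_enriches_heterozygotes():
    """With f_het > f_non, patients carry more heterozygotes than the population."""
    pop = simulate_population(2_000_000, 0.05, turkish_penetrance(), seed=77)
    patients, healthy = ascertain_cohort(pop)
    assert patients.n_het / patients.n_none > carrier_ratio(0.05)
    # and patient genotype fractions approach the published (0.51, 0.19, 0.30)
    fractions = np.array([patients.n_two_mut, patients.n_het, patients.n_none]) / patients.total
    assert np.allclose(fractions, [0.51, 0.19, 0.30], atol=0.03)


def test_null_model_gives_population_ratio_and_uniformish_pvalue():
    model = calibrate_penetrance(0.001, 0.05, f_het=5e-4, f_non=5e-4)
    pvals = []
    for seed in range(30):
        pop = simulate_population(500_000, 0.05, model, seed=seed)
        patients, healthy = ascertain_cohort(pop)
        _, p = pearson_chi2_2x2(
            (patients.n_het, patients.n_none), (healthy.n_het, healthy.n_none)
        )
        pvals.append(p)
    assert 0.05 < np.median(pvals) < 0.95


def test_recover_risk_on_published_worked_example():
    from mefvrisk import GenotypeTally

    patients = GenotypeTally(51, 19, 30)
    healthy = GenotypeTally(199, 9_082, 90_818)
    estimate = recover_risk(patients, healthy)
    assert estimate.risk_het == pytest.approx(2.1e-3, rel=0.01)
    assert estimate.relative_risk == pytest.approx(6.32, abs=0.01)
    with pytest.raises(UndefinedRatioError):
        recover_risk(GenotypeTally(0, 0, 5), GenotypeTally(0, 0, 5))


def test_recovered_relative_risk_is_one_under_null():
    model = calibrate_penetrance(0.001, 0.05, f_het=5e-4, f_non=5e-4)
    estimates = []
    for seed in range(10):
        pop = simulate_population(1_000_000, 0.05, model, seed=seed)
        estimates.append(recover_risk(*ascertain_cohort(pop)).relative_risk)
    assert np.mean(estimates) == pytest.approx(1.0, abs=0.15)


def test_families_deterministic_and_ascertainment_respected():
    model = turkish_penetrance()
    fam_a = simulate_families(20, 0.05, model, seed=3)
    fam_b = simulate_families(20, 0.05, model, seed=3)
    assert fam_a == fam_b
    for family in fam_a:
        proband = [m for m in family.members if m.role == "proband"]
        assert len(proband) == 1 and proband[0].genotype == "two_mut" and proband[0].affected
        assert any(m.affected for m in family.members if m.role == "sibling")


def test_strict_recessive_families_have_only_two_mut_affected_sibs():
    families = simulate_families(40, 0.05, PenetranceModel(1.0, 0.0, 0.0), seed=21)
    summary = summarize_families(families)
    assert summary.affected_by_genotype[1] == summary.affected_by_genotype[2] == 0
    assert summary.n_affected_sibs >= 40


def test_family_het_fraction_matches_conditional_closed_form():
    """penetrance (1, h, 0), het x het matings: affected-sib het fraction -> (h/2)/(h/2 + 1/4)."""
    h = 0.05
    families = simulate_families(
        3_000, 0.05, PenetranceModel(1.0, h, 0.0), seed=13, mating="het_x_het"
    )
    summary = summarize_families(families)
    observed = summary.affected_by_genotype[1] / summary.n_affected_sibs
    expected = (0.5 * h) / (0.5 * h + 0.25)
    se = np.sqrt(expected * (1 - expected) / summary.n_affected_sibs)
    assert abs(observed - expected) < 4 * se


def test_infeasible_family_ascertainment_aborts():
    with pytest.raises(RuntimeError, match="acceptance probability"):
        simulate_families(
            1, 0.05, PenetranceModel(0.0, 0.0, 0.0), seed=1, max_attempts_per_family=100
        )
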