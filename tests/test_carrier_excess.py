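"""Heterozygote-excess testing: ratios, expected counts, 2x2 tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mefvrisk import (
    ConfigError,
    GenotypeTally,
    UndefinedRatioError,
    expected_counts,
    fisher_exact_2x2,
    observed_ratio,
    pearson_chi2_2x2,
    round_half_up,
    run_carrier_excess,
)
from mefvrisk.carrier_excess import DegenerateTableError

from .oracles import chi2_null_pvalue_mc, fisher_two_sided_enumeration


@pytest.mark.parametrize(
    "het, none, display",
    [(25, 19, 1.32), (41, 25, 1.64), (38, 98, 0.39), (15, 24, 0.63), (0, 10, 0.0)],
)
def test_observed_ratio_matches_published_display(het, none, display):
    ratio = observed_ratio(GenotypeTally(0, het, none))
    assert round_half_up(ratio, 2) == display


def test_observed_ratio_undefined_without_noncarriers():
    with pytest.raises(UndefinedRatioError):
        observed_ratio(GenotypeTally(0, 5, 0))


@pytest.mark.parametrize(
    "n, q, expected",
    [
        (44, 0.07, (5.74, 38.26)),
        (136, 0.04, (10.07, 125.93)),
        (66, 0.09, (11.00, 55.00)),
        (39, 0.05, (3.86, 35.14)),
    ],
)
def test_expected_counts_reproduce_published_pairs(n, q, expected):
    assert expected_counts(n, q) == expected


@given(
    n=st.integers(min_value=1, max_value=10_000),
    q=st.floats(min_value=0.0, max_value=0.5, allow_nan=False),
)
def test_expected_counts_sum_to_group_size_exactly(n, q):
    e_het, e_none = expected_counts(n, q)
    assert e_het + e_none == n  # exact by subtraction construction


def test_expected_counts_exact_universe_keeps_homozygotes():
    e_het, e_none = expected_counts(100, 0.05, exact_universe=True)
    assert (e_het, e_none) == (9.5, 90.25)  # 2pq*n, p^2*n; missing q^2*n = 0.25
    with pytest.raises(UndefinedRatioError):
        expected_counts(10, 1.0)


def test_pearson_chi2_armenian_reproduces_hand_computation():
    # hand-computed Pearson 2x2 with marginals N=88 gives 18.55, p=1.66e-5
    stat, p = pearson_chi2_2x2((25, 19), (5.74, 38.26))
    assert stat == pytest.approx(18.546, abs=0.01)
    assert p == pytest.approx(1.66e-5, rel=0.01)
    assert p < 2e-5


def test_pearson_chi2_identical_rows_is_null():
    stat, p = pearson_chi2_2x2((10, 30), (10, 30))
    assert stat == 0.0
    assert p == 1.0


def test_pearson_chi2_symmetries():
    stat, _ = pearson_chi2_2x2((25, 19), (6, 38))
    stat_rows, _ = pearson_chi2_2x2((6, 38), (25, 19))
    stat_cols, _ = pearson_chi2_2x2((19, 25), (38, 6))
    assert stat_rows == pytest.approx(stat, rel=1e-12)
    assert stat_cols == pytest.approx(stat, rel=1e-12)


def test_degenerate_tables_rejected():
    with pytest.raises(DegenerateTableError):
        pearson_chi2_2x2((5, 0), (3, 0))
    with pytest.raises(DegenerateTableError):
        pearson_chi2_2x2((0, 0), (3, 4))
    with pytest.raises(ValueError):
        pearson_chi2_2x2((-1, 5), (3, 4))


@pytest.mark.parametrize(
    "observed, control",
    [((25, 19), (6, 38)), ((1, 0), (0, 1)), ((10, 10), (10, 10)), ((3, 17), (12, 8))],
)
def test_fisher_matches_enumeration_oracle(observed, control):
    p = fisher_exact_2x2(observed, control)
    oracle = fisher_two_sided_enumeration(*observed, *control)
    assert p == pytest.approx(oracle, rel=1e-9)


def test_fisher_rounds_fractional_control_counts():
    assert fisher_exact_2x2((25, 19), (5.74, 38.26)) == pytest.approx(
        fisher_two_sided_enumeration(25, 19, 6, 38), rel=1e-9
    )


def test_fisher_and_pearson_agree_on_large_tables():
    """Smoke property: for well-filled tables the two tests agree within 3x."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        row1 = tuple(rng.integers(20, 80, size=2))
        row2 = tuple(rng.integers(20, 80, size=2))
        _, p_chi2 = pearson_chi2_2x2(row1, row2)
        p_fisher = fisher_exact_2x2(row1, row2)
        assert p_fisher / 3 <= p_chi2 <= p_fisher * 3


def test_chi2_pvalue_within_monte_carlo_error():
    observed, control = (15, 24), (4, 35)
    _, p = pearson_chi2_2x2(observed, control)
    n_sim = 100_000
    p_mc = chi2_null_pvalue_mc(observed, control, n_sim=n_sim, seed=11)
    se = np.sqrt(p * (1 - p) / n_sim)
    assert abs(p - p_mc) <= 3 * se


def test_run_carrier_excess_reproduces_published_rows(unexplained_tallies, study_populations):
    results = run_carrier_excess(unexplained_tallies, study_populations)
    by_label = {r.group_label: r for r in results}
    assert (by_label["Armenian"].expected_het, by_label["Armenian"].expected_none) == (5.74, 38.26)
    assert (by_label["Sephardic"].expected_het, by_label["Sephardic"].expected_none) == (11.0, 55.0)
    assert (by_label["Arab"].expected_het, by_label["Arab"].expected_none) == (10.07, 125.93)
    turkish = by_label["Turkish"]
    # the published expected pair implies the two-decimal carrier ratio 0.11,
    # although the ratio itself was printed at one decimal (0.1)
    assert (turkish.expected_het, turkish.expected_none) == (3.86, 35.14)
    assert turkish.r_expected == 0.11
    assert round_half_up(turkish.r_expected_unrounded, 1) == 0.1
    # both p-value variants are reported; they straddle the published bound
    assert turkish.p_value_unrounded < 3e-3 < turkish.p_value < 4e-3


def test_run_carrier_excess_fisher_method(unexplained_tallies, study_populations):
    results = run_carrier_excess(unexplained_tallies, study_populations, method="fisher_exact")
    for result in results:
        assert 0.0 < result.p_value <= 1.0
        assert np.isnan(result.statistic)


def test_run_carrier_excess_input_validation(study_populations):
    with pytest.raises(ConfigError):
        run_carrier_excess([GenotypeTally(1, 5, 5, "Armenian")], study_populations)
    with pytest.raises(ConfigError):
        run_carrier_excess([GenotypeTally(0, 5, 5, "Atlantis")], study_populations)
    with pytest.raises(ConfigError):
        run_carrier_excess([], study_populations, method="t_test")
    assert run_carrier_excess([], study_populations) == []
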