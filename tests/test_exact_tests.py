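"""Exact tests against brute-force enumeration oracles and known identities."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from snpepi.exact_tests import TestResult as ExactResult
from snpepi.exact_tests import (
    chi_square,
    fisher_exact,
    hwe_exact,
    hwe_het_distribution,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration of genotype configurations.

    Conditional probability of (x, y, z) given the allele counts is
    proportional to the number of ways of pairing the alleles:
    n! 2^y / (x! y! z!).  Independent of the closed-form implementation.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    configs = []
    for y in range(min(na, 2 * n - na) + 1):
        if (na - y) % 2:
            continue
        x = (na - y) // 2
        z = n - x - y
        if z < 0:
            continue
        w = math.factorial(n) * 2**y // (
            math.factorial(x) * math.factorial(y) * math.factorial(z)
        )
        configs.append((y, w))
    total = sum(w for _, w in configs)
    obs = dict(configs)[n_ab]
    return sum(w for _, w in configs if w <= obs) / total


def fisher_oracle(table):
    """Two-sided Fisher p by exhaustive iteration over free cells."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    r, c = t.shape

    def prob(tab):
        num = sum(math.lgamma(x + 1) for x in rows) + sum(math.lgamma(x + 1) for x in cols)
        den = math.lgamma(tab.sum() + 1) + sum(math.lgamma(x + 1) for x in tab.flat)
        return math.exp(num - den)

    p_obs = prob(t)
    total = 0.0
    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for free in itertools.product(*ranges):
        tab = np.zeros((r, c), dtype=int)
        tab[: r - 1, : c - 1] = np.asarray(free).reshape(r - 1, c - 1)
        tab[: r - 1, c - 1] = rows[: r - 1] - tab[: r - 1, : c - 1].sum(axis=1)
        tab[r - 1, :] = cols - tab[: r - 1].sum(axis=0)
        if (tab >= 0).all():
            p = prob(tab)
            if p <= p_obs * (1 + 1e-7):
                total += p
    return total


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts",
    [(3, 4, 3), (5, 1, 4), (0, 7, 2), (10, 10, 10), (1, 1, 1), (12, 2, 7), (2, 9, 0)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact(counts).p_value == pytest.approx(hwe_oracle(*counts), rel=1e-9)


@given(
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_matches_oracle_property(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    assert hwe_exact((n_aa, n_ab, n_bb)).p_value == pytest.approx(
        hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9
    )


def test_hwe_perfect_proportions_give_p_one():
    assert hwe_exact((25, 50, 25)).p_value == pytest.approx(1.0)


def test_hwe_monomorphic_sample_is_uninformative():
    res = hwe_exact((30, 0, 0))
    assert res.p_value == 1.0
    assert "monomorphic" in res.note


def test_hwe_conditional_distribution_is_proper():
    hs, probs = hwe_het_distribution((7, 11, 5))
    assert probs.sum() == pytest.approx(1.0)
    assert (probs >= 0).all()
    assert len(hs) == len(probs)


def test_hwe_rejects_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact((-1, 2, 3))
    with pytest.raises(ValueError):
        hwe_exact((0, 0, 0))


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "table",
    [
        [[3, 5], [6, 2], [4, 4]],
        [[2, 0, 4], [1, 3, 2], [5, 1, 0]],
        [[8, 2], [3, 7]],
        [[1, 2, 3], [3, 2, 1]],
        [[6, 1], [2, 5], [0, 4], [3, 3]],
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    assert fisher_exact(table).p_value == pytest.approx(fisher_oracle(table), rel=1e-9)


@given(st.lists(st.lists(st.integers(0, 8), min_size=2, max_size=3), min_size=2, max_size=3))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_fisher_matches_oracle_property(rows):
    width = len(rows[0])
    table = [r[:width] + [0] * (width - len(r)) for r in rows]
    t = np.asarray(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return
    assert fisher_exact(table).p_value == pytest.approx(fisher_oracle(table), rel=1e-9)


def test_fisher_2x2_matches_scipy():
    for table in ([[8, 2], [1, 5]], [[12, 7], [3, 9]], [[2, 3], [4, 1]]):
        mine = fisher_exact(table).p_value
        ref = scipy.stats.fisher_exact(table).pvalue
        assert mine == pytest.approx(ref, rel=1e-9)


def test_fisher_modal_table_has_p_one():
    assert fisher_exact([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)


def test_fisher_invariant_to_permutation_and_transposition(rng):
    table = np.array([[3, 7, 2], [6, 1, 4], [2, 5, 5]])
    base = fisher_exact(table).p_value
    perm = rng.permutation(3)
    assert fisher_exact(table[perm]).p_value == pytest.approx(base, rel=1e-9)
    assert fisher_exact(table[:, perm]).p_value == pytest.approx(base, rel=1e-9)
    assert fisher_exact(table.T).p_value == pytest.approx(base, rel=1e-9)


def test_fisher_zero_margin_is_degenerate():
    res = fisher_exact([[0, 0], [3, 4]])
    assert res.p_value == 1.0
    assert "degenerate" in res.note


def test_fisher_monte_carlo_is_seeded_and_converges():
    table = [[4, 6], [7, 2], [3, 5]]
    exact = fisher_exact(table).p_value
    mc1 = fisher_exact(table, exact_cap_n=1, mc_replicates=200_000, seed=9)
    mc2 = fisher_exact(table, exact_cap_n=1, mc_replicates=200_000, seed=9)
    assert "Monte-Carlo" in mc1.method
    assert mc1.p_value == mc2.p_value  # reproducible
    assert mc1.mc_se is not None
    assert mc1.p_value == pytest.approx(exact, abs=4 * mc1.mc_se)
    # more replicates tighten the estimate
    mc_big = fisher_exact(table, exact_cap_n=1, mc_replicates=800_000, seed=9)
    assert abs(mc_big.p_value - exact) <= abs(mc1.p_value - exact) + 2 * mc1.mc_se


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


def test_chi_square_perfect_fit():
    res = chi_square([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_matches_hand_computed_statistic():
    table = np.array([[164, 51], [31, 26], [55, 23]])
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = ((table - expected) ** 2 / expected).sum()
    res = chi_square(table)
    assert res.statistic == pytest.approx(stat, rel=1e-12)
    assert res.df == 2
    assert res.p_value == pytest.approx(scipy.stats.chi2.sf(stat, 2), rel=1e-12)


def test_chi_square_2x2_equals_squared_two_proportion_z():
    a, b, c, d = 30, 20, 15, 35
    res = chi_square([[a, b], [c, d]])
    p1, p2 = a / (a + b), c / (c + d)
    p_pool = (a + c) / (a + b + c + d)
    z = (p1 - p2) / math.sqrt(p_pool * (1 - p_pool) * (1 / (a + b) + 1 / (c + d)))
    assert res.statistic == pytest.approx(z**2, rel=1e-9)


def test_chi_square_zero_expected_cell_advises_fisher():
    with pytest.raises(ValueError, match="fisher"):
        chi_square([[0, 0], [3, 4]])


def test_p_values_are_probabilities():
    with pytest.raises(ValueError):
        ExactResult(p_value=1.5, method="bad")
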