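"""Exact and asymptotic tests for the descriptive layer.

Three tests back the stratified descriptive tables:

* :func:`hwe_exact` — the exact Hardy-Weinberg equilibrium test,
  conditional on the observed allele counts.  The p-value sums the
  conditional probabilities of all heterozygote counts whose probability
  does not exceed that of the observed configuration (probability-mass
  two-sided ordering).
* :func:`fisher_exact` — the two-sided Fisher exact test for r x c
  contingency tables, by full enumeration of the margin-consistent
  tables when feasible and by seeded Monte-Carlo sampling (Patefield
  tables) otherwise.
* :func:`chi_square` — the Pearson chi-square test without continuity
  correction.

Two-sided p-values follow probability-mass ordering with a small
relative slack when comparing table probabilities, matching the
convention of the R ecosystem these analyses are usually run in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency, random_table

#: relative slack when comparing table probabilities for the two-sided sum
REL_SLACK = 1e-7


class GenotypeCounts(NamedTuple):
    """Genotype class counts for one biallelic SNP."""

    n_hom_wild: int
    n_het: int
    n_hom_variant: int


@dataclass(frozen=True)
class TestResult:
    """Outcome of a descriptive test."""

    p_value: float
    method: str
    statistic: float | None = None
    df: int | None = None
    note: str | None = None
    mc_se: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_het_distribution(counts) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns ``(het_counts, probabilities)`` over every heterozygote count
    with the parity of the minor-allele count.  This is the exact null
    distribution under random mating, conditional on the observed number
    of each allele.
    """
    n_aa, n_ab, n_bb = (int(v) for v in counts)
    n = n_aa + n_ab + n_bb
    minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hs = np.arange(minor % 2, minor + 1, 2)
    hom_minor = (minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = (
        hs * math.log(2)
        + gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(hom_major + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    return hs, probs


def hwe_exact(counts) -> TestResult:
    """Exact test of Hardy-Weinberg equilibrium for one SNP.

    ``counts`` is ``(n_hom_wild, n_het, n_hom_variant)``.  Conditions on
    the observed allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    A monomorphic sample (one allele absent) is compatible with any
    allele frequency and returns p = 1.
    """
    c = GenotypeCounts(*(int(v) for v in counts))
    if min(c) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = sum(c)
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    method = "exact HWE test (conditional on allele counts)"
    n_variant = 2 * c.n_hom_variant + c.n_het
    if n_variant == 0 or n_variant == 2 * n:
        return TestResult(p_value=1.0, method=method, note="monomorphic sample")
    hs, probs = hwe_het_distribution(c)
    p_obs = probs[np.searchsorted(hs, c.n_het)]
    p = float(probs[probs <= p_obs * (1 + REL_SLACK)].sum())
    return TestResult(p_value=min(p, 1.0), method=method)


# ---------------------------------------------------------------------------
# Fisher exact test for r x c tables
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("contingency table has negative cells")
    return t


def _drop_zero_margins(t: np.ndarray) -> tuple[np.ndarray, bool]:
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    dropped = not (rows.all() and cols.all())
    return t[np.ix_(rows, cols)], dropped


class _EnumerationOverflow(Exception):
    pass


def _enumerate_fisher(t: np.ndarray, max_tables: int) -> float:
    """Two-sided exact p by recursive enumeration over margin-consistent tables."""
    r, c = t.shape
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    logfact = gammaln(np.arange(n + 1) + 1.0)
    const = logfact[rows].sum() + logfact[cols].sum() - logfact[n]

    obs_logp = const - logfact[t].sum()
    cutoff = obs_logp + math.log1p(REL_SLACK)
    total = 0.0
    count = 0

    def rec(i: int, rem_cols: np.ndarray, acc: float):
        nonlocal total, count
        if i == r - 1:
            count += 1
            if count > max_tables:
                raise _EnumerationOverflow
            lp = const - acc - logfact[rem_cols].sum()
            if lp <= cutoff:
                total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def cells(j: int, rem_row: int, rc: np.ndarray, acc_row: float):
            if j == c - 1:
                if rem_row <= rc[j]:
                    rc2 = rc.copy()
                    rc2[j] -= rem_row
                    rec(i + 1, rc2, acc_row + logfact[rem_row])
                return
            hi = min(rem_row, rc[j])
            for v in range(hi + 1):
                rc2 = rc.copy()
                rc2[j] -= v
                cells(j + 1, rem_row - v, rc2, acc_row + logfact[v])

        cells(0, int(rows[i]), rem_cols, acc)

    rec(0, cols.copy(), 0.0)
    return min(total, 1.0)


def _monte_carlo_fisher(
    t: np.ndarray, replicates: int, seed: int
) -> tuple[float, float]:
    """Seeded Monte-Carlo two-sided p with add-one correction and its SE."""
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    logfact = gammaln(np.arange(n + 1) + 1.0)
    obs = -logfact[t].sum()  # log prob up to the margin constant
    cutoff = obs + math.log1p(REL_SLACK)
    dist = random_table(rows, cols)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    chunk = 100_000
    while done < replicates:
        m = min(chunk, replicates - done)
        tabs = dist.rvs(m, random_state=rng).astype(np.int64)
        lps = -logfact[tabs].sum(axis=(1, 2))
        hits += int((lps <= cutoff).sum())
        done += m
    p = (hits + 1) / (replicates + 1)
    mc_se = math.sqrt(p * (1 - p) / replicates)
    return p, mc_se


def fisher_exact(
    table,
    *,
    exact_cap_n: int = 500,
    exact_cap_dim: int = 4,
    max_tables: int = 2_000_000,
    mc_replicates: int = 1_000_000,
    seed: int = 0,
) -> TestResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    The p-value sums the multivariate hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    the observed table's (with relative slack ``1e-7``).  Enumeration is
    exact when the table is at most ``exact_cap_dim`` in each dimension,
    the total is at most ``exact_cap_n`` and the enumeration stays below
    ``max_tables`` tables; otherwise a seeded Monte-Carlo estimate over
    ``mc_replicates`` Patefield-sampled tables is returned together with
    its standard error.

    Rows or columns with a zero margin carry no information and are
    dropped; a table degenerate after dropping returns p = 1 with a note.
    """
    t = _as_table(table)
    t, dropped = _drop_zero_margins(t)
    note = "zero-margin rows/columns dropped" if dropped else None
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult(
            p_value=1.0,
            method="Fisher exact test (degenerate margins)",
            note="table degenerate after dropping zero margins",
        )
    n = int(t.sum())
    if max(t.shape) <= exact_cap_dim and n <= exact_cap_n:
        try:
            p = _enumerate_fisher(t, max_tables)
            return TestResult(
                p_value=p, method="Fisher exact test (full enumeration)", note=note
            )
        except _EnumerationOverflow:
            pass
    p, mc_se = _monte_carlo_fisher(t, mc_replicates, seed)
    return TestResult(
        p_value=min(p, 1.0),
        method=f"Fisher exact test (Monte-Carlo, {mc_replicates} replicates)",
        note=note,
        mc_se=mc_se,
    )


# ---------------------------------------------------------------------------
# Pearson chi-square
# ---------------------------------------------------------------------------

def chi_square(table) -> TestResult:
    """Pearson chi-square test without continuity correction.

    Requires every expected cell to be positive; degenerate tables raise
    with a pointer to :func:`fisher_exact`.
    """
    t = _as_table(table)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected <= 0).any():
        raise ValueError(
            "zero expected cell count; the chi-square approximation is invalid "
            "- use fisher_exact instead"
        )
    stat, p, df, _ = chi2_contingency(t, correction=False)
    return TestResult(
        p_value=float(p), method="Pearson chi-square test", statistic=float(stat), df=int(df)
    )


def chi_square_from_counts(observed, expected) -> TestResult:
    """Goodness-of-fit chi-square for pre-computed expected counts."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise ValueError("zero expected count")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return TestResult(
        p_value=float(chi2_dist.sf(stat, df)),
        method="chi-square goodness of fit",
        statistic=stat,
        df=df,
    )
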