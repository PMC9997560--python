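"""Partition tests for mutation counts.

Three procedures: Pearson chi-square homogeneity of two 6-class spectra
(2x6 table, df = 5), Pearson chi-square of per-replicon mutation counts
against site-proportional expectations (df = k - 1), and a two-sided
Fisher exact test comparing coding vs noncoding mutation rates.  No
continuity correction is applied anywhere — reproducing the replicon
statistic from small observed counts requires the uncorrected statistic.
The Fisher two-sided p-value uses the conventional minimum-likelihood
rule: the sum of probabilities of all tables (with the observed margins)
no more probable than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .generations import MALine
from .rates import RateEstimate


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def chisq_homogeneity(counts_a, counts_b) -> TestResult:
    """Pearson chi-square homogeneity test of two mutation-class spectra.

    ``counts_a`` and ``counts_b`` are same-length count vectors (length 6
    for the base-substitution spectrum); the test is Pearson's chi-square
    on the 2xk contingency table with df = k - 1 and no continuity
    correction.  Expected cells below 5 trigger a warning, not an error.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("expected two equal-length count vectors (length >= 2)")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    table = np.vstack([a, b])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("zero row total in contingency table")
    # Classes observed in neither spectrum have O = E = 0 and contribute
    # nothing to the statistic; df stays k - 1 for the k declared classes.
    keep = table.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("all column totals are zero")
    chi2, _, _, expected = stats.chi2_contingency(table[:, keep], correction=False)
    df = table.shape[1] - 1
    p = stats.chi2.sf(chi2, df)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    return TestResult(float(chi2), int(df), float(p), "chi-square homogeneity")


def chisq_proportional(observed, weights) -> TestResult:
    """Chi-square test of counts against weight-proportional expectations.

    Used to ask whether mutations are distributed across replicons in
    proportion to replicon size (or callable sites): expected_i =
    total x weight_i / sum(weights), Pearson chi-square, df = k - 1.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(weights, dtype=float)
    if obs.shape != w.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and weights must be equal-length vectors (>= 2)")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    if obs.sum() == 0:
        raise ValueError("observed total is zero")
    expected = obs.sum() * w / w.sum()
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return TestResult(float(chi2), len(obs) - 1, float(p), "chi-square proportional")


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the
    observed table (minimum-likelihood rule).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative entries in 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    odds, p = stats.fisher_exact(t.astype(np.int64), alternative="two-sided")
    return TestResult(float(odds), None, float(p), "Fisher exact (two-sided)")


def coding_noncoding_test(
    m_coding: int,
    m_noncoding: int,
    coding_sites: int,
    noncoding_sites: int,
    lines: list[MALine] | float | None = None,
    ci_level: float = 0.95,
) -> tuple[TestResult, RateEstimate | None, RateEstimate | None]:
    """Fisher exact comparison of coding vs noncoding mutation rates.

    Builds the 2x2 table ``[[m_coding, coding_sites - m_coding],
    [m_noncoding, noncoding_sites - m_noncoding]]``.  When ``lines`` is
    given (a list of :class:`MALine` or a plain line-generations total, sum
    over lines of total generations), per-site rate estimates with exact
    Poisson intervals are returned alongside the test.
    """
    if m_coding > coding_sites or m_noncoding > noncoding_sites:
        raise ValueError("mutation counts cannot exceed site counts")
    result = fisher_exact_2x2(
        [
            [m_coding, coding_sites - m_coding],
            [m_noncoding, noncoding_sites - m_noncoding],
        ]
    )
    rate_c = rate_n = None
    if lines is not None:
        line_gens = (
            sum(line.total_generations for line in lines)
            if isinstance(lines, list)
            else float(lines)
        )
        rate_c = RateEstimate(
            m=m_coding, denominator=coding_sites * line_gens, ci_level=ci_level
        )
        rate_n = RateEstimate(
            m=m_noncoding, denominator=noncoding_sites * line_gens, ci_level=ci_level
        )
    return result, rate_c, rate_n
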