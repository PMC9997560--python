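"""Mutation-rate estimation with exact Poisson confidence intervals.

All rates are per site per generation.  The denominator is the
site-generations total, sum over lines of callable sites x total
generations; conditional (per-class) rates scale it by the fraction of
sites at which the class can occur (G/C sites for G:C-origin classes, A/T
sites otherwise).  Confidence intervals are exact Garwood intervals on the
count scale,

    low  = chi2.ppf(alpha/2, 2m) / 2        (0 when m = 0)
    high = chi2.ppf(1 - alpha/2, 2m + 2) / 2

divided by the site-generations denominator.

Two standard errors are available for the overall rate: the among-line SE
(SD of per-line rates / sqrt(L)), which captures overdispersion across MA
lines, and the pooled-Poisson SE sqrt(m)/denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calling import (
    AT_TO_GC_CLASSES,
    BPS_CLASSES,
    GC_TO_AT_CLASSES,
    MutationCall,
    TRANSITION_CLASSES,
)
from .generations import MALine

logger = logging.getLogger(__name__)


def poisson_ci(m: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval on the count scale."""
    if m < 0:
        raise ValueError("count must be >= 0")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    alpha = 1.0 - ci_level
    low = 0.0 if m == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * m)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * m + 2)
    return float(low), float(high)


@dataclass
class RateEstimate:
    """A Poisson rate with exact CI: m events over a site-generations total."""

    m: int
    denominator: float
    rate: float = field(init=False)
    se: float | None = None  # among-line SE when per-line data are available
    se_poisson: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be > 0 site-generations")
        self.rate = self.m / self.denominator
        self.se_poisson = math.sqrt(self.m) / self.denominator
        lo, hi = poisson_ci(self.m, self.ci_level)
        self.ci_low = lo / self.denominator
        self.ci_high = hi / self.denominator


def site_generations(lines: list[MALine], fraction: float = 1.0) -> float:
    """Sum over lines of callable_sites x total_generations, times ``fraction``.

    ``fraction`` restricts the denominator to a class-eligible subset of
    sites (e.g. the genome's GC fraction for G:C-origin classes).
    """
    total = 0.0
    for line in lines:
        if line.callable_sites <= 0 or line.total_generations <= 0:
            raise ValueError(
                f"line {line.id!r} lacks callable_sites/total_generations"
            )
        total += line.callable_sites * line.total_generations
    return total * fraction


def overall_rate(
    m: int | dict[str, int],
    lines: list[MALine],
    ci_level: float = 0.95,
    fraction: float = 1.0,
) -> RateEstimate:
    """Overall mutation rate over all lines.

    ``m`` is either the total mutation count, or a per-line count mapping
    — in which case the among-line standard error (SD of per-line rates /
    sqrt(number of lines)) is attached to the estimate.
    """
    denom = site_generations(lines, fraction)
    if isinstance(m, dict):
        per_line = np.array(
            [
                m.get(line.id, 0) / (line.callable_sites * line.total_generations * fraction)
                for line in lines
            ]
        )
        total = int(sum(m.values()))
        est = RateEstimate(m=total, denominator=denom, ci_level=ci_level)
        if len(lines) > 1:
            est.se = float(per_line.std(ddof=1) / math.sqrt(len(lines)))
        return est
    return RateEstimate(m=int(m), denominator=denom, ci_level=ci_level)


def per_genome_rate(rate: float, genome_size: int) -> float:
    """Convert a per-site rate to a per-genome per-generation rate."""
    if rate < 0 or genome_size <= 0:
        raise ValueError("rate must be >= 0 and genome_size > 0")
    return rate * genome_size


def equilibrium_gc(mu_at_to_gc: float, mu_gc_to_at: float) -> float:
    """Expected GC content under mutation pressure alone.

    eq_GC = mu_AT->GC / (mu_AT->GC + mu_GC->AT); NaN if both rates are 0.
    """
    if mu_at_to_gc < 0 or mu_gc_to_at < 0:
        raise ValueError("directional rates must be >= 0")
    total = mu_at_to_gc + mu_gc_to_at
    if total == 0:
        return float("nan")
    return mu_at_to_gc / total


def equilibrium_gc_sem(
    m_at_to_gc: int,
    m_gc_to_at: int,
    denom_at: float,
    denom_gc: float,
) -> float:
    """Delta-method SEM of the equilibrium GC fraction from Poisson counts."""
    a = m_at_to_gc / denom_at
    b = m_gc_to_at / denom_gc
    total = a + b
    if total == 0:
        return float("nan")
    var_a = m_at_to_gc / denom_at**2
    var_b = m_gc_to_at / denom_gc**2
    return math.sqrt(b**2 * var_a + a**2 * var_b) / total**2


def ts_tv_ratio(calls: list[MutationCall]) -> tuple[float, int, int]:
    """Count-based transition:transversion ratio.

    Returns ``(ratio, n_ts, n_tv)``; the ratio is NaN (with a warning)
    when there are no transversions.
    """
    n_ts = sum(1 for c in calls if c.kind == "BPS" and c.ts_or_tv == "transition")
    n_tv = sum(1 for c in calls if c.kind == "BPS" and c.ts_or_tv == "transversion")
    if n_tv == 0:
        logger.warning("no transversions observed; Ts/Tv reported as NaN")
        return float("nan"), n_ts, n_tv
    return n_ts / n_tv, n_ts, n_tv


@dataclass
class SpectrumEstimate:
    """Conditional 6-class spectrum plus derived directional statistics."""

    classes: dict[str, RateEstimate]
    mu_gc_to_at: RateEstimate
    mu_at_to_gc: RateEstimate
    equilibrium_gc: float
    equilibrium_gc_sem: float
    ts_tv_count: float
    ts_tv_rate: float
    n_ts: int
    n_tv: int


def conditional_spectrum(
    calls: list[MutationCall],
    lines: list[MALine],
    gc_fraction: float,
    ci_level: float = 0.95,
) -> SpectrumEstimate:
    """Estimate the conditional base-substitution spectrum.

    Class denominators use ``gc_fraction`` of the site-generations total
    for G:C-origin classes and ``1 - gc_fraction`` for A:T-origin classes
    (base composition of the surveyed sites, or of the genome when
    per-site composition is unavailable).  Directional rates are the sums
    of the two class rates in each direction; the two conservative
    transversion classes contribute to neither direction.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    counts = {cls: 0 for cls in BPS_CLASSES}
    for c in calls:
        if c.kind == "BPS":
            counts[c.bps_class] += 1
    return spectrum_from_counts(counts, lines, gc_fraction, ci_level)


def spectrum_from_counts(
    counts: dict[str, int],
    lines: list[MALine],
    gc_fraction: float,
    ci_level: float = 0.95,
) -> SpectrumEstimate:
    """Spectrum estimate from pre-tabulated 6-class counts (see
    :func:`conditional_spectrum`)."""
    denom_all = site_generations(lines)
    denom = {
        cls: denom_all * (gc_fraction if cls.startswith("G:C") else 1 - gc_fraction)
        for cls in BPS_CLASSES
    }
    classes = {
        cls: RateEstimate(m=counts.get(cls, 0), denominator=denom[cls],
                          ci_level=ci_level)
        for cls in BPS_CLASSES
    }
    m_gc = sum(counts.get(cls, 0) for cls in GC_TO_AT_CLASSES)
    m_at = sum(counts.get(cls, 0) for cls in AT_TO_GC_CLASSES)
    denom_gc = denom_all * gc_fraction
    denom_at = denom_all * (1 - gc_fraction)
    mu_gc_to_at = RateEstimate(m=m_gc, denominator=denom_gc, ci_level=ci_level)
    mu_at_to_gc = RateEstimate(m=m_at, denominator=denom_at, ci_level=ci_level)
    eq = equilibrium_gc(mu_at_to_gc.rate, mu_gc_to_at.rate)
    sem = equilibrium_gc_sem(m_at, m_gc, denom_at, denom_gc)

    n_ts = sum(counts.get(cls, 0) for cls in TRANSITION_CLASSES)
    n_tv = sum(counts.values()) - n_ts
    ts_tv_count = n_ts / n_tv if n_tv else float("nan")
    ts_rate = sum(classes[cls].rate for cls in TRANSITION_CLASSES)
    tv_rate = sum(
        est.rate for cls, est in classes.items() if cls not in TRANSITION_CLASSES
    )
    ts_tv_rate = ts_rate / tv_rate if tv_rate else float("nan")
    return SpectrumEstimate(
        classes=classes,
        mu_gc_to_at=mu_gc_to_at,
        mu_at_to_gc=mu_at_to_gc,
        equilibrium_gc=eq,
        equilibrium_gc_sem=sem,
        ts_tv_count=ts_tv_count,
        ts_tv_rate=ts_tv_rate,
        n_ts=n_ts,
        n_tv=n_tv,
    )


def bootstrap_equilibrium_gc(
    calls: list[MutationCall],
    lines: list[MALine],
    gc_fraction: float,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap-over-lines standard error of the equilibrium GC fraction."""
    rng = np.random.default_rng(seed)
    line_ids = [line.id for line in lines]
    by_line: dict[str, list[MutationCall]] = {lid: [] for lid in line_ids}
    for c in calls:
        if c.kind == "BPS" and c.line_id in by_line:
            by_line[c.line_id].append(c)
    lines_by_id = {line.id: line for line in lines}
    estimates = []
    for _ in range(n_boot):
        pick = rng.choice(line_ids, size=len(line_ids), replace=True)
        boot_calls = [c for lid in pick for c in by_line[lid]]
        boot_lines = [lines_by_id[lid] for lid in pick]
        # resampled lines keep their own denominators; duplicate ids are fine
        spec = conditional_spectrum(boot_calls, boot_lines, gc_fraction)
        if not math.isnan(spec.equilibrium_gc):
            estimates.append(spec.equilibrium_gc)
    return float(np.std(estimates, ddof=1)) if len(estimates) > 1 else float("nan")
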