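"""Summary-table report: the study's headline statistics as one JSON dict.

Mirrors the fields a mutation-accumulation study tabulates — sites
surveyed, generations, mutation counts, Ts/Tv, coding/noncoding split,
overall base-substitution and indel rates — plus the conditional spectrum
(per-class rates with exact Poisson CIs), directional rates, equilibrium
GC content and the partition tests.
"""

from __future__ import annotations

import math
from typing import Any

from .calling import BPS_CLASSES, CallingResult, MutationCall
from .generations import MALine
from .genome import GenomeModel
from .rates import (
    SpectrumEstimate,
    overall_rate,
    per_genome_rate,
    site_generations,
    spectrum_from_counts,
)
from .stattests import chisq_proportional, coding_noncoding_test


def _rate_dict(est) -> dict[str, float]:
    out = {
        "m": est.m,
        "denominator": est.denominator,
        "rate": est.rate,
        "se_poisson": est.se_poisson,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "ci_level": est.ci_level,
    }
    if est.se is not None:
        out["se_among_lines"] = est.se
    return out


def _spectrum_dict(spec: SpectrumEstimate) -> dict[str, Any]:
    return {
        "classes": {cls: _rate_dict(spec.classes[cls]) for cls in BPS_CLASSES},
        "mu_gc_to_at": _rate_dict(spec.mu_gc_to_at),
        "mu_at_to_gc": _rate_dict(spec.mu_at_to_gc),
        "equilibrium_gc": spec.equilibrium_gc,
        "equilibrium_gc_percent": 100 * spec.equilibrium_gc,
        "equilibrium_gc_sem": spec.equilibrium_gc_sem,
        "ts_tv_count_based": spec.ts_tv_count,
        "ts_tv_rate_based": spec.ts_tv_rate,
        "n_transitions": spec.n_ts,
        "n_transversions": spec.n_tv,
    }


def uniform_lines(n_lines: int, sites: int, generations: float) -> list[MALine]:
    """Identical MALine records, for summary-level inputs (no per-line data)."""
    return [
        MALine(
            id=f"L{i:03d}", n_transfers=1.0,
            generations_per_transfer=generations,
            total_generations=generations, callable_sites=sites,
        )
        for i in range(1, n_lines + 1)
    ]


def report_from_summary(
    n_bps: int,
    n_indels: int,
    n_lines: int,
    sites_surveyed: int,
    mean_generations: float,
    genome_size: int,
    gc_fraction: float,
    class_counts: dict[str, int] | None = None,
    directional_counts: tuple[int, int] | None = None,
    replicon_counts: list[int] | None = None,
    replicon_weights: list[float] | None = None,
    n_coding: int | None = None,
    n_noncoding: int | None = None,
    coding_sites: int | None = None,
    noncoding_sites: int | None = None,
    ci_level: float = 0.95,
) -> dict[str, Any]:
    """Build the summary report from tabulated inputs.

    This is the entry point for reproducing a published summary table:
    every statistic is recomputed from the given counts and denominators.
    ``directional_counts`` is ``(m_gc_to_at, m_at_to_gc)`` and may be given
    instead of the full 6-class breakdown; class counts, when provided,
    take precedence.
    """
    lines = uniform_lines(n_lines, sites_surveyed, mean_generations)
    denom = site_generations(lines)
    bps = overall_rate(n_bps, lines, ci_level=ci_level)
    indel = overall_rate(n_indels, lines, ci_level=ci_level)
    report: dict[str, Any] = {
        "n_lines": n_lines,
        "sites_surveyed": sites_surveyed,
        "mean_generations": mean_generations,
        "genome_size": genome_size,
        "gc_fraction": gc_fraction,
        "site_generations": denom,
        "n_base_substitutions": n_bps,
        "n_indels": n_indels,
        "overall_bps_rate": _rate_dict(bps),
        "per_genome_bps_rate": per_genome_rate(bps.rate, genome_size),
        "overall_indel_rate": _rate_dict(indel),
        "per_genome_indel_rate": per_genome_rate(indel.rate, genome_size),
    }

    if class_counts is None and directional_counts is not None:
        # distribute the directional totals over their transition class;
        # only the directional sums and equilibrium GC are then meaningful
        m_gc, m_at = directional_counts
        class_counts = {cls: 0 for cls in BPS_CLASSES}
        class_counts["G:C->A:T"] = m_gc
        class_counts["A:T->G:C"] = m_at
    if class_counts is not None:
        spec = spectrum_from_counts(class_counts, lines, gc_fraction, ci_level)
        report["spectrum"] = _spectrum_dict(spec)

    if replicon_counts is not None and replicon_weights is not None:
        res = chisq_proportional(replicon_counts, replicon_weights)
        report["replicon_test"] = {
            "observed": list(replicon_counts),
            "weights": list(replicon_weights),
            "chi2": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
        }

    if None not in (n_coding, n_noncoding, coding_sites, noncoding_sites):
        line_gens = sum(l.total_generations for l in lines)
        test, rate_c, rate_n = coding_noncoding_test(
            n_coding, n_noncoding, coding_sites, noncoding_sites,
            lines=line_gens, ci_level=ci_level,
        )
        report["coding_noncoding"] = {
            "n_coding": n_coding,
            "n_noncoding": n_noncoding,
            "coding_sites": coding_sites,
            "noncoding_sites": noncoding_sites,
            "coding_rate": _rate_dict(rate_c),
            "noncoding_rate": _rate_dict(rate_n),
            "fisher_p": test.p_value,
        }
    return report


def report_from_calls(
    result: CallingResult,
    lines: list[MALine],
    genome: GenomeModel,
    coding_sites: int | None = None,
    ci_level: float = 0.95,
) -> dict[str, Any]:
    """Build the summary report from a calling result and line metadata.

    ``lines`` must carry callable_sites (usually copied from ``result``)
    and total_generations.  The "sites surveyed" headline is the per-line
    mean; the intersection and union across lines are reported alongside.
    """
    calls = result.calls
    bps_calls = [c for c in calls if c.kind == "BPS"]
    indel_calls = [c for c in calls if c.kind != "BPS"]
    per_line_bps: dict[str, int] = {line.id: 0 for line in lines}
    for c in bps_calls:
        per_line_bps[c.line_id] = per_line_bps.get(c.line_id, 0) + 1

    gc = genome.gc_fraction
    bps = overall_rate(per_line_bps, lines, ci_level=ci_level)
    indel = overall_rate(len(indel_calls), lines, ci_level=ci_level)
    class_counts = {cls: 0 for cls in BPS_CLASSES}
    for c in bps_calls:
        class_counts[c.bps_class] += 1
    spec = spectrum_from_counts(class_counts, lines, gc, ci_level)

    report: dict[str, Any] = {
        "n_lines": len(lines),
        "sites_surveyed": result.callable_mean,
        "sites_surveyed_intersection": result.callable_intersection,
        "sites_surveyed_union": result.callable_union,
        "mean_generations": (
            sum(l.total_generations for l in lines) / len(lines)
        ),
        "genome_size": genome.total_size,
        "gc_fraction": gc,
        "site_generations": site_generations(lines),
        "n_base_substitutions": len(bps_calls),
        "n_indels": len(indel_calls),
        "n_insertions": sum(1 for c in indel_calls if c.kind == "insertion"),
        "n_deletions": sum(1 for c in indel_calls if c.kind == "deletion"),
        "n_excluded_sites": len(result.excluded),
        "overall_bps_rate": _rate_dict(bps),
        "per_genome_bps_rate": per_genome_rate(bps.rate, genome.total_size),
        "overall_indel_rate": _rate_dict(indel),
        "per_genome_indel_rate": per_genome_rate(indel.rate, genome.total_size),
        "spectrum": _spectrum_dict(spec),
    }

    # replicon partition vs replicon lengths
    rep_counts = [
        sum(1 for c in bps_calls if c.replicon == rep.id) for rep in genome
    ]
    if sum(rep_counts) > 0 and len(genome) >= 2:
        res = chisq_proportional(rep_counts, [rep.length for rep in genome])
        report["replicon_test"] = {
            "observed": rep_counts,
            "weights": [rep.length for rep in genome],
            "chi2": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
        }

    contexts = {c.context for c in bps_calls}
    if coding_sites is not None and contexts <= {"coding", "noncoding"} and contexts:
        n_coding = sum(1 for c in bps_calls if c.context == "coding")
        n_noncoding = len(bps_calls) - n_coding
        noncoding_sites = genome.total_size - coding_sites
        line_gens = sum(l.total_generations for l in lines)
        test, rate_c, rate_n = coding_noncoding_test(
            n_coding, n_noncoding, coding_sites, noncoding_sites,
            lines=line_gens, ci_level=ci_level,
        )
        report["coding_noncoding"] = {
            "n_coding": n_coding,
            "n_noncoding": n_noncoding,
            "coding_sites": coding_sites,
            "noncoding_sites": noncoding_sites,
            "coding_fraction": n_coding / len(bps_calls) if bps_calls else math.nan,
            "coding_rate": _rate_dict(rate_c),
            "noncoding_rate": _rate_dict(rate_n),
            "fisher_p": test.p_value,
        }
    return report
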