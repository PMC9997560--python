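"""Consensus-based mutation calling across mutation-accumulation lines.

The caller's sole input is a per-line, per-site read summary (allele read
counts).  A line-specific consensus allele is called at a site when depth
and consensus-fraction thresholds are met (defaults: >=10 reads and >=99%
of reads, the ~1% slack absorbing aberrant reads from sequencing error or
index contamination).  Because all MA lines descend from a single
progenitor colony, the ancestral allele at a site is inferred as the
*unanimous* consensus of the non-focal lines; a focal consensus that
differs from it is a mutation.  Sites where two or more lines share the
same non-ancestral allele are excluded as suspected progenitor
polymorphisms or mapping artifacts — independent recurrence at one site is
vanishingly unlikely at rates of ~1e-10 per site per generation.

Indel alleles are text-encoded at their VCF-style anchor base (the base
before the event): ``+SEQ`` inserts SEQ after the anchor, ``-SEQ`` deletes
SEQ following the anchor.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .genome import BASES, GenomeModel

logger = logging.getLogger(__name__)

NO_CALL = "NO_CALL"
UNRESOLVED = "UNRESOLVED"

#: Consensus code for "supported allele is the indel allele".
INDEL_CODE = 4

#: The six strand-collapsed base-substitution classes.
BPS_CLASSES = (
    "A:T->G:C",
    "A:T->C:G",
    "A:T->T:A",
    "G:C->A:T",
    "G:C->T:A",
    "G:C->C:G",
)

#: Directional unions: classes moving composition toward AT or toward GC.
#: The two conservative transversion classes belong to neither direction.
GC_TO_AT_CLASSES = ("G:C->A:T", "G:C->T:A")
AT_TO_GC_CLASSES = ("A:T->G:C", "A:T->C:G")
TRANSITION_CLASSES = ("G:C->A:T", "A:T->G:C")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

def _collapse_class(ref: str, alt: str) -> str:
    """Strand-collapsed class label, pivot base (A or G) on the left."""
    if ref in "GC":
        oriented = alt if ref == "G" else _COMPLEMENT[alt]
        return f"G:C->{oriented}:{_COMPLEMENT[oriented]}"
    oriented = alt if ref == "A" else _COMPLEMENT[alt]
    return f"A:T->{oriented}:{_COMPLEMENT[oriented]}"


_PURINES = {"A", "G"}


def classify_bps(ref: str, alt: str) -> tuple[str, str, str]:
    """Classify a base substitution.

    Returns ``(bps_class, direction, ts_or_tv)`` where ``bps_class`` is one
    of the six strand-collapsed classes, ``direction`` is ``GC->AT``,
    ``AT->GC``, ``GC-conservative`` or ``AT-conservative``, and ``ts_or_tv``
    is ``transition`` or ``transversion``.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ref/alt must be single A/C/G/T bases, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    cls = _collapse_class(ref, alt)
    if cls in GC_TO_AT_CLASSES:
        direction = "GC->AT"
    elif cls in AT_TO_GC_CLASSES:
        direction = "AT->GC"
    elif cls == "G:C->C:G":
        direction = "GC-conservative"
    else:
        direction = "AT-conservative"
    ts_or_tv = (
        "transition"
        if (ref in _PURINES) == (alt in _PURINES)
        else "transversion"
    )
    return cls, direction, ts_or_tv


@dataclass
class SiteReadSummary:
    """Allele read counts for one line at one genomic site."""

    line_id: str
    replicon: str
    pos: int  # 1-based
    ref: str
    nA: int
    nC: int
    nG: int
    nT: int
    indel_allele: str | None = None
    n_indel: int = 0

    @property
    def depth(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.n_indel

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.nA, self.nC, self.nG, self.nT], dtype=np.int64)


@dataclass
class ConsensusCall:
    """Line-specific consensus at a site (NO_CALL is a value, not an error)."""

    line_id: str
    replicon: str
    pos: int
    allele: str  # base, indel allele text, or NO_CALL
    fraction: float


@dataclass
class MutationCall:
    """One called mutation: a focal-line departure from the ancestral allele."""

    line_id: str
    replicon: str
    pos: int  # anchor position for indels
    ref: str  # ancestral allele (anchored form for indels)
    alt: str
    kind: str  # "BPS" | "insertion" | "deletion"
    indel_length: int = 0
    bps_class: str | None = None
    direction: str | None = None
    ts_or_tv: str | None = None
    context: str | None = None  # "coding" | "noncoding"

    def __post_init__(self) -> None:
        if self.kind == "BPS":
            if not (len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt):
                raise ValueError(f"BPS requires single distinct bases: {self}")
            if self.bps_class is None:
                self.bps_class, self.direction, self.ts_or_tv = classify_bps(
                    self.ref, self.alt
                )
        else:
            self.indel_length = abs(len(self.ref) - len(self.alt))


@dataclass
class SiteBlock:
    """Compact per-(line, replicon) site summary: the array twin of the TSV.

    ``pos`` (1-based, ascending), ``counts`` of shape (n, 4) in A/C/G/T
    order, ``n_indel`` reads supporting the indel allele and, where
    ``n_indel > 0``, the allele text in ``indel_alleles[pos]``.
    """

    pos: np.ndarray
    counts: np.ndarray
    n_indel: np.ndarray
    indel_alleles: dict[int, str] = field(default_factory=dict)


def consensus_codes(
    counts: np.ndarray,
    n_indel: np.ndarray,
    min_depth: int,
    consensus_fraction: float,
) -> np.ndarray:
    """Vectorized consensus over sites: 0..3 base, 4 indel, -1 NO_CALL.

    A site is called when depth >= min_depth and the top allele holds a
    fraction >= consensus_fraction of all reads; ties give NO_CALL.  The
    fraction comparison carries a 1e-9 relative guard so that exact
    boundary cases (e.g. 198/200 at 0.99) are not lost to float rounding.

    With consensus_fraction > 0.5 (enforced) a tied top allele can hold at
    most half the reads and always fails the fraction test, so no explicit
    tie check is needed.
    """
    if not 0.5 < consensus_fraction <= 1:
        raise ValueError("consensus_fraction must be in (0.5, 1]")
    depth = counts.sum(axis=1) + n_indel
    best = counts.argmax(axis=1)
    n_best = counts.max(axis=1)
    is_indel = n_indel > n_best
    n_best = np.maximum(n_best, n_indel)
    ok = (
        (depth >= max(min_depth, 1))
        & (n_best + 1e-9 * depth >= consensus_fraction * depth)
    )
    code = np.where(is_indel, INDEL_CODE, best)
    return np.where(ok, code, -1).astype(np.int8)


def call_consensus(
    summary: SiteReadSummary,
    min_depth: int = 10,
    consensus_fraction: float = 0.99,
) -> ConsensusCall:
    """Scalar consensus call for one site summary."""
    code = consensus_codes(
        summary.counts[None, :],
        np.array([summary.n_indel]),
        min_depth,
        consensus_fraction,
    )[0]
    depth = summary.depth
    if code < 0:
        return ConsensusCall(summary.line_id, summary.replicon, summary.pos, NO_CALL, 0.0)
    if code == INDEL_CODE:
        allele = summary.indel_allele or ""
        n = summary.n_indel
    else:
        allele = BASES[code]
        n = int(summary.counts[code])
    return ConsensusCall(
        summary.line_id, summary.replicon, summary.pos, allele, n / depth
    )


def infer_ancestral(
    calls: Mapping[str, str | None],
    focal_line: str,
    min_other_lines: int = 3,
) -> str:
    """Infer the progenitor allele at one site from non-focal line calls.

    ``calls`` maps line id -> consensus allele (``None``/``NO_CALL`` for
    uncalled lines).  The ancestral allele is the unanimous allele of the
    called non-focal lines; any disagreement, or fewer than
    ``min_other_lines`` called non-focal lines, yields ``UNRESOLVED``.
    """
    others = {
        allele
        for line, allele in calls.items()
        if line != focal_line and allele is not None and allele != NO_CALL
    }
    n_called = sum(
        1
        for line, allele in calls.items()
        if line != focal_line and allele is not None and allele != NO_CALL
    )
    if n_called < min_other_lines or len(others) != 1:
        return UNRESOLVED
    return next(iter(others))


@dataclass
class ExcludedSite:
    """A site excluded because >=2 lines share the same non-ancestral allele."""

    replicon: str
    pos: int
    allele: str
    n_lines: int


@dataclass
class CallingResult:
    calls: list[MutationCall]
    callable_sites: dict[str, int]
    excluded: list[ExcludedSite]
    callable_intersection: int = 0
    callable_union: int = 0

    @property
    def callable_mean(self) -> float:
        return float(np.mean(list(self.callable_sites.values())))


def _frame_to_blocks(frame: pd.DataFrame) -> dict[str, SiteBlock]:
    """Split one line's site-summary DataFrame into per-replicon SiteBlocks."""
    blocks: dict[str, SiteBlock] = {}
    for rep, grp in frame.groupby("replicon", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        grp = grp.iloc[order]
        pos = pos[order]
        counts = grp[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int32)
        n_indel = grp["n_indel"].to_numpy(dtype=np.int32)
        alleles: dict[int, str] = {}
        if (n_indel > 0).any():
            sub = grp.loc[grp["n_indel"] > 0, ["pos", "indel_allele"]]
            alleles = dict(zip(sub["pos"].astype(int), sub["indel_allele"]))
        blocks[str(rep)] = SiteBlock(pos, counts, n_indel, alleles)
    return blocks


def _make_call(
    line_id: str,
    replicon: str,
    pos: int,
    ancestral: str,
    focal: str,
) -> MutationCall | None:
    """Build a MutationCall from ancestral and focal alleles at a site."""
    if len(ancestral) == 1 and len(focal) == 1:
        return MutationCall(line_id, replicon, pos, ancestral, focal, "BPS")
    if len(ancestral) == 1 and focal[:1] in "+-":
        seq = focal[1:]
        if focal[0] == "+":
            return MutationCall(
                line_id, replicon, pos, ancestral, ancestral + seq, "insertion"
            )
        return MutationCall(
            line_id, replicon, pos, ancestral + seq, ancestral, "deletion"
        )
    # Ancestral indel vs focal base (or two distinct indel alleles): a
    # reversion-like event the MA design does not produce; skip with a log.
    logger.warning(
        "unsupported allele pair at %s:%d in line %s (ancestral=%r focal=%r); skipped",
        replicon, pos, line_id, ancestral, focal,
    )
    return None


def call_mutations(
    summaries: Mapping[str, pd.DataFrame | dict[str, SiteBlock]]
    | Iterable[tuple[str, pd.DataFrame | dict[str, SiteBlock]]],
    genome: GenomeModel,
    min_depth: int = 10,
    consensus_fraction: float = 0.99,
    min_other_lines: int = 3,
    annotation: AnnotationSet | None = None,
) -> CallingResult:
    """Call mutations across all MA lines from per-line site summaries.

    ``summaries`` maps line id to either a site-summary DataFrame (columns
    ``line_id, replicon, pos, ref, nA, nC, nG, nT, indel_allele, n_indel``)
    or a pre-split ``{replicon: SiteBlock}`` dict.  Returns the mutation
    calls, per-line callable-site counts (sites with a focal consensus call
    *and* a resolved ancestral allele), and the excluded-site log.
    """
    items = summaries.items() if isinstance(summaries, Mapping) else summaries

    line_ids: list[str] = []
    # per replicon: list of (line_index, positions0, codes) to fill matrices
    per_rep_codes: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {
        rep.id: [] for rep in genome
    }
    indel_alleles: dict[tuple[int, str], dict[int, str]] = {}

    n_sites_in = 0
    for line_id, data in items:
        i = len(line_ids)
        line_ids.append(line_id)
        blocks = data if isinstance(data, dict) else _frame_to_blocks(data)
        for rep_id, blk in blocks.items():
            if rep_id not in per_rep_codes:
                raise KeyError(f"site summary references unknown replicon {rep_id!r}")
            codes = consensus_codes(blk.counts, blk.n_indel, min_depth, consensus_fraction)
            per_rep_codes[rep_id].append((i, blk.pos - 1, codes))
            if blk.indel_alleles:
                indel_alleles[(i, rep_id)] = blk.indel_alleles
            n_sites_in += len(blk.pos)

    n_lines = len(line_ids)
    callable_sites = np.zeros(n_lines, dtype=np.int64)
    calls: list[MutationCall] = []
    excluded: list[ExcludedSite] = []
    inter_total = 0
    union_total = 0

    for rep in genome:
        entries = per_rep_codes[rep.id]
        L = rep.length
        M = np.full((n_lines, L), -1, dtype=np.int8)
        for i, pos0, codes in entries:
            M[i, pos0] = codes
        counts5 = np.stack(
            [(M == k).sum(axis=0, dtype=np.int32) for k in range(5)]
        )
        called = counts5.sum(axis=0)
        n_maj = counts5.max(axis=0)
        maj = counts5.argmax(axis=0)
        n_other = called - n_maj

        has_indel = counts5[INDEL_CODE] > 0
        resolved_unanimous = (
            (n_other == 0) & (called >= min_other_lines + 1) & ~has_indel
        )
        candidate = (n_other == 1) & (called - 1 >= min_other_lines)
        multi = n_other >= 2
        exact_cols = np.nonzero(
            candidate | multi | (has_indel & (called > 0))
        )[0]
        # Restrict the bulk path to sites not revisited by the exact path.
        bulk = resolved_unanimous.copy()
        bulk[exact_cols] = False

        inter_mask = np.ones(L, dtype=bool)
        union_mask = np.zeros(L, dtype=bool)
        for i in range(n_lines):
            line_callable = (M[i] >= 0) & bulk
            callable_sites[i] += int(line_callable.sum())
            inter_mask &= line_callable
            union_mask |= line_callable

        # Exact (per-site) path for candidate / shared-allele / indel sites.
        for col in exact_cols:
            site_alleles: dict[str, str] = {}
            for i in range(n_lines):
                c = M[i, col]
                if c < 0:
                    continue
                if c == INDEL_CODE:
                    site_alleles[line_ids[i]] = indel_alleles.get((i, rep.id), {}).get(
                        int(col) + 1, "+?"
                    )
                else:
                    site_alleles[line_ids[i]] = BASES[c]
            # shared non-ancestral allele check (against the majority allele)
            tally = Counter(site_alleles.values())
            if len(tally) > 1:
                maj_allele, _ = tally.most_common(1)[0]
                for allele, n in tally.items():
                    if allele != maj_allele and n >= 2:
                        excluded.append(
                            ExcludedSite(rep.id, int(col) + 1, allele, n)
                        )
                        logger.info(
                            "excluded %s:%d — allele %r shared by %d lines "
                            "(suspected progenitor polymorphism/artifact)",
                            rep.id, int(col) + 1, allele, n,
                        )
            for idx, line_id in enumerate(line_ids):
                focal = site_alleles.get(line_id)
                if focal is None:
                    continue
                ancestral = infer_ancestral(site_alleles, line_id, min_other_lines)
                if ancestral == UNRESOLVED:
                    continue
                callable_sites[idx] += 1
                if focal != ancestral:
                    call = _make_call(
                        line_id, rep.id, int(col) + 1, ancestral, focal
                    )
                    if call is not None:
                        calls.append(call)
        # intersection/union tallies come from the bulk path; exact-path
        # sites (mutations, indels, exclusions) are a negligible correction
        inter_total += int(inter_mask.sum())
        union_total += int(union_mask.sum())

    if annotation is not None:
        calls = [annotate_context(c, annotation) for c in calls]

    logger.info(
        "calling: %d site summaries in, %d lines, %d mutation calls, "
        "%d excluded sites, mean callable sites %.0f "
        "(min_depth=%d consensus_fraction=%g min_other_lines=%d)",
        n_sites_in, n_lines, len(calls), len(excluded),
        float(callable_sites.mean()) if n_lines else 0.0,
        min_depth, consensus_fraction, min_other_lines,
    )
    return CallingResult(
        calls=sorted(calls, key=lambda c: (c.replicon, c.pos, c.line_id)),
        callable_sites=dict(zip(line_ids, callable_sites.tolist())),
        excluded=excluded,
        callable_intersection=inter_total,
        callable_union=union_total,
    )


def annotate_context(call: MutationCall, annotation: AnnotationSet) -> MutationCall:
    """Set coding/noncoding context from CDS intervals (anchor pos for indels)."""
    call.context = (
        "coding" if annotation.is_coding(call.replicon, call.pos) else "noncoding"
    )
    return call
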