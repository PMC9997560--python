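"""Readers and writers for the pipeline's external formats.

Formats: FASTA genome (see :mod:`.genome`), GFF3 annotation (see
:mod:`.annotation`), site-summary TSV (the pipeline's contract with the
upstream alignment layer), CFU TSV, calls TSV, VCF 4.2 output, YAML run
configuration, and JSON reports.

The site-summary TSV is a per-line, per-site table of allele read counts:

    line_id  replicon  pos  ref  nA  nC  nG  nT  indel_allele  n_indel

with 1-based positions, ``indel_allele`` either ``.`` or an anchored
``+SEQ``/``-SEQ`` allele, and a mandatory header row.  A converter from a
samtools-style pileup would populate exactly these columns (counting only
reads passing the upstream mapping filters); whether candidate sites are
every covered position or only variant-caller-emitted positions is a
choice the upstream layer makes — this package consumes whatever set of
rows it is given and treats missing rows as uncovered sites.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam
import yaml

from .calling import BASES, MutationCall, SiteReadSummary
from .genome import GenomeModel

logger = logging.getLogger(__name__)

SITE_SUMMARY_COLUMNS = [
    "line_id", "replicon", "pos", "ref",
    "nA", "nC", "nG", "nT", "indel_allele", "n_indel",
]

CFU_COLUMNS = ["line_id", "transfer_index", "cfu"]

CALLS_COLUMNS = [
    "line_id", "replicon", "pos", "ref", "alt", "kind", "indel_length",
    "bps_class", "direction", "ts_or_tv", "context",
]


@dataclass
class RunConfig:
    """Structured run configuration with the standard study thresholds."""

    min_depth: int = 10
    consensus_fraction: float = 0.99
    min_other_lines: int = 3
    ci_level: float = 0.95
    genome_path: str | None = None
    annotation_path: str | None = None
    site_summary_paths: dict[str, str] = field(default_factory=dict)
    cfu_path: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0.5, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


def _parse_summary_row(
    fields: list[str], lineno: int, genome: GenomeModel | None
) -> SiteReadSummary:
    if len(fields) != len(SITE_SUMMARY_COLUMNS):
        raise ValueError(
            f"line {lineno}: expected {len(SITE_SUMMARY_COLUMNS)} columns, "
            f"got {len(fields)}"
        )
    try:
        pos = int(fields[2])
        counts = [int(x) for x in fields[4:8]]
        n_indel = int(fields[9])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
    if pos < 1:
        raise ValueError(f"line {lineno}: pos must be >= 1 (1-based), got {pos}")
    if min(counts) < 0 or n_indel < 0:
        raise ValueError(f"line {lineno}: negative read count")
    replicon = fields[1]
    if genome is not None:
        if replicon not in genome:
            raise ValueError(f"line {lineno}: unknown replicon {replicon!r}")
        if pos > genome[replicon].length:
            raise ValueError(
                f"line {lineno}: pos {pos} outside replicon {replicon!r} "
                f"(length {genome[replicon].length})"
            )
    indel_allele = None if fields[8] in (".", "") else fields[8]
    return SiteReadSummary(
        line_id=fields[0], replicon=replicon, pos=pos, ref=fields[3],
        nA=counts[0], nC=counts[1], nG=counts[2], nT=counts[3],
        indel_allele=indel_allele, n_indel=n_indel,
    )


def read_site_summaries(
    path: str | Path, genome: GenomeModel | None = None
) -> Iterator[SiteReadSummary]:
    """Stream :class:`SiteReadSummary` records from a site-summary TSV.

    Malformed rows raise with their line number; positions outside the
    (optional) genome's replicons are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_SUMMARY_COLUMNS:
            raise ValueError(
                f"{path}: bad header; expected {SITE_SUMMARY_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            yield _parse_summary_row(line.split("\t"), lineno, genome)


def read_site_summary_table(
    path: str | Path, genome: GenomeModel | None = None
) -> pd.DataFrame:
    """Read a site-summary TSV into a validated DataFrame."""
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"line_id": str, "replicon": str, "ref": str, "indel_allele": str},
    )
    if list(frame.columns) != SITE_SUMMARY_COLUMNS:
        raise ValueError(
            f"{path}: bad columns; expected {SITE_SUMMARY_COLUMNS}, "
            f"got {list(frame.columns)}"
        )
    if (frame["pos"] < 1).any():
        bad = frame.index[frame["pos"] < 1][0] + 2
        raise ValueError(f"{path}: line {bad}: pos must be >= 1 (1-based)")
    if genome is not None:
        for rep_id, grp in frame.groupby("replicon"):
            if rep_id not in genome:
                raise ValueError(f"{path}: unknown replicon {rep_id!r}")
            if (grp["pos"] > genome[rep_id].length).any():
                raise ValueError(f"{path}: pos outside replicon {rep_id!r}")
    frame["indel_allele"] = frame["indel_allele"].fillna(".")
    logger.info("read %d site summaries from %s", len(frame), path)
    return frame


def write_site_summary_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=SITE_SUMMARY_COLUMNS)


def read_cfu_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    if list(frame.columns) != CFU_COLUMNS:
        raise ValueError(f"{path}: expected columns {CFU_COLUMNS}")
    if (frame["cfu"] < 1).any():
        raise ValueError(f"{path}: CFU counts must be >= 1")
    return frame


def write_cfu_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=CFU_COLUMNS)


def write_calls_table(calls: list[MutationCall], path: str | Path) -> None:
    rows = [
        {
            "line_id": c.line_id, "replicon": c.replicon, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "kind": c.kind,
            "indel_length": c.indel_length,
            "bps_class": c.bps_class or ".",
            "direction": c.direction or ".",
            "ts_or_tv": c.ts_or_tv or ".",
            "context": c.context or ".",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> list[MutationCall]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    calls = []
    for row in frame.itertuples(index=False):
        calls.append(
            MutationCall(
                line_id=row.line_id, replicon=row.replicon, pos=int(row.pos),
                ref=row.ref, alt=row.alt, kind=row.kind,
                indel_length=int(row.indel_length),
                bps_class=None if row.bps_class == "." else row.bps_class,
                direction=None if row.direction == "." else row.direction,
                ts_or_tv=None if row.ts_or_tv == "." else row.ts_or_tv,
                context=None if row.context == "." else row.context,
            )
        )
    return calls


def write_mutations_vcf(
    calls: list[MutationCall], genome: GenomeModel, path: str | Path
) -> None:
    """Write mutation calls as VCF 4.2, one record per call.

    The MA line carrying each mutation goes in the ``LINE`` INFO field;
    indels are written left-anchored (ref/alt share their first base), the
    representation calls already carry.
    """
    header = pysam.VariantHeader()
    for rep in genome:
        header.contigs.add(rep.id, length=rep.length)
    header.info.add("LINE", 1, "String", "MA line carrying the mutation")
    header.info.add("KIND", 1, "String", "BPS, insertion or deletion")
    header.info.add("BPSCLASS", 1, "String", "Strand-collapsed substitution class")
    header.info.add("CONTEXT", 1, "String", "coding or noncoding")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.replicon, c.pos, c.line_id)):
            if call.replicon not in genome:
                raise KeyError(f"call references unknown replicon {call.replicon!r}")
            rec = vcf.new_record(
                contig=call.replicon,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            rec.info["LINE"] = call.line_id
            rec.info["KIND"] = call.kind
            if call.bps_class:
                rec.info["BPSCLASS"] = call.bps_class
            if call.context:
                rec.info["CONTEXT"] = call.context
            vcf.write(rec)
    logger.info("wrote %d calls to %s", len(calls), path)


def read_mutations_vcf(path: str | Path) -> list[MutationCall]:
    """Read back a calls VCF (inverse of :func:`write_mutations_vcf`)."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref
            alt = rec.alts[0]
            kind = rec.info.get("KIND", "BPS" if len(ref) == len(alt) == 1 else None)
            if kind is None:
                kind = "insertion" if len(alt) > len(ref) else "deletion"
            bps_class = rec.info.get("BPSCLASS")
            calls.append(
                MutationCall(
                    line_id=rec.info["LINE"],
                    replicon=rec.contig,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    kind=kind,
                    bps_class=bps_class,
                    context=rec.info.get("CONTEXT"),
                )
            )
    return calls


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
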