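"""Multi-replicon genome model with base-composition bookkeeping.

Halophilic archaeal genomes such as that of *Halobacterium salinarum* NRC-1
consist of a GC-rich main chromosome plus one or more mini-chromosomes
(pNRC100, pNRC200).  Mutation-rate denominators and the conditional
mutation-spectrum classes both depend on the base composition of each
replicon, so the model keeps per-replicon A/C/G/T counts alongside the raw
sequence.

Coordinates are 1-based inclusive throughout (the GFF3/VCF convention);
conversions to 0-based indexing are confined to array internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Base encoding used everywhere in the package: A=0, C=1, G=2, T=3.
BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

#: Codes for characters that are not plain A/C/G/T (IUPAC ambiguity codes,
#: gaps...).  They are retained in sequences but excluded from composition
#: counts and from callable-site denominators.
NON_ACGT = -2

_ENCODER = np.full(256, NON_ACGT, dtype=np.int8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODER[ord(_b)] = _c
    _ENCODER[ord(_b.lower())] = _c

MAIN_CHROMOSOME = "main-chromosome"
MINI_CHROMOSOME = "mini-chromosome"


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0,C=1,G=2,T=3, else -2)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODER[raw]


@dataclass
class Replicon:
    """One independently replicating genome component."""

    id: str
    sequence: str
    role: str = MAIN_CHROMOSOME

    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("replicon id must be non-empty")
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.codes = encode_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def base_counts(self) -> np.ndarray:
        """Counts of A, C, G, T (non-ACGT characters excluded)."""
        return np.bincount(self.codes[self.codes >= 0], minlength=4)

    @property
    def n_acgt(self) -> int:
        return int((self.codes >= 0).sum())

    @property
    def gc_fraction(self) -> float:
        counts = self.base_counts
        total = counts.sum()
        if total == 0:
            return float("nan")
        return float((counts[1] + counts[2]) / total)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(
                f"position {pos} outside replicon {self.id!r} (length {self.length})"
            )
        return self.sequence[pos - 1]


class GenomeModel:
    """An ordered collection of replicons with unique ids."""

    def __init__(self, replicons: list[Replicon]):
        if not replicons:
            raise ValueError("genome must contain at least one replicon")
        ids = [r.id for r in replicons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate replicon id(s): {sorted(dupes)}")
        self.replicons: list[Replicon] = list(replicons)
        self._by_id = {r.id: r for r in replicons}

    def __iter__(self) -> Iterator[Replicon]:
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def __contains__(self, replicon_id: str) -> bool:
        return replicon_id in self._by_id

    def __getitem__(self, replicon_id: str) -> Replicon:
        try:
            return self._by_id[replicon_id]
        except KeyError:
            raise KeyError(
                f"unknown replicon {replicon_id!r}; genome has {sorted(self._by_id)}"
            ) from None

    @property
    def total_size(self) -> int:
        return sum(r.length for r in self.replicons)

    @property
    def base_counts(self) -> np.ndarray:
        return sum((r.base_counts for r in self.replicons), np.zeros(4, dtype=np.int64))

    @property
    def n_acgt(self) -> int:
        return sum(r.n_acgt for r in self.replicons)

    @property
    def gc_fraction(self) -> float:
        counts = self.base_counts
        return float((counts[1] + counts[2]) / counts.sum())

    @property
    def at_fraction(self) -> float:
        return 1.0 - self.gc_fraction

    def base(self, replicon_id: str, pos: int) -> str:
        return self[replicon_id].base(pos)


def read_genome(path: str | Path) -> GenomeModel:
    """Read a (multi-)FASTA genome into a :class:`GenomeModel`.

    One replicon per FASTA record, record order preserved.  The longest
    record is labelled the main chromosome, all others mini-chromosomes.
    Duplicate record ids and empty records are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    replicons = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        replicons.append(Replicon(id=rec.id, sequence=seq))
    longest = max(replicons, key=lambda r: r.length)
    for rep in replicons:
        rep.role = MAIN_CHROMOSOME if rep is longest else MINI_CHROMOSOME
    return GenomeModel(replicons)


def write_genome(genome: GenomeModel, path: str | Path, width: int = 70) -> None:
    """Write a :class:`GenomeModel` to FASTA (inverse of :func:`read_genome`)."""
    records = [
        SeqRecord(Seq(rep.sequence), id=rep.id, description=rep.role)
        for rep in genome
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
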