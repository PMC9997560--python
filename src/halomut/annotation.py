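"""Coding/noncoding annotation from GFF3 CDS features.

Only feature rows of type ``CDS`` are used; overlapping CDS intervals on a
replicon are merged, so every genomic position is either coding or
noncoding.  Intervals are 1-based inclusive, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np

from .genome import GenomeModel


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class AnnotationSet:
    """Merged coding intervals per replicon, with fast point lookup."""

    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.intervals = {rep: _merge(ivs) for rep, ivs in self.intervals.items()}
        self._starts = {
            rep: np.array([s for s, _ in ivs], dtype=np.int64)
            for rep, ivs in self.intervals.items()
        }
        self._ends = {
            rep: np.array([e for _, e in ivs], dtype=np.int64)
            for rep, ivs in self.intervals.items()
        }

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "CDS") -> "AnnotationSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"annotation GFF3 not found: {path}")
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        intervals: dict[str, list[tuple[int, int]]] = {}
        for feat in db.features_of_type(feature_type):
            intervals.setdefault(feat.seqid, []).append((feat.start, feat.end))
        return cls(intervals)

    def validate(self, genome: GenomeModel) -> None:
        for rep_id, ivs in self.intervals.items():
            length = genome[rep_id].length
            for start, end in ivs:
                if not 1 <= start <= end <= length:
                    raise ValueError(
                        f"interval {start}-{end} outside replicon {rep_id!r} "
                        f"(length {length})"
                    )

    def is_coding(self, replicon: str, pos: int) -> bool:
        """True if 1-based ``pos`` lies inside a coding interval (ends inclusive)."""
        starts = self._starts.get(replicon)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= self._ends[replicon][i]

    def is_coding_array(self, replicon: str, pos: np.ndarray) -> np.ndarray:
        starts = self._starts.get(replicon)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] <= self._ends[replicon][i[ok]]
        return out

    def coding_sites(self, replicon: str | None = None) -> int:
        """Total merged coding length, for one replicon or the whole set."""
        if replicon is not None:
            return sum(e - s + 1 for s, e in self.intervals.get(replicon, []))
        return sum(self.coding_sites(rep) for rep in self.intervals)

    def noncoding_sites(self, genome: GenomeModel) -> int:
        return genome.total_size - self.coding_sites()


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write merged CDS intervals back out as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        n = 0
        for rep, ivs in annotation.intervals.items():
            for start, end in ivs:
                n += 1
                fh.write(
                    f"{rep}\thalomut\tCDS\t{start}\t{end}\t.\t+\t0\tID=cds{n}\n"
                )
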