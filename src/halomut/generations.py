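"""Generation estimation for MA lines from colony-forming-unit counts.

Each MA line is bottlenecked through a single colony at every transfer, so
the number of cell divisions between consecutive transfers is estimated as
n = log2(CFU) from the colony's plating count.  The experiment-wide mean of
those per-observation estimates, multiplied by a line's transfer count,
gives that line's total generations — the generations term of the
site-generations denominator used by all rate estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class MALine:
    """One mutation-accumulation line with its rate-denominator metadata."""

    id: str
    n_transfers: float
    generations_per_transfer: float
    total_generations: float
    callable_sites: int = 0

    def __post_init__(self) -> None:
        for name in ("n_transfers", "generations_per_transfer",
                     "total_generations", "callable_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"MALine.{name} must be >= 0")


def generations_from_cfu(cfu: float) -> float:
    """Generations per transfer from one CFU count: n = log2(CFU).

    A count below one colony would imply negative generations and is
    rejected.
    """
    if cfu < 1:
        raise ValueError(f"CFU must be >= 1, got {cfu}")
    return math.log2(cfu)


def mean_generations(series: pd.DataFrame | list[float]) -> float:
    """Mean generations per transfer over a CFU series.

    The mean is taken over the per-observation generation estimates
    log2(CFU) — not over raw CFU counts then logged.  ``series`` is either
    a CFU table (DataFrame with a ``cfu`` column) or a plain list of CFU
    counts.
    """
    cfus = series["cfu"].tolist() if isinstance(series, pd.DataFrame) else list(series)
    if not cfus:
        raise ValueError("empty CFU series")
    return sum(generations_from_cfu(c) for c in cfus) / len(cfus)


def per_line_mean_generations(series: pd.DataFrame) -> dict[str, float]:
    """Per-line means of log2(CFU); the experiment-wide mean is the default."""
    return {
        str(line): mean_generations(grp)
        for line, grp in series.groupby("line_id")
    }


def total_line_generations(mean_gens: float, n_transfers: float) -> float:
    """Total generations of a line: mean generations/transfer x transfers."""
    if mean_gens <= 0 or n_transfers <= 0:
        raise ValueError(
            f"mean_gens and n_transfers must be > 0 "
            f"(got {mean_gens}, {n_transfers})"
        )
    return mean_gens * n_transfers


def build_lines(
    cfu_table: pd.DataFrame,
    transfers: dict[str, float],
    callable_sites: dict[str, int] | None = None,
    per_line: bool = False,
) -> list[MALine]:
    """Assemble :class:`MALine` records from a CFU table and transfer counts.

    By default a single experiment-wide mean generations-per-transfer is
    applied to every line; ``per_line=True`` uses each line's own CFU
    observations instead (lines without observations fall back to the
    experiment-wide mean).
    """
    overall = mean_generations(cfu_table)
    by_line = per_line_mean_generations(cfu_table) if per_line else {}
    lines = []
    for line_id, n_transfers in transfers.items():
        g = by_line.get(line_id, overall)
        lines.append(
            MALine(
                id=line_id,
                n_transfers=n_transfers,
                generations_per_transfer=g,
                total_generations=total_line_generations(g, n_transfers),
                callable_sites=(callable_sites or {}).get(line_id, 0),
            )
        )
    return lines
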