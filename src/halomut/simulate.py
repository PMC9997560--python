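"""Synthetic MA-experiment generator.

Generates everything the analysis consumes — genomes, per-line mutation
histories, noisy per-site read summaries, and CFU series — with the
statistical structure the pipeline assumes: mutations accumulate neutrally
and independently per line (Poisson counts per class, positions uniform
over class-eligible sites), read summaries carry Poisson depth, uniform
sequencing error, ancestral-allele contamination and incomplete site
callability, and CFU counts carry multiplicative lognormal plating noise.

Defaults emulate the *Hbt. salinarum* NRC-1 study design: a 2.57 Mb genome
in three replicons (~66% GC overall), 67 lines, ~1267 generations, ~200x
depth, 96.8% callability, ~1% aberrant-read contamination, and per-class
conditional rates that sum to an overall base-substitution rate of
~4e-10 per site per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import AT_TO_GC_CLASSES, BPS_CLASSES, GC_TO_AT_CLASSES, SiteBlock
from .genome import BASES, GenomeModel, Replicon

#: Study-design constants of the emulated experiment.
HBT_N_LINES = 67
HBT_GENERATIONS = 1267.0
HBT_SITES_SURVEYED = 2_489_236
HBT_GC_FRACTION = 0.659
HBT_DEPTH_MEAN = 200.0
HBT_CALLABILITY = 0.968
HBT_CONTAMINATION = 0.01
HBT_ERROR_RATE = 1e-3

#: Replicon blueprints: (id, length bp, target GC fraction) for the main
#: chromosome and the two mini-chromosomes pNRC200/pNRC100.
HBT_REPLICON_SPECS = (
    ("chr", 2_014_239, 0.68),
    ("pNRC200", 365_425, 0.58),
    ("pNRC100", 191_346, 0.59),
)

# Per-class mutation counts consistent with the emulated study: 71
# GC->AT-direction changes, 9 AT->GC, 4 conservative transversions, and a
# transition bias (66 transitions) — 84 substitutions in all, plus 7
# deletions and 3 insertions.
_DEFAULT_CLASS_COUNTS = {
    "G:C->A:T": 64,
    "G:C->T:A": 7,
    "G:C->C:G": 2,
    "A:T->G:C": 2,
    "A:T->C:G": 7,
    "A:T->T:A": 2,
}
_SITE_GENS = HBT_SITES_SURVEYED * HBT_N_LINES * HBT_GENERATIONS


def _default_class_rates() -> dict[str, float]:
    rates = {}
    for cls, count in _DEFAULT_CLASS_COUNTS.items():
        frac = HBT_GC_FRACTION if cls.startswith("G:C") else 1 - HBT_GC_FRACTION
        rates[cls] = count / (_SITE_GENS * frac)
    return rates


def _default_indel_length_probs() -> np.ndarray:
    # geometric decay over 1..30 bp: most indels are short
    probs = 0.5 ** np.arange(30)
    return probs / probs.sum()


@dataclass
class SpectrumMatrix:
    """Per-class conditional mutation rates (per site per generation).

    ``class_rates`` holds the six strand-collapsed base-substitution
    classes; ``insertion_rate``/``deletion_rate`` are per (any) site per
    generation; ``indel_length_probs`` is the length distribution over
    1..30 bp.
    """

    class_rates: dict[str, float] = field(default_factory=_default_class_rates)
    insertion_rate: float = 3 / _SITE_GENS
    deletion_rate: float = 7 / _SITE_GENS
    indel_length_probs: np.ndarray = field(default_factory=_default_indel_length_probs)

    def __post_init__(self) -> None:
        missing = set(BPS_CLASSES) - set(self.class_rates)
        if missing:
            raise ValueError(f"missing class rates: {sorted(missing)}")
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("class rates must be >= 0")
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ValueError("indel rates must be >= 0")
        self.indel_length_probs = np.asarray(self.indel_length_probs, dtype=float)
        if len(self.indel_length_probs) != 30 or (self.indel_length_probs < 0).any():
            raise ValueError("indel_length_probs must be 30 nonnegative weights")
        total = self.indel_length_probs.sum()
        if total > 0:
            self.indel_length_probs = self.indel_length_probs / total

    def gc_origin_rate(self) -> float:
        """Total rate per G/C site: all G:C-origin classes."""
        return sum(r for c, r in self.class_rates.items() if c.startswith("G:C"))

    def at_origin_rate(self) -> float:
        return sum(r for c, r in self.class_rates.items() if c.startswith("A:T"))

    def overall_bps_rate(self, gc_fraction: float) -> float:
        """Genome-wide per-site rate given the genome's GC fraction."""
        return (
            self.gc_origin_rate() * gc_fraction
            + self.at_origin_rate() * (1 - gc_fraction)
        )

    def true_equilibrium_gc(self) -> float:
        """Equilibrium GC implied by the directional class rates."""
        mu_at = sum(self.class_rates[c] for c in AT_TO_GC_CLASSES)
        mu_gc = sum(self.class_rates[c] for c in GC_TO_AT_CLASSES)
        return mu_at / (mu_at + mu_gc)


@dataclass
class TrueMutationRecord:
    """Simulation ground truth for one injected mutation.

    Indels use the anchored representation: ``pos`` is the base before the
    event, ``ref``/``alt`` include the anchor base (VCF convention), so
    truth records compare directly against :class:`~.calling.MutationCall`.
    """

    line_id: str
    replicon: str
    pos: int
    ref: str
    alt: str
    kind: str  # "BPS" | "insertion" | "deletion"
    bps_class: str | None
    generation: int

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.line_id, self.replicon, self.pos, self.ref, self.alt)


# alt base for each (class, ref) pair
_CLASS_ALT = {
    ("G:C->A:T", "G"): "A", ("G:C->A:T", "C"): "T",
    ("G:C->T:A", "G"): "T", ("G:C->T:A", "C"): "A",
    ("G:C->C:G", "G"): "C", ("G:C->C:G", "C"): "G",
    ("A:T->G:C", "A"): "G", ("A:T->G:C", "T"): "C",
    ("A:T->C:G", "A"): "C", ("A:T->C:G", "T"): "G",
    ("A:T->T:A", "A"): "T", ("A:T->T:A", "T"): "A",
}

_CODE_TO_CHAR = np.frombuffer(BASES.encode(), dtype="S1")


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


def default_line_ids(n_lines: int) -> list[str]:
    return [f"L{i:03d}" for i in range(1, n_lines + 1)]


def generate_genome(
    replicon_specs=HBT_REPLICON_SPECS,
    seed: int | None = None,
) -> GenomeModel:
    """Generate a genome of i.i.d. bases with per-replicon GC targets.

    ``replicon_specs`` is a sequence of ``(id, length, gc_fraction)``
    triples (lengths >= 1 kb).  P(G) = P(C) = gc/2 and P(A) = P(T) =
    (1-gc)/2 independently per site; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    replicons = []
    for rep_id, length, gc in replicon_specs:
        if length < 1000:
            raise ValueError(f"replicon {rep_id!r}: length must be >= 1 kb")
        if not 0 <= gc <= 1:
            raise ValueError(f"replicon {rep_id!r}: GC fraction must be in [0, 1]")
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        codes = rng.choice(4, size=length, p=p).astype(np.int8)
        replicons.append(Replicon(id=rep_id, sequence=_codes_to_str(codes)))
    longest = max(replicons, key=lambda r: r.length)
    for rep in replicons:
        rep.role = "main-chromosome" if rep is longest else "mini-chromosome"
    return GenomeModel(replicons)


def simulate_ma_lines(
    genome: GenomeModel,
    spectrum: SpectrumMatrix | None = None,
    n_lines: int = HBT_N_LINES,
    generations: float = HBT_GENERATIONS,
    seed: int | None = None,
    line_ids: list[str] | None = None,
) -> list[TrueMutationRecord]:
    """Simulate neutral mutation accumulation across independent MA lines.

    For each line and mutation class the number of events is Poisson
    (rate x class-eligible sites x generations); positions are uniform over
    eligible sites.  Lines are independent (no shared mutations) and
    double hits at one site within a line are removed by rejection —
    negligible at these rates, and it keeps the truth set unambiguous.
    """
    spectrum = spectrum or SpectrumMatrix()
    rng = np.random.default_rng(seed)
    line_ids = line_ids or default_line_ids(n_lines)
    if len(line_ids) != n_lines:
        raise ValueError("line_ids length must equal n_lines")

    # class-eligible site registers, concatenated across replicons
    gc_sites: list[tuple[str, np.ndarray]] = []
    at_sites: list[tuple[str, np.ndarray]] = []
    for rep in genome:
        gc_sites.append((rep.id, np.nonzero((rep.codes == 1) | (rep.codes == 2))[0]))
        at_sites.append((rep.id, np.nonzero((rep.codes == 0) | (rep.codes == 3))[0]))

    def _flat(sites):
        reps = [r for r, _ in sites]
        lens = [len(p) for _, p in sites]
        return reps, lens, np.concatenate([p for _, p in sites]) if sites else np.array([])

    gc_reps, gc_lens, gc_flat = _flat(gc_sites)
    at_reps, at_lens, at_flat = _flat(at_sites)
    gc_bounds = np.cumsum([0] + gc_lens)
    at_bounds = np.cumsum([0] + at_lens)

    per_site = max(
        spectrum.gc_origin_rate(), spectrum.at_origin_rate()
    ) * generations + (spectrum.insertion_rate + spectrum.deletion_rate) * generations
    if per_site > 0.01:
        warnings.warn(
            f"expected hits per site {per_site:.3g} > 0.01; "
            "double-hit rejection may distort the spectrum",
            stacklevel=2,
        )

    records: list[TrueMutationRecord] = []
    for line_id in line_ids:
        used: set[tuple[str, int]] = set()

        def _draw_site(flat, bounds, reps):
            """One uniform eligible site, rejecting within-line double hits."""
            while True:
                j = int(rng.integers(0, len(flat)))
                k = int(np.searchsorted(bounds, j, side="right")) - 1
                rep_id = reps[k]
                pos = int(flat[j]) + 1
                if (rep_id, pos) not in used:
                    used.add((rep_id, pos))
                    return rep_id, pos

        for cls in BPS_CLASSES:
            rate = spectrum.class_rates[cls]
            flat, bounds, reps = (
                (gc_flat, gc_bounds, gc_reps)
                if cls.startswith("G:C")
                else (at_flat, at_bounds, at_reps)
            )
            lam = rate * len(flat) * generations
            for _ in range(rng.poisson(lam)):
                rep_id, pos = _draw_site(flat, bounds, reps)
                ref = genome.base(rep_id, pos)
                alt = _CLASS_ALT[(cls, ref)]
                records.append(
                    TrueMutationRecord(
                        line_id, rep_id, pos, ref, alt, "BPS", cls,
                        int(rng.integers(1, int(generations) + 1)),
                    )
                )

        # indels: anchored at the base before the event
        n_sites = genome.total_size
        for kind, rate in (
            ("deletion", spectrum.deletion_rate),
            ("insertion", spectrum.insertion_rate),
        ):
            lam = rate * n_sites * generations
            for _ in range(rng.poisson(lam)):
                length = int(rng.choice(30, p=spectrum.indel_length_probs)) + 1
                while True:
                    rep = genome.replicons[int(rng.integers(0, len(genome)))]
                    max_anchor = rep.length - length if kind == "deletion" else rep.length
                    if max_anchor < 1:
                        continue
                    pos = int(rng.integers(1, max_anchor + 1))
                    if (rep.id, pos) not in used:
                        used.add((rep.id, pos))
                        break
                anchor = rep.base(pos)
                if kind == "deletion":
                    seq = rep.sequence[pos : pos + length]
                    ref, alt = anchor + seq, anchor
                else:
                    gc = genome.gc_fraction
                    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
                    seq = _codes_to_str(rng.choice(4, size=length, p=p).astype(np.int8))
                    ref, alt = anchor, anchor + seq
                records.append(
                    TrueMutationRecord(
                        line_id, rep.id, pos, ref, alt, kind, None,
                        int(rng.integers(1, int(generations) + 1)),
                    )
                )
    records.sort(key=lambda r: (r.line_id, r.replicon, r.pos))
    return records


def _indel_allele(rec: TrueMutationRecord) -> str:
    if rec.kind == "deletion":
        return "-" + rec.ref[1:]
    return "+" + rec.alt[1:]


def simulate_read_summaries(
    genome: GenomeModel,
    mutations: list[TrueMutationRecord],
    line_ids: list[str],
    depth_mean: float = HBT_DEPTH_MEAN,
    error_rate: float = HBT_ERROR_RATE,
    contamination: float = HBT_CONTAMINATION,
    callability: float = HBT_CALLABILITY,
    seed: int | None = None,
    as_frames: bool = True,
):
    """Generate per-line site read summaries with noise.

    Per emitted site, depth ~ Poisson(depth_mean); each read reports the
    line's true allele except that a ``contamination`` fraction of reads
    report the progenitor (ancestral) base — the worst case for the
    consensus-fraction rule — and an ``error_rate`` fraction of the
    remaining reads report a uniformly chosen other base.  A fraction
    ``1 - callability`` of sites is omitted at random per line.

    Yields ``(line_id, data)`` pairs where ``data`` is a site-summary
    DataFrame (``as_frames=True``) or a ``{replicon: SiteBlock}`` dict
    (the compact array form the caller also accepts).
    """
    if not (0 <= error_rate < 0.5 and 0 <= contamination < 0.5):
        raise ValueError("error_rate and contamination must be in [0, 0.5)")
    if not 0 < callability <= 1:
        raise ValueError("callability must be in (0, 1]")
    rng = np.random.default_rng(seed)

    by_line: dict[str, dict[str, dict[int, TrueMutationRecord]]] = {}
    for rec in mutations:
        by_line.setdefault(rec.line_id, {}).setdefault(rec.replicon, {})[rec.pos] = rec

    for line_id in line_ids:
        blocks: dict[str, SiteBlock] = {}
        line_muts = by_line.get(line_id, {})
        for rep in genome:
            L = rep.length
            emit = rng.random(L) < callability
            pos0 = np.nonzero(emit)[0]
            n = pos0.size
            depth = rng.poisson(depth_mean, n)
            anc_code = rep.codes[pos0].astype(np.int64)

            # Non-mutated sites: a contaminant read reports the ancestral
            # base, which IS the reference there, so contamination is
            # invisible and only errors displace reads — each read is an
            # error-read with probability (1 - contamination) x error_rate
            # exactly.  Mutated rows are fully re-drawn below.
            n_err = rng.binomial(depth, (1 - contamination) * error_rate)
            counts = np.zeros((n, 4), dtype=np.int32)
            rows = np.arange(n)
            counts[rows, anc_code] = depth - n_err
            err_rows = np.nonzero(n_err)[0]
            if err_rows.size:
                ne = n_err[err_rows]
                e1 = rng.binomial(ne, 1 / 3)
                e2 = rng.binomial(ne - e1, 0.5)
                ac = anc_code[err_rows]
                counts[err_rows, (ac + 1) % 4] += e1
                counts[err_rows, (ac + 2) % 4] += e2
                counts[err_rows, (ac + 3) % 4] += ne - e1 - e2

            n_indel = np.zeros(n, dtype=np.int32)
            alleles: dict[int, str] = {}
            for pos, rec in line_muts.get(rep.id, {}).items():
                row = int(np.searchsorted(pos0, pos - 1))
                if row >= n or pos0[row] != pos - 1:
                    continue  # site not emitted for this line
                d = int(depth[row])
                n_contam = rng.binomial(d, contamination)
                ne = rng.binomial(d - n_contam, error_rate)
                n_true = d - n_contam - ne
                counts[row, :] = 0
                if rec.kind == "BPS":
                    true_code = BASES.index(rec.alt)
                    counts[row, true_code] = n_true
                else:
                    true_code = int(anc_code[row])
                    n_indel[row] = n_true
                    alleles[pos] = _indel_allele(rec)
                counts[row, anc_code[row]] += n_contam
                errs = rng.multinomial(ne, [1 / 3] * 3)
                for k in range(3):
                    counts[row, (true_code + 1 + k) % 4] += errs[k]

            blocks[rep.id] = SiteBlock(pos0 + 1, counts, n_indel, alleles)

        if as_frames:
            yield line_id, _blocks_to_frame(line_id, genome, blocks)
        else:
            yield line_id, blocks


def _blocks_to_frame(
    line_id: str, genome: GenomeModel, blocks: dict[str, SiteBlock]
) -> pd.DataFrame:
    frames = []
    for rep_id, blk in blocks.items():
        seq = np.frombuffer(genome[rep_id].sequence.encode(), dtype="S1")
        ref = seq[blk.pos - 1].astype("U1")
        indel_allele = np.full(len(blk.pos), ".", dtype=object)
        for pos, allele in blk.indel_alleles.items():
            indel_allele[np.searchsorted(blk.pos, pos)] = allele
        frames.append(
            pd.DataFrame(
                {
                    "line_id": line_id,
                    "replicon": rep_id,
                    "pos": blk.pos,
                    "ref": ref,
                    "nA": blk.counts[:, 0],
                    "nC": blk.counts[:, 1],
                    "nG": blk.counts[:, 2],
                    "nT": blk.counts[:, 3],
                    "indel_allele": indel_allele,
                    "n_indel": blk.n_indel,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_cfu(
    true_generations_per_transfer: float,
    n_observations: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a CFU table: CFU = round(2**g x lognormal noise).

    ``noise_sd`` is the standard deviation of the natural-log noise on the
    count scale (plating counts are positive and right-skewed); with
    ``noise_sd=0``, log2(CFU) recovers ``g`` exactly up to rounding.
    Returns a DataFrame with columns ``line_id, transfer_index, cfu``.
    """
    if true_generations_per_transfer <= 0:
        raise ValueError("true_generations_per_transfer must be > 0")
    if n_observations == 0:
        return pd.DataFrame(columns=["line_id", "transfer_index", "cfu"])
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, noise_sd, n_observations))
    cfu = np.maximum(
        1, np.rint(2.0**true_generations_per_transfer * noise)
    ).astype(np.int64)
    if line_ids is None:
        line_ids = default_line_ids(min(n_observations, 10))
    ids = [line_ids[i % len(line_ids)] for i in range(n_observations)]
    return pd.DataFrame(
        {
            "line_id": ids,
            "transfer_index": np.arange(1, n_observations + 1),
            "cfu": cfu,
        }
    )
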