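"""Genome FASTA I/O, site-summary TSV parsing, VCF round trips, config."""

from __future__ import annotations

import numpy as np
import pytest

import halomut as hm
from halomut.calling import MutationCall
from halomut.genome import Replicon
from halomut.io import (
    RunConfig,
    load_config,
    read_site_summaries,
    read_site_summary_table,
    save_config,
    write_site_summary_table,
)

NRC1_LENGTHS = {"chr": 2_014_239, "pNRC200": 365_425, "pNRC100": 191_346}


class TestReadGenome:
    def test_three_replicon_genome_total_size(self, tmp_path):
        """A genome with the NRC-1 replicon lengths totals 2,571,010 bp."""
        genome = hm.generate_genome(
            [(rid, length, 0.66) for rid, length in NRC1_LENGTHS.items()], seed=0
        )
        path = tmp_path / "genome.fasta"
        hm.write_genome(genome, path)
        back = hm.read_genome(path)
        assert back.total_size == 2_571_010
        assert [r.id for r in back] == list(NRC1_LENGTHS)
        assert back["chr"].role == "main-chromosome"
        assert back["pNRC100"].role == "mini-chromosome"
        # write/read is the identity on sequences
        assert all(
            a.sequence == b.sequence for a, b in zip(genome, back)
        )

    def test_single_record(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">r1\nACGT\n")
        genome = hm.read_genome(path)
        assert len(genome) == 1
        assert genome["r1"].length == 4
        assert genome["r1"].gc_fraction == pytest.approx(0.5)

    def test_duplicate_ids_error(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">r1\nACGT\n>r1\nGGCC\n")
        with pytest.raises(ValueError, match="r1"):
            hm.read_genome(path)

    def test_missing_file_and_empty_record(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            hm.read_genome(tmp_path / "nope.fasta")
        path = tmp_path / "empty.fasta"
        path.write_text(">r1\n\n>r2\nACGT\n")
        with pytest.raises(ValueError):
            hm.read_genome(path)

    def test_non_acgt_excluded_from_composition(self):
        rep = Replicon(id="r", sequence="ACGTNNNN")
        assert rep.length == 8
        assert rep.n_acgt == 4
        assert rep.gc_fraction == pytest.approx(0.5)


class TestSiteSummaryTSV:
    HEADER = "line_id\treplicon\tpos\tref\tnA\tnC\tnG\tnT\tindel_allele\tn_indel\n"

    def test_parse_rows(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            self.HEADER
            + "L01\tchr\t100\tG\t0\t0\t200\t0\t.\t0\n"
            + "L01\tchr\t101\tG\t2\t0\t198\t0\t.\t0\n"
        )
        rows = list(read_site_summaries(path))
        assert rows[0].depth == 200
        assert rows[0].counts.tolist() == [0, 0, 200, 0]
        assert rows[1].nG / rows[1].depth == pytest.approx(0.99)

    def test_pos_zero_is_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(self.HEADER + "L01\tchr\t0\tG\t0\t0\t9\t0\t.\t0\n")
        with pytest.raises(ValueError, match="1-based"):
            list(read_site_summaries(path))

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            self.HEADER
            + "L01\tchr\t10\tG\t0\t0\t50\t0\t.\t0\n"
            + "L01\tchr\tXX\tG\t0\t0\t50\t0\t.\t0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            list(read_site_summaries(path))

    def test_pos_outside_replicon(self, tmp_path, small_genome):
        path = tmp_path / "s.tsv"
        path.write_text(self.HEADER + "L01\tchr\t999999\tG\t0\t0\t50\t0\t.\t0\n")
        with pytest.raises(ValueError, match="outside"):
            list(read_site_summaries(path, small_genome))

    def test_table_roundtrip(self, tmp_path, clean_experiment):
        genome, truth, _, line_ids = clean_experiment
        frames = dict(
            hm.simulate_read_summaries(
                genome, truth, line_ids[:1], error_rate=0.0, contamination=0.0,
                callability=1.0, seed=8, as_frames=True,
            )
        )
        frame = frames[line_ids[0]]
        path = tmp_path / "line.tsv"
        write_site_summary_table(frame, path)
        back = read_site_summary_table(path, genome)
        assert len(back) == len(frame)
        assert (back["pos"].to_numpy() == frame["pos"].to_numpy()).all()
        assert (back["nG"].to_numpy() == frame["nG"].to_numpy()).all()


class TestVCF:
    def test_empty_call_list(self, tmp_path, small_genome):
        path = tmp_path / "empty.vcf"
        hm.write_mutations_vcf([], small_genome, path)
        assert hm.read_mutations_vcf(path) == []

    def test_single_bps_record(self, tmp_path, small_genome):
        call = MutationCall("L01", "chr", 100, "G", "A", "BPS")
        path = tmp_path / "one.vcf"
        hm.write_mutations_vcf([call], small_genome, path)
        text = path.read_text()
        assert "chr\t100\t.\tG\tA" in text
        back = hm.read_mutations_vcf(path)[0]
        assert (back.pos, back.ref, back.alt, back.line_id) == (100, "G", "A", "L01")

    def test_deletion_is_left_anchored(self, tmp_path, small_genome):
        """A 2 bp deletion at 200-201 is anchored at POS=199 with REF len 3."""
        anchor = small_genome.base("chr", 199)
        deleted = small_genome["chr"].sequence[199:201]
        call = MutationCall("L01", "chr", 199, anchor + deleted, anchor, "deletion")
        path = tmp_path / "del.vcf"
        hm.write_mutations_vcf([call], small_genome, path)
        back = hm.read_mutations_vcf(path)[0]
        assert back.pos == 199
        assert len(back.ref) == 3 and len(back.alt) == 1
        assert back.indel_length == 2

    def test_unknown_replicon_error(self, tmp_path, small_genome):
        call = MutationCall("L01", "nope", 5, "G", "A", "BPS")
        with pytest.raises(KeyError, match="nope"):
            hm.write_mutations_vcf([call], small_genome, tmp_path / "x.vcf")

    def test_roundtrip_random_calls(self, tmp_path, small_genome, call_keys):
        """1000 random calls survive a VCF write/read cycle exactly."""
        rng = np.random.default_rng(11)
        calls = []
        for _ in range(1000):
            rep = small_genome.replicons[rng.integers(0, 3)]
            pos = int(rng.integers(1, rep.length - 40))
            line = f"L{rng.integers(1, 21):03d}"
            ref = rep.base(pos)
            kind = ["BPS", "insertion", "deletion"][rng.integers(0, 3)]
            if kind == "BPS":
                alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
                calls.append(MutationCall(line, rep.id, pos, ref, alt, "BPS"))
            elif kind == "insertion":
                ins = "".join(rng.choice(list("ACGT"), rng.integers(1, 31)))
                calls.append(
                    MutationCall(line, rep.id, pos, ref, ref + ins, "insertion")
                )
            else:
                k = int(rng.integers(1, 31))
                seq = rep.sequence[pos : pos + k]
                calls.append(
                    MutationCall(line, rep.id, pos, ref + seq, ref, "deletion")
                )
        path = tmp_path / "all.vcf"
        hm.write_mutations_vcf(calls, small_genome, path)
        back = hm.read_mutations_vcf(path)
        assert sorted(call_keys(back)) == sorted(call_keys(calls))


class TestRunConfig:
    def test_defaults_match_study_thresholds(self):
        cfg = RunConfig()
        assert cfg.min_depth == 10
        assert cfg.consensus_fraction == 0.99
        assert cfg.ci_level == 0.95

    @pytest.mark.parametrize(
        "kwargs", [{"min_depth": 0}, {"consensus_fraction": 0.4},
                   {"consensus_fraction": 1.2}, {"ci_level": 0.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(min_depth=12, consensus_fraction=0.98, seed=5)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg
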