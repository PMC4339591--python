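"""Coordinate frames, FASTA header dialect, and GFF3 round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from cnmskit.seq_model import (
    FastaFormatError,
    LocatedFeature,
    OrthologyTable,
    UpInterval,
    UpstreamSequence,
    read_loci_gff3,
    read_orthology_table,
    read_upstream_fasta,
    to_string_frame,
    to_upstream_frame,
    write_loci_gff3,
    write_orthology_table,
    write_upstream_fasta,
)


def write_fasta(tmp_path, text):
    p = tmp_path / "in.fa"
    p.write_text(text)
    return p


class TestReadUpstreamFasta:
    def test_full_header_parsed(self, tmp_path):
        seq = "ACGT" * 250
        p = write_fasta(tmp_path, f">g1|Chr2|+|3541793\n{seq}\n")
        (rec,) = read_upstream_fasta(p, species="chickpea")
        assert rec.gene_id == "g1"
        assert rec.chromosome == "Chr2"
        assert rec.strand == "+"
        assert rec.atg_genomic_pos == 3541793
        assert rec.length == 1000
        assert rec.species == "chickpea"

    def test_minimal_header(self, tmp_path):
        p = write_fasta(tmp_path, ">g2\nACGT\n")
        (rec,) = read_upstream_fasta(p)
        assert rec.gene_id == "g2"
        assert rec.chromosome is None and rec.strand is None
        assert rec.length == 4

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write_fasta(tmp_path, ">g1\nAAAA\n>g1\nCCCC\n")
        with pytest.raises(FastaFormatError, match="g1"):
            read_upstream_fasta(p)

    def test_malformed_header_reports_line(self, tmp_path):
        p = write_fasta(tmp_path, ">ok\nAAAA\n>bad|Chr1|+|xyz\nCCCC\n")
        with pytest.raises(FastaFormatError, match="line 3"):
            read_upstream_fasta(p)

    def test_u_converted_and_case_folded(self, tmp_path):
        p = write_fasta(tmp_path, ">g1\nacgu\n")
        (rec,) = read_upstream_fasta(p)
        assert rec.seq == "ACGT"

    def test_illegal_characters_rejected(self, tmp_path):
        p = write_fasta(tmp_path, ">g1\nACXT\n")
        with pytest.raises(FastaFormatError, match="X"):
            read_upstream_fasta(p)

    def test_round_trip_preserves_everything(self, tmp_path, rng):
        records = [
            UpstreamSequence("gA", "ACGTN" * 10, chromosome="Chr1",
                             strand="-", atg_genomic_pos=1234),
            UpstreamSequence("gB", "TTTT"),
            UpstreamSequence("gC", "ACGT" * 30, chromosome="Chr7"),
        ]
        out = tmp_path / "out.fa"
        write_upstream_fasta(records, out)
        back = read_upstream_fasta(out)
        assert [
            (r.gene_id, r.seq, r.chromosome, r.strand, r.atg_genomic_pos)
            for r in back
        ] == [
            (r.gene_id, r.seq, r.chromosome, r.strand, r.atg_genomic_pos)
            for r in records
        ]


class TestCoordinateFrame:
    @pytest.mark.parametrize(
        "i,j,L,expected",
        [
            (991, 1000, 1000, (1, 10)),    # last 10 bases are nearest the ATG
            (1, 1, 1000, (1000, 1000)),    # first base is the farthest
            (3, 5, 10, (6, 8)),
        ],
    )
    def test_examples(self, i, j, L, expected):
        up = to_upstream_frame(i, j, L)
        assert (up.start_up, up.end_up) == expected

    def test_self_inverse_for_many_lengths(self):
        rng = np.random.default_rng(7)
        for L in [1, 2, 10, 999, 1000]:
            for _ in range(50):
                i = int(rng.integers(1, L + 1))
                j = int(rng.integers(i, L + 1))
                up = to_upstream_frame(i, j, L)
                assert to_string_frame(up, L) == (i, j)
                # applying the same reflection twice returns the input
                twice = to_upstream_frame(up.start_up, up.end_up, L)
                assert (twice.start_up, twice.end_up) == (i, j)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_upstream_frame(0, 5, 10)
        with pytest.raises(ValueError):
            to_upstream_frame(2, 11, 10)
        with pytest.raises(ValueError):
            UpInterval(5, 4)


class TestGff3:
    def test_single_feature_coordinates(self, tmp_path):
        out = tmp_path / "loci.gff3"
        write_loci_gff3(
            [LocatedFeature("g1", "SSR", 101, 124)], out, {"g1": 1000}
        )
        lines = out.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        cols = lines[1].split("\t")
        assert (cols[0], cols[3], cols[4]) == ("g1", "101", "124")
        assert "up_start=877" in cols[8] and "up_end=900" in cols[8]

    def test_empty_collection_header_only(self, tmp_path):
        out = tmp_path / "empty.gff3"
        write_loci_gff3([], out)
        assert out.read_text() == "##gff-version 3\n"

    def test_round_trip_of_random_features(self, tmp_path, rng):
        feats = []
        for n in range(50):
            start = int(rng.integers(1, 900))
            end = start + int(rng.integers(0, 100))
            feats.append(
                LocatedFeature(
                    gene_id=f"g{n % 7}",
                    ftype=str(rng.choice(["SSR", "TFBS", "CNMS_marker"])),
                    start=start,
                    end=end,
                    strand=str(rng.choice(["+", "-", "."])),
                    attributes={"ID": f"f{n}", "note": "x"},
                )
            )
        out = tmp_path / "rt.gff3"
        write_loci_gff3(feats, out)
        back = read_loci_gff3(out)
        assert [
            (f.gene_id, f.ftype, f.start, f.end, f.strand, dict(f.attributes))
            for f in back
        ] == [
            (f.gene_id, f.ftype, f.start, f.end, f.strand, dict(f.attributes))
            for f in feats
        ]


class TestOrthologyTable:
    def test_round_trip_and_validation(self, tmp_path):
        table = OrthologyTable(
            {"g1": [("spA", "a1"), ("spB", "b1")], "g2": [("spA", "a2")]}
        )
        p = tmp_path / "orth.tsv"
        write_orthology_table(table, p)
        back = read_orthology_table(p)
        assert back.mapping == table.mapping
        back.validate(["g1", "g2"], {"spA": ["a1", "a2"], "spB": ["b1"]})
        with pytest.raises(ValueError, match="unknown gene"):
            back.validate(["g1", "g2"], {"spA": ["a1"], "spB": ["b1"]})

    def test_self_species_paralogs_allowed(self):
        table = OrthologyTable({"g1": [("target", "g2")]})
        table.validate(["g1"], {"target": ["g1", "g2"]})

    def test_missing_gene_gives_empty_list(self):
        assert OrthologyTable({}).comparators("nope") == []
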