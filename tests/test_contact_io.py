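"""Genome binning, contact-matrix I/O, and record readers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicdelta.contact_io import (
    Breakpoint,
    ContactMatrix,
    FileFormatError,
    GenomeSpec,
    Loop,
    bin_genome,
    classify_de,
    read_bedpe_loops,
    read_breakpoints,
    read_gene_table,
    read_matrix,
    read_sv_table,
    write_bedpe_loops,
    write_matrix,
)


class TestBinGenome:
    @pytest.mark.parametrize(
        "lengths,res,expected_bins",
        [
            ({"chr1": 100}, 50, [("chr1", 0, 50), ("chr1", 50, 100)]),
            ({"chr1": 120}, 50, [("chr1", 0, 50), ("chr1", 50, 100), ("chr1", 100, 120)]),
        ],
    )
    def test_tiling(self, lengths, res, expected_bins):
        bins = bin_genome(GenomeSpec.from_dict(lengths), res)
        got = [
            (bins.chrom_of(i), int(bins.starts[i]), int(bins.ends[i]))
            for i in range(bins.n_bins)
        ]
        assert got == expected_bins

    def test_two_chromosome_indexing(self):
        bins = bin_genome(GenomeSpec.from_dict({"chr1": 1000, "chr2": 500}), 100)
        assert bins.n_bins == 15
        assert bins.chrom_range("chr2") == (10, 15)

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError):
            bin_genome(GenomeSpec.from_dict({"chr1": 100}), 0)

    @given(length=st.integers(1, 10_000), res=st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_bins_tile_without_gaps(self, length, res):
        bins = bin_genome(GenomeSpec.from_dict({"c": length}), res)
        assert bins.starts[0] == 0 and bins.ends[-1] == length
        assert (bins.starts[1:] == bins.ends[:-1]).all()
        widths = bins.ends - bins.starts
        assert (widths[:-1] == res).all() and widths[-1] <= res

    def test_position_to_bin_edges(self):
        bins = bin_genome(GenomeSpec.from_dict({"chr1": 120}), 50)
        assert bins.position_to_bin("chr1", 0) == 0
        assert bins.position_to_bin("chr1", 50) == 1
        assert bins.position_to_bin("chr1", 119) == 2
        with pytest.raises(ValueError):
            bins.position_to_bin("chr1", 120)


class TestMatrixIO:
    def _write(self, tmp_path, bin_lines, matrix_lines):
        b = tmp_path / "t_abs.bed"
        m = tmp_path / "t.matrix"
        b.write_text("".join(bin_lines))
        m.write_text("".join(matrix_lines))
        return m, b

    def test_single_entry_symmetry(self, tmp_path):
        m, b = self._write(
            tmp_path,
            ["chr1\t0\t50\t1\n", "chr1\t50\t100\t2\n"],
            ["1 2 7\n"],
        )
        cm = read_matrix(m, b)
        assert cm.get(0, 1) == 7 and cm.get(1, 0) == 7

    def test_duplicate_entries_rejected(self, tmp_path):
        m, b = self._write(
            tmp_path,
            ["chr1\t0\t50\t1\n", "chr1\t50\t100\t2\n"],
            ["1 2 7\n", "2 1 3\n"],
        )
        with pytest.raises(FileFormatError, match="duplicate"):
            read_matrix(m, b)

    def test_empty_matrix_file(self, tmp_path):
        m, b = self._write(tmp_path, ["chr1\t0\t50\t1\n", "chr1\t50\t100\t2\n"], [])
        cm = read_matrix(m, b)
        assert cm.total() == 0 and cm.bins.n_bins == 2

    @pytest.mark.parametrize(
        "line,msg",
        [("1 9 4\n", "unknown bin id"), ("1 2 -3\n", "negative"), ("1 2\n", "3 columns")],
    )
    def test_malformed_lines_report(self, tmp_path, line, msg):
        m, b = self._write(tmp_path, ["chr1\t0\t50\t1\n", "chr1\t50\t100\t2\n"], [line])
        with pytest.raises(FileFormatError, match=msg):
            read_matrix(m, b)

    def test_integer_round_trip_bit_exact(self, tmp_path):
        bins = bin_genome(GenomeSpec.from_dict({"chr1": 300, "chr2": 200}), 100)
        rng = np.random.default_rng(7)
        dense = rng.integers(0, 40, (5, 5)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        cm = ContactMatrix.from_dense(bins, dense)
        write_matrix(cm, tmp_path / "a.matrix", tmp_path / "a_abs.bed")
        back = read_matrix(tmp_path / "a.matrix", tmp_path / "a_abs.bed")
        assert np.array_equal(back.dense(), cm.dense())
        write_matrix(back, tmp_path / "b.matrix", tmp_path / "b_abs.bed")
        assert (tmp_path / "a.matrix").read_bytes() == (tmp_path / "b.matrix").read_bytes()
        assert (tmp_path / "a_abs.bed").read_bytes() == (tmp_path / "b_abs.bed").read_bytes()


class TestLoops:
    def test_read_canonicalizes_and_counts_inter(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t100\t200\tchr1\t900\t1000\n"
            "chr1\t900\t1000\tchr1\t100\t200\n"   # reversed anchors
            "chr1\t0\t100\tchr2\t0\t100\n"        # inter-chromosomal
        )
        res = read_bedpe_loops(p)
        assert res.n_rejected_inter == 1
        assert len(res.loops) == 2
        assert res.loops[0] == res.loops[1] == Loop.make("chr1", 100, 200, 900, 1000)

    def test_write_read_round_trip(self, tmp_path):
        loops = [Loop.make("chr1", 0, 100, 500, 600, 3.5), Loop.make("chr1", 200, 300, 800, 900)]
        write_bedpe_loops(loops, tmp_path / "x.bedpe")
        assert read_bedpe_loops(tmp_path / "x.bedpe").loops == loops

    def test_loop_length_is_midpoint_distance(self):
        assert Loop.make("c", 0, 100, 900, 1000).length == 900


class TestTables:
    def test_gene_status_thresholds(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tchrom\tstart\tend\tstrand\tbaseMean\tlog2FC\tpadj\n"
            "g1\tchr1\t10\t500\t+\t100\t2.0\t0.01\n"
            "g2\tchr1\t600\t900\t-\t100\t-2.0\t0.01\n"
            "g3\tchr1\t1000\t1200\t+\t100\t2.0\t0.5\n"
            "g4\tchr1\t1300\t1500\t+\t100\t0.5\t0.001\n"
        )
        genes = read_gene_table(p, GenomeSpec.from_dict({"chr1": 2000}))
        assert [g.status for g in genes] == ["up", "down", "not-DE", "not-DE"]

    def test_classify_de_threshold_edge(self):
        assert classify_de(1.0, 0.049) == "up"
        assert classify_de(-1.0, 0.049) == "down"
        assert classify_de(1.0, 0.05) == "not-DE"

    def test_sv_aliases_and_validation(self, tmp_path):
        p = tmp_path / "sv.bed"
        p.write_text("chr1\t100\t500\tDUP\nchr1\t600\t800\tdeletion\n")
        svs = read_sv_table(p, GenomeSpec.from_dict({"chr1": 1000}))
        assert [s.sv_type for s in svs] == ["duplication", "deletion"]
        p.write_text("chr1\t100\t500\tWAT\n")
        with pytest.raises(FileFormatError, match="unknown SV type"):
            read_sv_table(p)

    def test_breakpoint_beyond_length_rejected(self, tmp_path):
        p = tmp_path / "bp.tsv"
        p.write_text("chromA\tposA\tchromB\tposB\nchr1\t5000\tchr2\t10\n")
        with pytest.raises(FileFormatError, match="beyond"):
            read_breakpoints(p, GenomeSpec.from_dict({"chr1": 1000, "chr2": 1000}))
        p.write_text("chromA\tposA\tchromB\tposB\nchr1\t500\tchr2\t10\n")
        assert read_breakpoints(p) == [Breakpoint("chr1", 500, "chr2", 10)]
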