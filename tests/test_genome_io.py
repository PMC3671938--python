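import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cescape import genome_io as gio


MAF_TWO_BLOCKS = """\
##maf version=1
a score=0
s ref.chr1 0 10 + 100 ACGTACGTAC
s sp2.chr5 0 10 + 100 ACGTAAGTAC

a score=0
s ref.chr1 10 10 + 100 GGGGGCCCCC
s sp2.chr5 10 10 + 100 GGGGGCCCCC
"""


class TestReadAlignment:
    def test_gap_projection(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text("##maf version=1\n"
                     "a\ns ref.c 0 3 + 10 ACG\ns o.c 0 2 + 10 A-G\n")
        aln = gio.read_alignment(p, "ref")
        assert aln.seq("ref") == "ACG"
        assert aln.seq("o") == "A-G"

    def test_reference_gap_column_dropped(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text("##maf version=1\n"
                     "a\ns ref.c 0 3 + 10 A-CG\ns o.c 0 4 + 10 ATCG\n")
        aln = gio.read_alignment(p, "ref")
        assert aln.length == 3
        assert aln.seq("ref") == "ACG"
        assert aln.seq("o") == "ACG"

    def test_contiguous_blocks(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text(MAF_TWO_BLOCKS)
        aln = gio.read_alignment(p, "ref")
        assert aln.length == 20
        assert aln.seq("ref") == "ACGTACGTACGGGGGCCCCC"

    def test_missing_species_filled_with_n(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text("##maf version=1\n"
                     "a\ns ref.c 0 3 + 10 ACG\ns o.c 0 3 + 10 ACG\n\n"
                     "a\ns ref.c 3 3 + 10 TTT\n")
        aln = gio.read_alignment(p, "ref")
        assert aln.seq("o") == "ACGNNN"

    def test_missing_refspecies_fatal(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text("##maf version=1\na\ns x.c 0 3 + 10 ACG\n")
        with pytest.raises(ValueError, match="refspecies"):
            gio.read_alignment(p, "ref")

    def test_overlapping_blocks_fatal(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text("##maf version=1\n"
                     "a\ns ref.c 0 5 + 10 ACGTA\n\n"
                     "a\ns ref.c 3 5 + 10 TACGT\n")
        with pytest.raises(ValueError, match="overlap"):
            gio.read_alignment(p, "ref")

    def test_write_read_roundtrip(self, tmp_path):
        p = tmp_path / "a.maf"
        p.write_text(MAF_TWO_BLOCKS)
        aln = gio.read_alignment(p, "ref")
        q = tmp_path / "b.maf"
        gio.write_alignment(aln, q)
        aln2 = gio.read_alignment(q, "ref")
        assert aln2.species == aln.species
        assert (aln2.codes == aln.codes).all()


class TestMask:
    def test_basic_exclusion(self):
        mask = gio.GenomeMask.from_tuples([("c", 10, 20, "exon")])
        assert gio.apply_mask({5, 15}, mask, chrom="c") == {5}

    def test_empty_mask_identity(self):
        mask = gio.GenomeMask()
        assert gio.apply_mask({1, 2, 3}, mask, chrom="c") == {1, 2, 3}

    def test_matches_bruteforce(self, rng):
        ivs = []
        for _ in range(50):
            s = int(rng.integers(0, 5000))
            ivs.append(("c", s, s + int(rng.integers(1, 100)),
                        "exon" if rng.random() < 0.5 else "repeat"))
        mask = gio.GenomeMask.from_tuples(ivs)
        pos = rng.integers(0, 5200, size=1000)
        expected = {int(p) for p in pos
                    if not any(s <= p < e for _, s, e, _ in ivs)}
        assert gio.apply_mask(set(pos.tolist()), mask, chrom="c") == expected

    def test_unknown_chromosome_warns_and_drops(self):
        mask = gio.GenomeMask.from_tuples([("c1", 0, 10, "exon")])
        with pytest.warns(UserWarning, match="absent from mask"):
            out = gio.apply_mask({("c1", 50), ("cX", 5)}, mask)
        assert out == {("c1", 50)}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=20),
           st.sets(st.integers(0, 600), max_size=50))
    def test_masking_idempotent(self, ivs, positions):
        mask = gio.GenomeMask.from_tuples(
            [("c", s, s + w, "exon") for s, w in ivs])
        once = gio.apply_mask(positions, mask, chrom="c")
        assert gio.apply_mask(once, mask, chrom="c") == once


class TestSnpTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "s.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        return p

    def test_major_minor_assignment(self, tmp_path):
        p = self._write(tmp_path, [dict(chrom="c", pos=1, allele1="A",
                                        allele2="G", freq1=0.7, coverage=20)])
        t = gio.read_snp_table(p)
        assert t.major[0] == "A" and t.minor[0] == "G"
        assert t.maf[0] == pytest.approx(0.3)

    def test_tie_goes_to_allele1(self, tmp_path):
        p = self._write(tmp_path, [dict(chrom="c", pos=1, allele1="C",
                                        allele2="T", freq1=0.5, coverage=20)])
        t = gio.read_snp_table(p)
        assert t.major[0] == "C"

    def test_bad_freq_fatal(self, tmp_path):
        p = self._write(tmp_path, [dict(chrom="c", pos=1, allele1="A",
                                        allele2="G", freq1=1.2, coverage=20)])
        with pytest.raises(ValueError, match="freq1"):
            gio.read_snp_table(p)

    def test_duplicate_position_fatal(self, tmp_path):
        rows = [dict(chrom="c", pos=1, allele1="A", allele2="G",
                     freq1=0.6, coverage=20)] * 2
        p = self._write(tmp_path, rows)
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_snp_table(p)

    def test_multiallelic_retained_at_read_time(self, tmp_path):
        p = self._write(tmp_path, [dict(chrom="c", pos=1, allele1="A",
                                        allele2="G", freq1=0.6, coverage=20,
                                        n_alleles=3)])
        t = gio.read_snp_table(p)
        assert len(t) == 1 and t.n_alleles[0] == 3


def test_bedgraph_roundtrip(tmp_path):
    tr = gio.SignalTrackRaw("c", 20, np.array([1.0, 2.5, -3.0]))
    p = tmp_path / "t.bedgraph"
    gio.write_bedgraph(tr, p)
    back = gio.read_bedgraph(p)["c"]
    assert np.allclose(back.values, tr.values)
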