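"""Scanner correctness against a brute-force oracle, plus strand and
window properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sodkit.core_io import GeneModel, SequenceRecord, revcomp
from sodkit.motif_scan import (
    FORWARD,
    REVERSE,
    build_count_table,
    compile_motif,
    default_motifs,
    extract_upstream,
    load_motifs,
    scan_sequence,
)
from sodkit.synthetic import brute_force_hits

IUPAC = "ACGTRYSWKMBDHVN"


class TestCompile:
    def test_xre_position_sets(self):
        m = compile_motif("XRE", "TGCRCNC")
        assert m.position_sets[3] == frozenset("AG")
        assert m.position_sets[5] == frozenset("ACGT")

    def test_exact_pattern(self):
        m = compile_motif("x", "ACGT")
        assert [len(s) for s in m.position_sets] == [1, 1, 1, 1]

    def test_bad_character_position(self):
        with pytest.raises(ValueError, match="position 3"):
            compile_motif("bad", "ACJT")

    def test_empty_pattern(self):
        with pytest.raises(ValueError):
            compile_motif("e", "")


ARE = compile_motif("ARE", "TGACNNNGC")
HARE = compile_motif("hARE", "TGACNNN")


class TestScan:
    def test_forward_instantiation(self):
        hits = scan_sequence("TGACAAAGC", ARE, ("+",))
        assert len(hits) == 1 and hits[0].start == 0 and hits[0].strand == "+"

    def test_reverse_reported_in_forward_coordinates(self):
        hits = scan_sequence("GCTTTGTCA", ARE, ("-",))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (0, "-")
        assert hits[0].matched_seq == "GCTTTGTCA"

    def test_overlapping_hits_all_reported(self):
        hits = scan_sequence("TGACTGACAAA", HARE, ("+",))
        assert [h.start for h in hits] == [0, 4]

    def test_window_shorter_than_pattern_is_empty(self):
        assert scan_sequence("TGA", ARE) == []

    def test_subject_n_matches_only_pattern_n(self):
        # masked genome bases cannot satisfy constrained positions
        assert scan_sequence("NNACAAAGC", ARE, ("+",)) == []
        assert len(scan_sequence("TGACNNNGC", ARE, ("+",))) == 1

    def test_invalid_window_character(self):
        with pytest.raises(ValueError):
            scan_sequence("ACGJ", HARE)

    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=300),
        st.text(alphabet=IUPAC, min_size=2, max_size=9),
    )
    def test_oracle_equivalence(self, window, pattern):
        motif = compile_motif("m", pattern)
        oracle = brute_force_hits(window, motif) if window else {FORWARD: [], REVERSE: []}
        hits = scan_sequence(window, motif) if window else []
        got_f = [h.start for h in hits if h.strand == "+"]
        got_r = [h.start for h in hits if h.strand == "-"]
        assert got_f == oracle[FORWARD]
        assert got_r == oracle[REVERSE]

    @given(st.text(alphabet="ACGT", min_size=9, max_size=120))
    def test_strand_symmetry(self, window):
        """Scanning the reverse complement with strands swapped mirrors
        the hit multiset."""
        fwd = scan_sequence(window, ARE)
        rc = scan_sequence(revcomp(window), ARE)
        n = len(window)
        mirrored = sorted(
            (n - (h.start + h.length), "+" if h.strand == "-" else "-") for h in rc
        )
        assert sorted((h.start, h.strand) for h in fwd) == mirrored

    @given(
        st.text(alphabet="ACGT", min_size=7, max_size=80),
        st.text(alphabet="ACGT", min_size=1, max_size=20),
    )
    def test_appending_bases_never_removes_hits(self, window, extra):
        before = {(h.start, h.strand) for h in scan_sequence(window, HARE)}
        after = {(h.start, h.strand) for h in scan_sequence(window + extra, HARE)}
        assert before <= after


def _toy_locus():
    # 30 nt promoter + 9 nt CDS on the plus strand
    seq = "A" * 21 + "TGACAAAGC" + "ATGAAATAA" + "C" * 10
    rec = SequenceRecord("s", seq)
    gene = GeneModel("g", "s", "+", exons=((30, 39),), cds=(30, 39))
    return rec, gene


class TestUpstream:
    def test_plus_strand_window(self):
        rec, gene = _toy_locus()
        assert extract_upstream(rec, gene, 9) == "TGACAAAGC"
        assert extract_upstream(rec, gene, 30) == rec.seq[:30]

    def test_truncation_warns(self, caplog):
        rec, gene = _toy_locus()
        with caplog.at_level("WARNING"):
            win = extract_upstream(rec, gene, 2000)
        assert len(win) == 30
        assert "truncated" in caplog.text

    def test_minus_strand_is_revcomp_of_downstream(self):
        # same biology placed on the minus strand of the mirrored scaffold
        rec, gene = _toy_locus()
        L = len(rec.seq)
        rc = SequenceRecord("s", revcomp(rec.seq))
        flipped = GeneModel(
            "g", "s", "-",
            exons=tuple(sorted((L - e, L - s) for s, e in gene.exons)),
            cds=(L - gene.cds[1], L - gene.cds[0]),
        )
        assert extract_upstream(rc, flipped, 9) == "TGACAAAGC"

    def test_scaffold_mismatch(self):
        rec, gene = _toy_locus()
        other = SequenceRecord("other", "ACGT")
        with pytest.raises(ValueError, match="scaffold"):
            extract_upstream(other, gene, 10)


class TestCountTable:
    def test_layout_motif_major_forward_first(self):
        rec, gene = _toy_locus()
        table = build_count_table([rec], [gene], window_nt=30)
        assert list(table.columns) == [
            ("ARE", FORWARD), ("ARE", REVERSE),
            ("hARE", FORWARD), ("hARE", REVERSE),
            ("XRE", FORWARD), ("XRE", REVERSE),
        ]
        # the planted ARE also counts as a forward hARE (independence)
        assert table.loc["g", ("ARE", FORWARD)] == 1
        assert table.loc["g", ("hARE", FORWARD)] == 1

    def test_all_a_promoter_is_zero(self):
        rec = SequenceRecord("s", "A" * 40 + "ATGTAA")
        gene = GeneModel("g", "s", "+", exons=((40, 46),), cds=(40, 46))
        assert (build_count_table([rec], [gene], window_nt=40) == 0).all().all()

    def test_matches_brute_force_on_random_loci(self, rng):
        motifs = default_motifs()
        records, genes = [], []
        for i in range(5):
            promoter = "".join(rng.choice(list("ACGT"), size=400))
            seq = promoter + "ATGAAATAA"
            records.append(SequenceRecord(f"s{i}", seq))
            genes.append(
                GeneModel(f"g{i}", f"s{i}", "+", exons=((400, 409),), cds=(400, 409))
            )
        table = build_count_table(records, genes, window_nt=400)
        for rec, gene in zip(records, genes):
            window = rec.seq[:400]
            for m in motifs:
                oracle = brute_force_hits(window, m)
                assert table.loc[gene.gene_id, (m.name, FORWARD)] == len(oracle[FORWARD])
                assert table.loc[gene.gene_id, (m.name, REVERSE)] == len(oracle[REVERSE])


class TestMotifConfig:
    def test_toml(self, tmp_path):
        p = tmp_path / "m.toml"
        p.write_text('[motifs]\nARE = "TGACNNNGC"\nMRE = "TGCRCNC"\n')
        motifs = load_motifs(p)
        assert [m.name for m in motifs] == ["ARE", "MRE"]

    def test_tsv(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("hARE\tTGACNNN\nXRE\tTGCRCNC\n")
        assert [m.pattern for m in load_motifs(p)] == ["TGACNNN", "TGCRCNC"]

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("a\tACGT\na\tTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_motifs(p)
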