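"""Generator contracts: determinism, truth-ledger exactness, and
statistical shape of the simulated datasets."""

import json

import numpy as np
import pytest

from sodkit.core_io import read_fasta, read_gene_models
from sodkit.gene_architecture import summarize_architecture
from sodkit.motif_scan import FORWARD, REVERSE, build_count_table, default_motifs
from sodkit.synthetic import (
    ArchitecturePlan,
    brute_force_counts,
    default_locus_plans,
    generate_activity_dataset,
    generate_bundle,
    generate_locus,
    generate_qpcr_dataset,
    generate_survival_dataset,
)


class TestLocus:
    def test_truth_equals_brute_force_rescan(self):
        locus = generate_locus(1, motif_plan={"hARE": (2, 1), "XRE": (1, 0)})
        window = locus.record.seq[
            locus.gene.cds[0] - locus.truth["window_nt"] : locus.gene.cds[0]
        ]
        assert brute_force_counts(window, default_motifs()) == locus.truth["motif_counts"]

    def test_zero_plan_scans_zero(self):
        locus = generate_locus(2, motif_plan={})
        counts = locus.truth["motif_counts"]
        assert all(v == 0 for m in counts.values() for v in m.values())

    def test_same_seed_is_byte_identical(self):
        a = generate_locus(3, motif_plan={"ARE": (1, 1)})
        b = generate_locus(3, motif_plan={"ARE": (1, 1)})
        assert a.record.seq == b.record.seq
        assert a.gene == b.gene
        assert a.truth == b.truth

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_locus(1, motif_plan={"hARE": (100, 100)}, window_nt=200)

    def test_scanner_recovers_truth_on_randomised_plans(self, rng):
        """Planted-motif recovery across random plans, both strands."""
        for i in range(15):
            plan = {
                "ARE": (int(rng.integers(0, 2)), int(rng.integers(0, 2))),
                "hARE": (int(rng.integers(0, 4)), int(rng.integers(0, 4))),
                "XRE": (int(rng.integers(0, 3)), int(rng.integers(0, 3))),
            }
            strand = "+" if i % 2 == 0 else "-"
            locus = generate_locus(100 + i, motif_plan=plan, strand=strand)
            table = build_count_table([locus.record], [locus.gene], window_nt=1000)
            for name, by_ori in locus.truth["motif_counts"].items():
                assert table.loc[locus.gene.gene_id, (name, FORWARD)] == by_ori[FORWARD]
                assert table.loc[locus.gene.gene_id, (name, REVERSE)] == by_ori[REVERSE]

    def test_architecture_recovers_truth(self):
        for strand in ("+", "-"):
            locus = generate_locus(
                21,
                architecture_plan=ArchitecturePlan(
                    utr5_nt=120, orf_nt=210, utr3_nt=80,
                    introns=((50, 40), (200, 30)), polya_positions=(370, 390),
                ),
                strand=strand,
            )
            arch = summarize_architecture(locus.record, locus.gene)
            t = locus.truth["architecture"]
            assert arch.orf_nt == t["orf_nt"]
            assert arch.protein_aa == t["protein_aa"]
            assert arch.utr5_nt == t["utr5_nt"]
            assert arch.utr3_nt == t["utr3_nt"]
            assert arch.n_exons == t["n_exons"]
            assert arch.n_introns == t["n_introns"]
            assert arch.utr_introns == t["utr_introns"]
            assert arch.polya_positions == t["polya_positions"]
            assert arch.mw_kda == pytest.approx(t["mw_kda"], rel=1e-12)
            assert arch.flags == []


class TestQpcr:
    def test_noiseless_fold_exact(self):
        ct, truth = generate_qpcr_dataset(1, {"g": {("hkBt1", "Bt1"): 4.0}}, noise_sd=0.0)
        assert truth["g"]["hkBt1/Bt1"] == 4.0
        from sodkit.qpcr import relative_expression

        rq = relative_expression(ct, "g").set_index(["priming", "challenge"])
        assert rq.loc[("hkBt1", "Bt1"), "rq_mean"] == pytest.approx(4.0)

    def test_design_shape(self):
        ct, _ = generate_qpcr_dataset(2, {"g": {}}, n_bio=3, n_tech=2)
        # 9 cells x 3 reps x 2 tech x 2 genes (target + reference)
        assert len(ct) == 9 * 3 * 2 * 2
        assert set(ct["gene"]) == {"g", "rp49"}

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="unknown treatment"):
            generate_qpcr_dataset(1, {"g": {("bogus", "Bt1"): 2.0}})

    def test_determinism(self):
        a, _ = generate_qpcr_dataset(7, {"g": {("PBS", "PBS"): 2.0}})
        b, _ = generate_qpcr_dataset(7, {"g": {("PBS", "PBS"): 2.0}})
        assert a.equals(b)


class TestSurvival:
    def test_extreme_probabilities(self):
        df, _ = generate_survival_dataset(1, {(p, c): 1.0 for p in ("naive", "PBS", "hkBt1")
                                              for c in ("naive", "PBS", "Bt1")})
        assert (df["alive"] == df["total"]).all()

    def test_binomial_concentration(self):
        df, _ = generate_survival_dataset(
            5, {("naive", "Bt1"): 0.5}, n_per_cell=10_000, n_experiments=1
        )
        row = df[(df.priming == "naive") & (df.challenge == "Bt1")].iloc[0]
        assert abs(row.alive / row.total - 0.5) < 0.02

    def test_determinism(self):
        a, _ = generate_survival_dataset(9, {("naive", "Bt1"): 0.7})
        b, _ = generate_survival_dataset(9, {("naive", "Bt1"): 0.7})
        assert a.equals(b)


class TestBundle:
    def test_files_and_truth(self, bundle):
        out, truth = bundle
        for name in ("genome.fasta", "genes.gff3", "ct.csv", "assay.csv",
                     "lowry.csv", "survival.csv", "truth.json"):
            assert (out / name).exists(), name
        on_disk = json.loads((out / "truth.json").read_text())
        assert set(on_disk["loci"]) == {"soda", "sodb", "sodc"}

    def test_default_loci_reproduce_published_count_table(self, bundle):
        out, _ = bundle
        table = build_count_table(read_fasta(out / "genome.fasta"),
                                  read_gene_models(out / "genes.gff3"))
        expected = {
            "soda": [0, 1, 6, 3, 1, 0],
            "sodb": [0, 0, 0, 2, 0, 0],
            "sodc": [0, 0, 2, 3, 0, 0],
        }
        for gene, row in expected.items():
            assert table.loc[gene].tolist() == row

    def test_default_architectures_match_plans(self, bundle):
        out, truth = bundle
        genomes = {r.id: r for r in read_fasta(out / "genome.fasta")}
        for gene in read_gene_models(out / "genes.gff3"):
            arch = summarize_architecture(genomes[gene.seq_id], gene)
            t = truth["loci"][gene.gene_id]["architecture"]
            assert arch.orf_nt == t["orf_nt"]
            assert arch.utr5_nt == t["utr5_nt"]
            assert arch.utr3_nt == t["utr3_nt"]
            assert arch.polya_positions == t["polya_positions"]
        plans = default_locus_plans()
        assert truth["loci"]["soda"]["architecture"]["polya_positions"] == [879]
        assert plans["sodb"]["architecture_plan"].utr5_nt == 2290
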