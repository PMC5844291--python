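"""Classification, protein-effect naming and recurrence filtering."""

import random

import numpy as np
import pytest
from Bio.Seq import Seq

from poolrevert import (AnchorIntegrityWarning, AnnotationSet, ClassifiedVariant,
                        ClassifierParams, ReferenceGenome, VariantCall,
                        annotate_effect, classify_calls, recurrence_filter)
from poolrevert.simulate import Gene


def vc(pos, ref, alt, af, depth=300, chrom="chr1", mixture="mix0"):
    return VariantCall(chrom, pos, ref, alt, depth, int(round(af * depth)),
                       1e-40, 1e-35, mixture)


TS = ("chr1", 5000, "A")


@pytest.fixture
def params():
    return ClassifierParams(TS)


class TestClassifyCalls:
    def test_category_assignment(self, params):
        calls = [
            vc(5000, "G", "A", 0.98),           # anchor
            vc(800, "C", "T", 0.11),            # suppressor candidate
            vc(1200, "T", "G", 1.0),            # parental (by VCF match)
            vc(2000, "G", "C", 0.95),           # fixed but not parental
            vc(3000, "A", "G", 0.01),           # below floor
        ]
        parental = [("chr1", 1200, "T", "G")]
        out = classify_calls(calls, params, parental)
        cats = {c.call.pos: c.category for c in out}
        assert cats == {5000: "anchor_ts", 800: "suppressor_candidate",
                        1200: "background_common", 2000: "background_common",
                        3000: "subthreshold"}

    def test_partition_is_exhaustive_and_exclusive(self, params):
        rng = random.Random(1)
        calls = [vc(5000, "G", "A", 0.99)] + [
            vc(i * 10 + 1, "A", "C", rng.random()) for i in range(50)]
        out = classify_calls(calls, params, [])
        assert len(out) == len(calls)
        valid = {"anchor_ts", "background_common", "suppressor_candidate",
                 "subthreshold"}
        assert {c.category for c in out} <= valid

    def test_anchor_absent_warns(self, params):
        with pytest.warns(AnchorIntegrityWarning, match="anchor absent"):
            classify_calls([vc(800, "C", "T", 0.11)], params, [])

    def test_low_af_anchor_not_anchor_and_warns(self, params):
        with pytest.warns(AnchorIntegrityWarning):
            out = classify_calls([vc(5000, "G", "A", 0.5)], params, [])
        assert out[0].category == "suppressor_candidate"

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            ClassifierParams(TS, anchor_min_af=0.7, background_min_af=0.8)


def build_cds_genome(codons, strand="+", pad=30):
    """Genome holding one gene with the given codon list (start..stop)."""
    cds = "".join(codons)
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    seq = "A" * pad + cds + "A" * pad
    genome = ReferenceGenome({"chr1": seq})
    gene = Gene("geneX", "chr1", pad + 1, pad + len(cds), strand)
    return genome, AnnotationSet([gene])


class TestAnnotateEffect:
    def test_missense_g338d(self):
        codons = ["ATG"] + ["GCT"] * 336 + ["GGC"] + ["GCT"] * 10 + ["TAA"]
        genome, ann = build_cds_genome(codons)
        pos = 30 + 3 * 337 + 2  # middle base of codon 338
        assert genome.base("chr1", pos) == "G"
        gid, eff = annotate_effect(vc(pos, "G", "A", 0.1), ann, genome)
        assert (gid, eff) == ("geneX", "G338D")

    def test_nonsense_q64stop(self):
        codons = ["ATG"] + ["GCT"] * 62 + ["CAA"] + ["GCT"] * 5 + ["TAA"]
        genome, ann = build_cds_genome(codons)
        pos = 30 + 3 * 63 + 1  # first base of codon 64
        gid, eff = annotate_effect(vc(pos, "C", "T", 0.1), ann, genome)
        assert (gid, eff) == ("geneX", "Q64Stop")

    def test_silent_third_position(self):
        codons = ["ATG", "TTA", "TAA"]
        genome, ann = build_cds_genome(codons)
        pos = 30 + 6  # third base of codon 2: TTA -> TTG, Leu -> Leu
        gid, eff = annotate_effect(vc(pos, "A", "G", 0.1), ann, genome)
        assert (gid, eff) == ("geneX", "silent")

    def test_minus_strand_missense(self):
        codons = ["ATG", "GGC", "TAA"]  # G at residue 2
        genome, ann = build_cds_genome(codons, strand="-")
        # genomic revcomp of GGC codon sits at positions 34..36 (TTA GCC CAT)
        # coding middle base of codon 2 is genomic position 35 (C on - strand)
        gid, eff = annotate_effect(vc(35, genome.base("chr1", 35), "T", 0.1),
                                   ann, genome)
        # GGC -> GAC on the coding strand: genomic C->T is coding G->A
        assert (gid, eff) == ("geneX", "G2D")

    def test_insertions_and_intergenic(self):
        codons = ["ATG", "GGC", "TAA"]
        genome, ann = build_cds_genome(codons)
        assert annotate_effect(vc(33, "G", "GAT", 0.1), ann, genome) == \
            ("geneX", "ins(frameshift)")
        assert annotate_effect(vc(33, "G", "GATT", 0.1), ann, genome)[1] == \
            "ins(in-frame)"
        assert annotate_effect(vc(5, "A", "C", 0.1), ann, genome) == \
            ("intergenic", "intergenic")

    def test_ref_disagreement_rejected(self):
        genome, ann = build_cds_genome(["ATG", "GGC", "TAA"])
        with pytest.raises(ValueError, match="disagreement"):
            annotate_effect(vc(32, "C", "A", 0.1), ann, genome)

    def test_agrees_with_full_translation_oracle(self, toy_genome,
                                                 toy_annotation):
        """Oracle: translate the whole mutated CDS with Bio.Seq and diff the
        protein; must agree with the codon-arithmetic annotator."""
        rng = np.random.default_rng(51)
        checked = 0
        while checked < 1000:
            gene = toy_annotation.genes[int(rng.integers(8))]
            pos = int(rng.integers(gene.start, gene.end + 1))
            ref = toy_genome.base("chr1", pos)
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            seq = toy_genome.sequence("chr1")
            mutated = seq[:pos - 1] + alt + seq[pos:]
            def protein(s):
                cds = s[gene.start - 1:gene.end]
                if gene.strand == "-":
                    cds = str(Seq(cds).reverse_complement())
                return str(Seq(cds).translate())
            p_ref, p_alt = protein(seq), protein(mutated)
            diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
            if not diffs:
                expected = "silent"
            else:
                (i,) = diffs
                expected = (f"{p_ref[i]}{i + 1}Stop" if p_alt[i] == "*"
                            else f"{p_ref[i]}{i + 1}{p_alt[i]}")
            gid, eff = annotate_effect(vc(pos, ref, alt, 0.1), toy_annotation,
                                       toy_genome)
            assert gid == gene.gene_id
            assert eff == expected, (gene, pos, ref, alt)
            checked += 1


def candidate(gene_ann, pos, ref, alt, effect, mixture, gene_id):
    return ClassifiedVariant(vc(pos, ref, alt, 0.1, mixture=mixture),
                             "suppressor_candidate", gene_id, effect)


class TestRecurrenceFilter:
    @pytest.fixture
    def saga_annotation(self):
        genes = [Gene(g, "chr1", 1000 * i + 1, 1000 * i + 300, "+")
                 for i, g in enumerate(
                     ["htb1", "ubp8", "sgf11", "sus1", "gcn5", "hfi1"])]
        cmap = {g: "SAGA" for g in ["ubp8", "sgf11", "sus1", "gcn5", "hfi1"]}
        return AnnotationSet(genes, cmap)

    def test_two_event_gene_selected(self, saga_annotation):
        cvs = [candidate(saga_annotation, 2100, "C", "T", "Q64Stop", "mix0", "sgf11"),
               candidate(saga_annotation, 2140, "G", "A", "C77Y", "mix1", "sgf11")]
        reports = recurrence_filter(cvs, saga_annotation, threshold=2)
        gene_reports = [r for r in reports if r.unit == "gene"]
        assert len(gene_reports) == 1
        r = gene_reports[0]
        assert (r.unit_id, r.n_events, r.n_distinct_variants) == ("sgf11", 2, 2)
        assert sorted(d for _, d in r.events) == ["C77Y", "Q64Stop"]

    def test_identical_substitution_across_mixtures_counts_twice(self,
                                                                 saga_annotation):
        cvs = [candidate(saga_annotation, 2100, "C", "T", "Q64Stop", m, "sgf11")
               for m in ("mix0", "mix1")]
        (r,) = [r for r in recurrence_filter(cvs, saga_annotation, 2)
                if r.unit == "gene"]
        assert r.n_events == 2 and r.n_distinct_variants == 1

    def test_complex_aggregation_over_five_genes(self, saga_annotation):
        cvs = [candidate(saga_annotation, 1000 * i + 100, "A", "C", f"X{i}Y",
                         f"mix{i % 3}", g)
               for i, g in enumerate(["ubp8", "sgf11", "sus1", "gcn5", "hfi1"], 1)]
        reports = recurrence_filter(cvs, saga_annotation, threshold=2)
        assert [r.unit for r in reports] == ["complex"]
        r = reports[0]
        assert r.unit_id == "SAGA" and r.n_events == 5
        assert set(r.genes) == {"ubp8", "sgf11", "sus1", "gcn5", "hfi1"}

    def test_single_gene_cannot_form_a_complex_unit(self, saga_annotation):
        cvs = [candidate(saga_annotation, 2100 + i, "C", "T", f"Q{i}Stop",
                         f"mix{i}", "sgf11") for i in range(3)]
        reports = recurrence_filter(cvs, saga_annotation, threshold=2)
        assert [r.unit for r in reports] == ["gene"]

    def test_intragenic_flagged(self, saga_annotation):
        cvs = [candidate(saga_annotation, 100 + i, "A", "G", f"M{i}V",
                         f"mix{i}", "htb1") for i in range(2)]
        (r,) = recurrence_filter(cvs, saga_annotation, 2, ts_gene="htb1")
        assert r.intragenic

    def test_invariant_to_mixture_ordering(self, saga_annotation):
        cvs = [candidate(saga_annotation, 1000 * i + 50, "A", "C", f"E{i}K",
                         f"mix{i % 2}", g)
               for i, g in enumerate(["ubp8", "ubp8", "sgf11", "sgf11"], 1)]
        fwd = recurrence_filter(cvs, saga_annotation, 2)
        rev = recurrence_filter(cvs[::-1], saga_annotation, 2)
        assert fwd == rev

    def test_empty_input_valid(self, saga_annotation):
        assert recurrence_filter([], saga_annotation, 2) == []
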