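"""Aligner correctness: k-mer index, brute-force Hamming oracle, pileup
conservation and SAM round-tripping."""

import numpy as np
import pytest

from poolrevert import (CallerParams, ReferenceGenome, build_index, call_mixture,
                        map_read, map_read_set, pileup, read_sam, write_sam)
from poolrevert._dna import encode, revcomp


def brute_force_best(genome: ReferenceGenome, seq: str):
    """Oracle: best ungapped placement by scanning every offset and strand."""
    best = None  # (mm, chrom, pos, strand)
    ties = 0
    for chrom in genome.chrom_names:
        ref = genome.codes(chrom)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            q = encode(s)
            for start in range(ref.size - q.size + 1):
                mm = int(np.count_nonzero(ref[start:start + q.size] != q))
                if best is None or mm < best[0]:
                    best = (mm, chrom, start + 1, strand)
                    ties = 0
                elif mm == best[0]:
                    ties += 1
    return best, ties


@pytest.fixture(scope="module")
def small_genome():
    from poolrevert import make_genome
    return make_genome(5000, 0.4, seed=31)


@pytest.fixture(scope="module")
def small_index(small_genome):
    return build_index(small_genome, k=15)


class TestKmerIndex:
    def test_hand_checkable_repeat_lookup(self):
        kmer = "ACGTTGCACGTA"[:11]
        genome = ReferenceGenome({"c": kmer + "TT" + kmer})
        idx = build_index(genome, k=11)
        assert idx.lookup(kmer) == [("c", 1), ("c", 14)]

    def test_absent_kmer_empty(self):
        genome = ReferenceGenome({"c": "ACGTACGTACGTACGT"})
        idx = build_index(genome, k=11)
        assert idx.lookup("T" * 11) == []

    def test_rebuild_invariance(self, small_genome):
        i1 = build_index(small_genome, 15)
        i2 = build_index(small_genome, 15)
        probe = small_genome.sequence("chr1")[100:115]
        assert i1.lookup(probe) == i2.lookup(probe)

    def test_k_out_of_range(self, small_genome):
        for k in (5, 40):
            with pytest.raises(ValueError):
                build_index(small_genome, k)


class TestMapRead:
    def test_exact_copy_maps_at_origin(self, small_genome, small_index):
        seq = small_genome.sequence("chr1")[1000:1150]
        rec = map_read("r", seq, small_index)
        assert rec.mapped and rec.pos == 1001 and rec.mismatches == 0
        # reverse-complement copy maps to the same locus, opposite strand
        rec2 = map_read("r2", revcomp(seq), small_index)
        assert rec2.mapped and rec2.pos == 1001 and rec2.strand == "-"

    def test_agrees_with_brute_force_oracle(self, small_genome, small_index):
        rng = np.random.default_rng(32)
        mapped_checked = unmapped_checked = 0
        for _ in range(60):
            start = int(rng.integers(0, 5000 - 150))
            seq = list(small_genome.sequence("chr1")[start:start + 150])
            n_mut = int(rng.integers(0, 4))
            for pos in rng.choice(150, size=n_mut, replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            (mm, chrom, pos, strand), ties = brute_force_best(small_genome, seq)
            rec = map_read("r", seq, small_index)
            if ties or mm > 15:
                assert not rec.mapped
                unmapped_checked += 1
            else:
                assert rec.mapped
                assert (rec.chrom, rec.pos, rec.strand, rec.mismatches) == \
                    (chrom, pos, strand, mm)
                mapped_checked += 1
        assert mapped_checked > 30

    def test_random_read_unmapped(self, small_index):
        rng = np.random.default_rng(33)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        assert not map_read("r", seq, small_index).mapped


class TestPileup:
    def test_three_reads_one_site(self):
        genome = ReferenceGenome({"c": "ACGTTGCAGGTCATCGATCCAGTA"})
        idx = build_index(genome, k=12)
        reads = [map_read(f"r{i}", genome.sequence("c")[0:20], idx)
                 for i in range(3)]
        pp = pileup(reads, genome)
        assert pp.site("c", 3) == {"A": 0, "C": 0, "G": 3, "T": 0}
        assert int(pp.depth("c")[:20].min()) == 3

    def test_base_conservation(self, small_genome, small_index):
        rng = np.random.default_rng(34)
        recs = []
        for _ in range(100):
            s = int(rng.integers(0, 4800))
            recs.append(map_read("r", small_genome.sequence("chr1")[s:s + 150],
                                 small_index))
        pp = pileup(recs, small_genome)
        assert pp.total_depth == sum(r.length for r in recs if r.mapped)

    def test_noiseless_nonref_only_at_planted_sites(self, toy_genome,
                                                    toy_screen,
                                                    noiseless_reads):
        idx = build_index(toy_genome, 15)
        alns = map_read_set(noiseless_reads, idx)
        assert sum(a.mapped for a in alns) / len(alns) >= 0.99
        pp = pileup(alns, toy_genome)
        mat = pp.counts["chr1"]
        ref_counts = mat[np.arange(mat.shape[0]), toy_genome.codes("chr1")]
        nonref_sites = set(np.nonzero(mat.sum(axis=1) - ref_counts)[0] + 1)
        planted = {m.pos for m in toy_screen.truth}
        assert nonref_sites == planted

    def test_calls_match_truth_noiseless(self, toy_genome, toy_screen,
                                         noiseless_reads):
        """Noiseless mixture: the caller recovers exactly the planted sites."""
        idx = build_index(toy_genome, 15)
        pp = pileup(map_read_set(noiseless_reads, idx), toy_genome)
        calls = call_mixture(pp, toy_genome, CallerParams(error_rate=1e-4))
        assert {(c.chrom, c.pos, c.alt) for c in calls} == \
            {(m.chrom, m.pos, m.alt) for m in toy_screen.truth}


class TestSamIO:
    def test_roundtrip_identical_pileup(self, small_genome, small_index,
                                        tmp_path):
        rng = np.random.default_rng(35)
        recs = []
        for i in range(200):
            s = int(rng.integers(0, 4800))
            seq = small_genome.sequence("chr1")[s:s + 150]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            recs.append(map_read(f"r{i}", seq, small_index))
        sam = tmp_path / "x.sam"
        write_sam(recs, small_genome, sam)
        back = read_sam(sam, small_genome)
        p1 = pileup(recs, small_genome)
        p2 = pileup(back, small_genome)
        assert np.array_equal(p1.counts["chr1"], p2.counts["chr1"])

    def test_unmapped_records_skipped(self, small_genome, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:5000\n"
            "q1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tFFFF\n"
            "q2\t0\tchr1\t101\t60\t4M\t*\t0\t0\tACGT\tFFFF\n")
        recs = read_sam(sam, small_genome)
        assert [r.read_id for r in recs] == ["q2"]
        assert recs[0].pos == 101

    def test_indel_cigar_coordinate_walking(self, small_genome, tmp_path):
        seq = small_genome.sequence("chr1")
        read = seq[100:110] + "AAAA" + seq[110:120]  # 10M4I10M
        sam = tmp_path / "i.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:5000\n"
            f"q1\t0\tchr1\t101\t60\t10M4I10M\t*\t0\t0\t{read}\tF" + "F" * 23 + "\n")
        (rec,) = read_sam(sam, small_genome)
        pp = pileup([rec], small_genome)
        # the 4 inserted bases are not tallied; ref sites 101..120 have depth 1
        assert int(pp.depth("chr1")[100:120].sum()) == 20
        assert pp.total_depth == 20

    def test_header_reference_mismatch_errors(self, small_genome, tmp_path):
        sam = tmp_path / "b.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:5000\n")
        with pytest.raises(ValueError, match="chrX"):
            read_sam(sam, small_genome)
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:4999\n")
        with pytest.raises(ValueError, match="length"):
            read_sam(sam, small_genome)
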