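"""Ungapped k-mer seed-and-extend read mapping and pileup construction.

This is a deliberately minimal mapper for small simulated genomes: it seeds
reads on non-overlapping exact k-mers, extends ungapped on both strands,
scores by Hamming distance, and drops ambiguous (multi-best) placements so
repeats cannot fabricate allele counts. Real or indel-containing data enters
the pipeline as standard SAM instead, via read_sam.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from ._dna import BASES, decode, encode, revcomp_codes
from .simulate import PairedReadSet, ReferenceGenome

log = logging.getLogger(__name__)

__all__ = ["AlignmentRecord", "KmerIndex", "PooledPileup", "build_index",
           "map_read", "map_read_set", "pileup", "read_sam", "write_sam"]


@dataclass
class AlignmentRecord:
    """One placed (or unplaced) read.

    ``codes`` holds the read bases oriented to the forward reference strand,
    so pileup can tally them directly. ``ref_offsets`` is only set for SAM
    ingested records whose CIGAR makes the alignment non-contiguous.
    """
    read_id: str
    chrom: str | None
    pos: int | None          # 1-based leftmost reference position
    strand: str | None
    mismatches: int
    mapped: bool
    codes: np.ndarray | None = None
    ref_offsets: np.ndarray | None = None  # 0-based ref positions per base

    @property
    def length(self) -> int:
        return 0 if self.codes is None else int(self.codes.size)


class KmerIndex:
    """Exact k-mer -> reference position lookup over all chromosomes."""

    def __init__(self, genome: ReferenceGenome, k: int = 15):
        if not 11 <= k <= 31:
            raise ValueError("k must be within [11, 31]")
        self.genome = genome
        self.k = k
        # chromosomes are concatenated; seeds never span a boundary because
        # candidates are bounds-checked against the owning chromosome
        self._starts: list[int] = []
        self._names: list[str] = []
        parts = []
        off = 0
        table: dict[bytes, list[int]] = {}
        for chrom in genome.chrom_names:
            seq = genome.sequence(chrom).encode()
            self._starts.append(off)
            self._names.append(chrom)
            parts.append(genome.codes(chrom))
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i:i + k], []).append(off + i)
            off += len(seq)
        self._concat = np.concatenate(parts)
        self._ends = self._starts[1:] + [off]
        self._table = {kk: np.asarray(v, dtype=np.int64) for kk, v in table.items()}

    def chrom_of(self, gpos: int) -> tuple[int, str]:
        ci = bisect_right(self._starts, gpos) - 1
        return ci, self._names[ci]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (chrom, 1-based position) occurrences of a k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        out = []
        for g in self._table.get(kmer.upper().encode(), ()):
            ci, chrom = self.chrom_of(int(g))
            out.append((chrom, int(g) - self._starts[ci] + 1))
        return out


def build_index(genome: ReferenceGenome, k: int = 15) -> KmerIndex:
    return KmerIndex(genome, k)


def map_read(read_id: str, seq: str, index: KmerIndex,
             max_mismatch_fraction: float = 0.1) -> AlignmentRecord:
    """Best unique ungapped placement of one read, or an unmapped record.

    Ties between equally good placements (across positions or strands) and
    best distances above max_mismatch_fraction x length are unmapped.
    """
    k = index.k
    L = len(seq)
    if L < k:
        raise ValueError(f"read shorter than k={k}")
    fwd = encode(seq)
    queries = ((b"+", fwd), (b"-", revcomp_codes(fwd)))
    concat = index._concat
    table = index._table
    candidates: set[tuple[int, bytes]] = set()
    seed_offsets = list(range(0, L - k + 1, k))
    if seed_offsets[-1] != L - k:
        seed_offsets.append(L - k)
    for strand, codes in queries:
        qbytes = _codes_to_bytes(codes)
        for off in seed_offsets:
            for g in table.get(qbytes[off:off + k], ()):
                candidates.add((int(g) - off, strand))
    best: tuple[int, bytes] | None = None
    best_mm = L + 1
    tied = False
    for start, strand in candidates:
        if start < 0 or start + L > concat.size:
            continue
        ci, _ = index.chrom_of(start)
        if start + L > index._ends[ci]:
            continue
        codes = fwd if strand == b"+" else revcomp_codes(fwd)
        mm = int(np.count_nonzero(concat[start:start + L] != codes))
        if mm < best_mm:
            best_mm, best, tied = mm, (start, strand), False
        elif mm == best_mm and (start, strand) != best:
            tied = True
    if best is None or tied or best_mm > int(max_mismatch_fraction * L):
        return AlignmentRecord(read_id, None, None, None, best_mm, False)
    start, strand = best
    ci, chrom = index.chrom_of(start)
    codes = fwd if strand == b"+" else revcomp_codes(fwd)
    return AlignmentRecord(read_id, chrom, start - index._starts[ci] + 1,
                           strand.decode(), best_mm, True, codes)


def _codes_to_bytes(codes: np.ndarray) -> bytes:
    return np.frombuffer(BASES, dtype=np.uint8)[codes].tobytes()


def map_read_set(reads: PairedReadSet, index: KmerIndex,
                 max_mismatch_fraction: float = 0.1) -> list[AlignmentRecord]:
    """Map both mates of every pair independently."""
    out = []
    for i, name in enumerate(reads.names):
        out.append(map_read(name + "/1", decode(reads.r1[i]), index,
                            max_mismatch_fraction))
        out.append(map_read(name + "/2", decode(reads.r2[i]), index,
                            max_mismatch_fraction))
    return out


# ---------------------------------------------------------------------------
# pileup


@dataclass
class PooledPileup:
    """Per-site A/C/G/T counts over the pooled mixture, one (L, 4) array
    per chromosome, row i = 1-based position i+1."""
    counts: dict[str, np.ndarray]

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=1)

    @property
    def total_depth(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def site(self, chrom: str, pos: int) -> dict[str, int]:
        row = self.counts[chrom][pos - 1]
        return {chr(b): int(row[i]) for i, b in enumerate(BASES)}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tA\tC\tG\tT\n")
            for chrom, mat in self.counts.items():
                nz = np.nonzero(mat.sum(axis=1))[0]
                for i in nz:
                    a, c, g, t = mat[i]
                    fh.write(f"{chrom}\t{i + 1}\t{a}\t{c}\t{g}\t{t}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, genome: ReferenceGenome) -> "PooledPileup":
        counts = {c: np.zeros((genome.length(c), 4), dtype=np.int64)
                  for c in genome.chrom_names}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                chrom, pos, a, c, g, t = line.split("\t")
                counts[chrom][int(pos) - 1] = (int(a), int(c), int(g), int(t))
        return cls(counts)


def pileup(alignments: list[AlignmentRecord], genome: ReferenceGenome,
           chunk: int = 20000) -> PooledPileup:
    """Tally every aligned base into its reference coordinate.

    Reverse-strand reads were already complemented at mapping/ingestion time
    (``codes`` is forward-oriented), so counts add directly.
    """
    counts = {c: np.zeros((genome.length(c), 4), dtype=np.int64)
              for c in genome.chrom_names}
    # contiguous records grouped per (chrom, length) for vectorised accumulation
    groups: dict[tuple[str, int], list[AlignmentRecord]] = {}
    for rec in alignments:
        if not rec.mapped:
            continue
        L = genome.length(rec.chrom)
        last = rec.pos - 1 + rec.length if rec.ref_offsets is None \
            else int(rec.ref_offsets.max()) + 1
        if rec.pos < 1 or last > L:
            log.warning("alignment %s out of bounds on %s; rejected",
                        rec.read_id, rec.chrom)
            continue
        if rec.ref_offsets is None:
            groups.setdefault((rec.chrom, rec.length), []).append(rec)
        else:
            flat = counts[rec.chrom].reshape(-1)
            np.add.at(flat, rec.ref_offsets * 4 + rec.codes, 1)
    offs = {}
    for (chrom, L), recs in groups.items():
        flat = counts[chrom].reshape(-1)
        rng_off = offs.setdefault(L, np.arange(L, dtype=np.int64))
        for lo in range(0, len(recs), chunk):
            batch = recs[lo:lo + chunk]
            starts = np.array([r.pos - 1 for r in batch], dtype=np.int64)
            codes = np.stack([r.codes for r in batch])
            idx = (starts[:, None] + rng_off) * 4 + codes
            np.add.at(flat, idx.ravel(), 1)
    return PooledPileup(counts)


# ---------------------------------------------------------------------------
# SAM input/output (plain text, via pysam)


def write_sam(alignments: list[AlignmentRecord], genome: ReferenceGenome,
              path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome.chrom_names],
    }
    tid = {c: i for i, c in enumerate(genome.chrom_names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec.read_id
            if not rec.mapped:
                seg.flag = 4
                seg.query_sequence = None
                fh.write(seg)
                continue
            seg.flag = 16 if rec.strand == "-" else 0
            seg.reference_id = tid[rec.chrom]
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = 60
            seg.cigarstring = f"{rec.length}M"
            seg.query_sequence = decode(rec.codes)
            seg.set_tag("NM", rec.mismatches)
            fh.write(seg)


def read_sam(path: str | Path, genome: ReferenceGenome) -> list[AlignmentRecord]:
    """Ingest primary mapped records from a SAM file.

    The header must agree with the reference on sequence names and lengths.
    CIGAR M/=/X consume reference and query; I and S consume query only; D/N
    consume reference only, producing per-base reference offsets when the
    alignment is not one contiguous block.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for sq in fh.header.get("SQ", []):
            name, ln = sq["SN"], sq["LN"]
            if name not in genome.chrom_names:
                raise ValueError(f"SAM sequence {name!r} not in reference")
            if ln != genome.length(name):
                raise ValueError(
                    f"SAM sequence {name!r} length {ln} != reference "
                    f"{genome.length(name)}")
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            seq = seg.query_sequence
            if seq is None:
                continue
            codes = encode(seq)
            ref_pos = seg.reference_start  # 0-based
            qi = 0
            ref_offsets: list[np.ndarray] = []
            base_parts: list[np.ndarray] = []
            for op, n in seg.cigartuples or ():
                if op in (0, 7, 8):           # M, =, X
                    ref_offsets.append(np.arange(ref_pos, ref_pos + n))
                    base_parts.append(codes[qi:qi + n])
                    ref_pos += n
                    qi += n
                elif op in (1, 4):            # I, S: query only
                    qi += n
                elif op in (2, 3):            # D, N: reference only
                    ref_pos += n
                # H/P consume nothing
            if not ref_offsets:
                continue
            roff = np.concatenate(ref_offsets)
            bases = np.concatenate(base_parts)
            contiguous = roff.size == roff[-1] - roff[0] + 1
            mm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            rec = AlignmentRecord(
                seg.query_name, fh.get_reference_name(seg.reference_id),
                int(roff[0]) + 1, "-" if seg.is_reverse else "+",
                int(mm), True, bases,
                None if contiguous else roff.astype(np.int64))
            out.append(rec)
    return out
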