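"""Synthetic pooled suppressor-screen generator.

Builds every input the downstream pipeline consumes: a toy reference genome,
non-overlapping single-exon gene models, parental background variants, a set
of revertant genomes that all share one fixed temperature-sensitive (ts)
mutation and each carry private suppressor mutation(s), and paired-end reads
from an equal-proportion DNA mixture of those revertants.

The model emulates a haploid fission-yeast suppressor screen: N revertant
genomes mixed in equal amounts, so the ts anchor and parental background
variants sit at allele frequency ~1 and a private suppressor at ~1/N.
Sequencing is 2x150 bp with uniform per-base substitution error and Poisson
fragment sampling (~coverage_per_genome fold per pooled genome).

Read names record the true origin of every fragment (revertant, chromosome,
start). That is ground-truth metadata for test oracles only; nothing in the
pipeline reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import (BASES, COMPLEMENT_CODE, STOP_CODONS, decode, encode,
                   revcomp_codes)
from ._codon import codon_genomic_span, substitution_effect

__all__ = [
    "ReferenceGenome", "Gene", "AnnotationSet", "Mutation", "PoolSpec",
    "ReadSimParams", "SuppressorModel", "Screen", "PairedReadSet",
    "make_genome", "make_annotation", "make_screen", "simulate_pool_reads",
    "write_truth_table", "read_truth_table", "write_parental_vcf",
]

_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]


# ---------------------------------------------------------------------------
# domain types


class ReferenceGenome:
    """A small haploid reference: named chromosomes of A/C/G/T sequence."""

    def __init__(self, sequences: dict[str, str] | dict[str, np.ndarray]):
        if not sequences:
            raise ValueError("genome needs at least one chromosome")
        self.chrom_names: list[str] = list(sequences)
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            codes = seq.copy() if isinstance(seq, np.ndarray) else encode(seq)
            if codes.size == 0:
                raise ValueError(f"chromosome {name} is empty")
            self._codes[name] = codes

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def sequence(self, chrom: str) -> str:
        return decode(self._codes[chrom])

    def length(self, chrom: str) -> int:
        return int(self._codes[chrom].size)

    @property
    def total_length(self) -> int:
        return sum(c.size for c in self._codes.values())

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return chr(BASES[self._codes[chrom][pos - 1]])

    def copy(self) -> "ReferenceGenome":
        return ReferenceGenome({n: c for n, c in self._codes.items()})

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(self.sequence(n)), id=n, description="")
                   for n in self.chrom_names]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ReferenceGenome)
                and self.chrom_names == other.chrom_names
                and all(np.array_equal(self._codes[n], other._codes[n])
                        for n in self.chrom_names))


@dataclass(frozen=True)
class Gene:
    """Single-exon CDS gene model, 1-based inclusive coordinates, phase 0."""
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationSet:
    """Gene models plus an optional gene -> protein-complex membership map."""
    genes: list[Gene]
    complex_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.length % 3 != 0:
                raise ValueError(f"{g.gene_id}: CDS length not divisible by 3")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_at(self, chrom: str, pos: int) -> Gene | None:
        for g in self.genes:
            if g.chrom == chrom and g.start <= pos <= g.end:
                return g
        return None

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda x: (x.chrom, x.start)):
                attrs = f"ID={g.gene_id}"
                fh.write(f"{g.chrom}\tpoolrevert\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
                fh.write(f"{g.chrom}\tpoolrevert\tCDS\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n")

    @classmethod
    def read_gff3(cls, path: str | Path,
                  complex_map: dict[str, str] | None = None) -> "AnnotationSet":
        genes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9 or cols[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                genes.append(Gene(attrs["ID"], cols[0], int(cols[3]),
                                  int(cols[4]), cols[6]))
        return cls(genes, complex_map or {})


@dataclass
class Mutation:
    """A planted variant. ``ref == ""`` denotes an insertion of ``alt``
    immediately after ``pos``.

    ``owner`` is "all" for the ts anchor and parental background variants,
    or "m<mixture>:rv<revertant>" for a private suppressor.
    """
    chrom: str
    pos: int
    ref: str
    alt: str
    role: str
    owner: str

    def __post_init__(self) -> None:
        if self.role not in ("ts", "suppressor", "background"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("ts", "background") and self.owner != "all":
            raise ValueError(f"role={self.role} must have owner 'all'")
        if self.role == "suppressor" and self.owner == "all":
            raise ValueError("a suppressor must belong to one revertant")

    @property
    def is_insertion(self) -> bool:
        return self.ref == ""

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PoolSpec:
    """How many revertant genomes are mixed and in what mass proportions."""
    N: int = 10
    proportions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("pool size must be >= 1")
        if self.proportions is None:
            self.proportions = np.full(self.N, 1.0 / self.N)
        else:
            self.proportions = np.asarray(self.proportions, dtype=float)
            if self.proportions.size != self.N:
                raise ValueError("one proportion per revertant required")
            if np.any(self.proportions <= 0):
                raise ValueError("proportions must be positive")
            if abs(self.proportions.sum() - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")


@dataclass
class ReadSimParams:
    read_length: int = 150
    paired: bool = True
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    coverage_per_genome: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_per_genome <= 0:
            raise ValueError("coverage_per_genome must be > 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass
class SuppressorModel:
    """What kind of suppressors arise and where.

    target_weights: gene_id -> sampling weight; None = uniform over all
    genes except the ts gene. effect_probs: relative probability of planting
    a missense, nonsense or (small) insertion suppressor. per_revertant_count
    defaults to one suppressor per revertant.
    """
    target_weights: dict[str, float] | None = None
    effect_probs: dict[str, float] = field(
        default_factory=lambda: {"missense": 0.7, "nonsense": 0.3, "insertion": 0.0})
    per_revertant_count: int = 1


@dataclass
class Screen:
    """One simulated screen: mixtures of revertant genomes plus the truth."""
    reference: ReferenceGenome
    annotation: AnnotationSet
    ts_gene: str
    mixtures: list[list[ReferenceGenome]]   # [mixture][revertant]
    truth: list[Mutation]

    @property
    def ts_mutation(self) -> Mutation:
        return next(m for m in self.truth if m.role == "ts")

    def suppressors(self, mixture: int | None = None) -> list[Mutation]:
        out = [m for m in self.truth if m.role == "suppressor"]
        if mixture is not None:
            out = [m for m in out if m.owner.startswith(f"m{mixture}:")]
        return out

    @property
    def background(self) -> list[Mutation]:
        return [m for m in self.truth if m.role == "background"]


# ---------------------------------------------------------------------------
# genome and annotation


def make_genome(length: int, gc_fraction: float = 0.36, seed: int = 0) -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content on one chromosome.

    The 0.36 default mirrors the AT-rich genomes of fission yeast-like fungi.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 (too small to host genes)")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return ReferenceGenome({"chr1": codes})


def make_annotation(genome: ReferenceGenome, n_genes: int,
                    gene_length_range: tuple[int, int] = (300, 1500),
                    seed: int = 0, max_tries: int = 200) -> AnnotationSet:
    """Place non-overlapping single-exon CDS genes on the genome.

    The genome sequence inside each placed gene is rewritten in place so the
    CDS is well formed on its coding strand: ATG start, sense codons
    throughout, one terminal stop codon. Gene length is a multiple of 3,
    strand is random.
    """
    lo, hi = gene_length_range
    if lo < 9 or hi < lo:
        raise ValueError("invalid gene length range")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.chrom_names}
    genes: list[Gene] = []
    for i in range(n_genes):
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        for attempt in range(max_tries):
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            L = genome.length(chrom)
            if L < length + 2:
                continue
            start = int(rng.integers(1, L - length + 1))  # 1-based
            end = start + length - 1
            # keep a 1 bp buffer so adjacent genes never abut
            if any(s - 1 <= end and start <= e + 1 for s, e in placed[chrom]):
                continue
            break
        else:
            raise ValueError(
                f"could not place gene {i + 1}/{n_genes} without overlap "
                f"after {max_tries} tries")
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = length // 3
        body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in body)
        cds += STOP_CODONS[int(rng.integers(3))]
        cds_codes = encode(cds)
        if strand == "-":
            cds_codes = revcomp_codes(cds_codes)
        genome.codes(chrom)[start - 1:end] = cds_codes
        placed[chrom].append((start, end))
        genes.append(Gene(f"gene{i + 1:03d}", chrom, start, end, strand))
    return AnnotationSet(sorted(genes, key=lambda g: (g.chrom, g.start)))


# ---------------------------------------------------------------------------
# screen construction


def _random_substitution(rng, genome: ReferenceGenome, gene: Gene,
                         want: str, max_tries: int = 200) -> tuple[int, str, str]:
    """Sample (pos, ref, alt) inside a CDS producing the wanted effect class."""
    seq = genome.sequence(gene.chrom)
    n_codons = gene.length // 3
    for _ in range(max_tries):
        # skip the start codon and the terminal stop
        ci = int(rng.integers(1, n_codons - 1))
        lo, hi = codon_genomic_span(ci, gene.start, gene.end, gene.strand)
        pos = int(rng.integers(lo, hi + 1))
        ref = seq[pos - 1]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        eff = substitution_effect(seq, gene.start, gene.end, gene.strand, pos, alt)
        if want == "missense" and eff not in ("silent",) and not eff.endswith("Stop"):
            return pos, ref, alt
        if want == "nonsense" and eff.endswith("Stop"):
            return pos, ref, alt
    raise RuntimeError(f"could not sample a {want} substitution in {gene.gene_id}")


def make_screen(genome: ReferenceGenome, annotation: AnnotationSet,
                ts_gene: str, N: int = 10, n_background: int = 5,
                suppressor_model: SuppressorModel | None = None,
                seed: int = 0, n_mixtures: int = 1) -> Screen:
    """Plant the ts anchor, parental background variants and one private
    suppressor per revertant (by default), and build the revertant genomes.

    All revertants of all mixtures share the single ts mutation and the same
    parental background variants; suppressors are private to one revertant.
    Identical suppressor substitutions may recur in distinct revertants —
    those are independent events, as in a real spontaneous screen.
    """
    model = suppressor_model or SuppressorModel()
    if model.per_revertant_count < 0 or model.per_revertant_count > 2:
        raise ValueError("per_revertant_count must be 0..2")
    rng = np.random.default_rng(seed)
    try:
        ts = annotation.gene(ts_gene)
    except KeyError:
        raise ValueError(f"ts gene {ts_gene!r} not in annotation") from None

    target_ids = (list(model.target_weights) if model.target_weights
                  else [g.gene_id for g in annotation.genes if g.gene_id != ts_gene])
    for gid in target_ids:
        annotation.gene(gid)  # raises KeyError -> unknown target
    if model.target_weights:
        w = np.array([model.target_weights[g] for g in target_ids], dtype=float)
    else:
        w = np.ones(len(target_ids))
    w = w / w.sum()

    used_positions: set[tuple[str, int]] = set()
    truth: list[Mutation] = []

    # ts anchor: a missense change, shared by every revertant
    pos, ref, alt = _random_substitution(rng, genome, ts, "missense")
    truth.append(Mutation(ts.chrom, pos, ref, alt, "ts", "all"))
    used_positions.add((ts.chrom, pos))

    # parental background variants: anywhere outside the ts gene
    chroms = genome.chrom_names
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    pchrom = lengths / lengths.sum()
    planted = 0
    while planted < n_background:
        chrom = chroms[int(rng.choice(len(chroms), p=pchrom))]
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        if (chrom, pos) in used_positions:
            continue
        if ts.chrom == chrom and ts.start <= pos <= ts.end:
            continue
        ref = genome.base(chrom, pos)
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        truth.append(Mutation(chrom, pos, ref, alt, "background", "all"))
        used_positions.add((chrom, pos))
        planted += 1

    effects = list(model.effect_probs)
    eff_p = np.array([model.effect_probs[e] for e in effects], dtype=float)
    eff_p = eff_p / eff_p.sum()

    for mi in range(n_mixtures):
        for ri in range(N):
            for _ in range(model.per_revertant_count):
                gene = annotation.gene(target_ids[int(rng.choice(len(target_ids), p=w))])
                kind = effects[int(rng.choice(len(effects), p=eff_p))]
                if kind == "insertion":
                    lo, hi = gene.start, gene.end
                    pos = int(rng.integers(lo, hi))
                    ins_len = int(rng.choice([1, 2, 3, 4]))
                    ins = "".join("ACGT"[int(rng.integers(4))] for _ in range(ins_len))
                    truth.append(Mutation(gene.chrom, pos, "", ins,
                                          "suppressor", f"m{mi}:rv{ri}"))
                    continue
                # avoid the anchor/background positions; a collision between
                # two suppressors is a legitimate recurrent event and kept
                for _ in range(50):
                    pos, ref, alt = _random_substitution(rng, genome, gene, kind)
                    if (gene.chrom, pos) not in used_positions:
                        break
                else:
                    raise RuntimeError("could not place suppressor away from "
                                       "anchor/background sites")
                truth.append(Mutation(gene.chrom, pos, ref, alt,
                                      "suppressor", f"m{mi}:rv{ri}"))

    mixtures: list[list[ReferenceGenome]] = []
    shared = [m for m in truth if m.owner == "all"]
    for mi in range(n_mixtures):
        revs = []
        for ri in range(N):
            own = [m for m in truth
                   if m.role == "suppressor" and m.owner == f"m{mi}:rv{ri}"]
            revs.append(_apply_mutations(genome, shared + own))
        mixtures.append(revs)
    return Screen(genome, annotation, ts_gene, mixtures, truth)


def _apply_mutations(genome: ReferenceGenome, muts: list[Mutation]) -> ReferenceGenome:
    """Copy the reference and apply substitutions/insertions (descending pos
    so insertion coordinate shifts cannot corrupt later edits)."""
    seqs = {c: genome.codes(c).copy() for c in genome.chrom_names}
    for m in sorted(muts, key=lambda m: (m.chrom, -m.pos)):
        arr = seqs[m.chrom]
        if m.is_insertion:
            seqs[m.chrom] = np.insert(arr, m.pos, encode(m.alt))
        else:
            if chr(BASES[arr[m.pos - 1]]) != m.ref:
                raise ValueError(
                    f"ref mismatch at {m.chrom}:{m.pos}: genome has "
                    f"{chr(BASES[arr[m.pos - 1]])}, mutation says {m.ref}")
            arr[m.pos - 1] = encode(m.alt)[0]
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class PairedReadSet:
    """In-memory paired reads: code matrices plus origin-bearing names."""
    names: list[str]
    r1: np.ndarray  # (n, read_length) uint8
    r2: np.ndarray
    expected_depth: float

    def __len__(self) -> int:
        return len(self.names)

    def pairs(self):
        """Yield (name, r1_seq, r2_seq) as strings."""
        for i, name in enumerate(self.names):
            yield name, decode(self.r1[i]), decode(self.r2[i])

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path,
                    quality_char: str = "F") -> None:
        # constant Q37 ('F' in Phred+33); quality-aware calling is out of scope
        qual = quality_char * self.r1.shape[1]
        for path, mat in ((path_r1, self.r1), (path_r2, self.r2)):
            with open(path, "w") as fh:
                chunks = []
                for i, name in enumerate(self.names):
                    chunks.append(f"@{name}\n{decode(mat[i])}\n+\n{qual}\n")
                fh.write("".join(chunks))

    @staticmethod
    def parse_read_name(name: str) -> tuple[int, str, int]:
        """Oracle helper: (revertant index, chrom, 1-based fragment start)."""
        rv, chrom, start, _ = name.split(":")
        return int(rv[2:]), chrom, int(start)


def simulate_pool_reads(revertants: list[ReferenceGenome], pool: PoolSpec,
                        params: ReadSimParams) -> PairedReadSet:
    """Draw paired-end fragments from the genome mixture.

    Fragment counts per revertant are Poisson with mean proportional to its
    mass fraction; with equal proportions the pooled depth is ~N x
    coverage_per_genome. Per-base substitution errors are uniform over the
    three non-template bases at rate ``error_rate``.
    """
    if len(revertants) != pool.N:
        raise ValueError("need one revertant genome per pool slot")
    R = params.read_length
    if params.insert_mean < R:
        raise ValueError("insert_mean must be >= read_length")
    rng = np.random.default_rng(params.seed)
    names: list[str] = []
    r1_parts: list[np.ndarray] = []
    r2_parts: list[np.ndarray] = []
    total_pairs_scale = pool.N * params.coverage_per_genome / (2 * R)
    for ri, rev in enumerate(revertants):
        prop = float(pool.proportions[ri])
        for chrom in rev.chrom_names:
            arr = rev.codes(chrom)
            L = arr.size
            n_frag = rng.poisson(prop * total_pairs_scale * L)
            if n_frag == 0:
                continue
            inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                                         size=n_frag)).astype(np.int64)
            np.clip(inserts, R, L, out=inserts)
            starts = (rng.random(n_frag) * (L - inserts + 1)).astype(np.int64)
            offs = np.arange(R)
            fwd = arr[starts[:, None] + offs]
            rev_idx = starts[:, None] + (inserts[:, None] - R) + offs
            bwd = COMPLEMENT_CODE[arr[rev_idx]][:, ::-1]
            if params.error_rate > 0:
                for mat in (fwd, bwd):
                    mask = rng.random(mat.shape) < params.error_rate
                    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
                    mat[mask] = (mat[mask] + shift[mask]) % 4
            r1_parts.append(fwd)
            r2_parts.append(bwd)
            names.extend(f"rv{ri}:{chrom}:{int(s) + 1}:{j}"
                         for j, s in enumerate(starts))
    if names:
        r1 = np.vstack(r1_parts)
        r2 = np.vstack(r2_parts)
    else:
        r1 = np.empty((0, R), dtype=np.uint8)
        r2 = np.empty((0, R), dtype=np.uint8)
    expected = pool.N * params.coverage_per_genome
    return PairedReadSet(names, r1, r2, expected)


# ---------------------------------------------------------------------------
# truth table and parental VCF


def write_truth_table(screen: Screen, path: str | Path) -> None:
    """TSV: chrom, pos, ref, alt, role, owner, gene_id, effect."""
    rows = []
    for m in screen.truth:
        gene = screen.annotation.gene_at(m.chrom, m.pos)
        if gene is None:
            gid, eff = "intergenic", "ins" if m.is_insertion else "intergenic"
        elif m.is_insertion:
            gid = gene.gene_id
            eff = "ins(in-frame)" if len(m.alt) % 3 == 0 else "ins(frameshift)"
        else:
            gid = gene.gene_id
            eff = substitution_effect(screen.reference.sequence(m.chrom),
                                      gene.start, gene.end, gene.strand,
                                      m.pos, m.alt)
        rows.append((m.chrom, m.pos, m.ref, m.alt, m.role, m.owner, gid, eff))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\trole\towner\tgene_id\teffect\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_truth_table(path: str | Path) -> list[Mutation]:
    muts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            c = line.rstrip("\n").split("\t")
            muts.append(Mutation(c[idx["chrom"]], int(c[idx["pos"]]),
                                 c[idx["ref"]], c[idx["alt"]],
                                 c[idx["role"]], c[idx["owner"]]))
    return muts


def write_parental_vcf(screen: Screen, path: str | Path) -> None:
    """Parental background variants as VCF v4.2 (insertions left-anchored)."""
    from .vcfio import write_simple_vcf
    records = []
    for m in screen.background:
        if m.is_insertion:
            anchor = screen.reference.base(m.chrom, m.pos)
            records.append((m.chrom, m.pos, anchor, anchor + m.alt, {}))
        else:
            records.append((m.chrom, m.pos, m.ref, m.alt, {}))
    write_simple_vcf(records, path, screen.reference)
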