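"""Codon-level effect computation for single-exon CDS gene models.

Shared by the simulator (to plant mutations with a requested consequence)
and the classifier (to name the consequence of a called variant).
"""

from __future__ import annotations

from Bio.Seq import Seq

from ._dna import revcomp


def codon_of(cds_offset: int) -> tuple[int, int]:
    """Return (codon index, position within codon), both 0-based."""
    return cds_offset // 3, cds_offset % 3


def cds_offset(pos: int, start: int, end: int, strand: str) -> int:
    """0-based offset of genomic position ``pos`` along the coding strand.

    ``start``/``end`` are 1-based inclusive gene bounds.
    """
    if not start <= pos <= end:
        raise ValueError(f"position {pos} outside gene [{start}, {end}]")
    return pos - start if strand == "+" else end - pos


def codon_genomic_span(codon_index: int, start: int, end: int, strand: str) -> tuple[int, int]:
    """1-based inclusive genomic span of a codon on either strand."""
    if strand == "+":
        lo = start + 3 * codon_index
        return lo, lo + 2
    hi = end - 3 * codon_index
    return hi - 2, hi


def substitution_effect(genome_seq: str, start: int, end: int, strand: str,
                        pos: int, alt: str) -> str:
    """Protein-level effect string of a single-base substitution in a CDS.

    Returns "XnY" for missense, "XnStop" for nonsense and "silent" for a
    synonymous change, with n the 1-based codon (residue) number on the
    coding strand.
    """
    off = cds_offset(pos, start, end, strand)
    ci, _ = codon_of(off)
    lo, hi = codon_genomic_span(ci, start, end, strand)
    ref_codon_genomic = genome_seq[lo - 1:hi]
    within = pos - lo
    alt_codon_genomic = (ref_codon_genomic[:within] + alt
                         + ref_codon_genomic[within + 1:])
    if strand == "-":
        ref_codon = revcomp(ref_codon_genomic)
        alt_codon = revcomp(alt_codon_genomic)
    else:
        ref_codon = ref_codon_genomic
        alt_codon = alt_codon_genomic
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "silent"
    if aa_alt == "*":
        return f"{aa_ref}{ci + 1}Stop"
    return f"{aa_ref}{ci + 1}{aa_alt}"
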