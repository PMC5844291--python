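"""Minimal VCF v4.2 text output plus pysam-based input.

Writing a handful of pooled-mixture records needs only the fixed columns and
a few INFO keys, so records are emitted as text; reading goes through
pysam.VariantFile so externally produced VCFs are handled properly.
"""

from __future__ import annotations

from pathlib import Path

import pysam

_INFO_META = {
    "DP": ("1", "Integer", "Pooled read depth at the site"),
    "AC": ("1", "Integer", "Alternate allele read count"),
    "AF": ("1", "Float", "Alternate allele frequency in the pooled mixture"),
    "PV": ("1", "Float", "Binomial upper-tail p-value against sequencing error"),
    "QV": ("1", "Float", "Bonferroni-adjusted p-value"),
    "MIX": ("1", "String", "Mixture identifier"),
}


def write_simple_vcf(records, path: str | Path, genome=None) -> None:
    """Write (chrom, pos, ref, alt, info_dict) tuples as a VCF v4.2 file."""
    info_keys = sorted({k for *_, info in records for k in info})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolrevert\n")
        if genome is not None:
            for chrom in genome.chrom_names:
                fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        for key in info_keys:
            num, typ, desc = _INFO_META.get(key, ("1", "String", key))
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},'
                     f'Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, info in sorted(records, key=lambda r: (r[0], r[1])):
            if info:
                info_str = ";".join(
                    f"{k}={_fmt(info[k])}" for k in info_keys if k in info)
            else:
                info_str = "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info_str}\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def read_vcf_records(path: str | Path):
    """Yield (chrom, pos, ref, alt, info) for every ALT allele in the file."""
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                info = {k: rec.info.get(k) for k in rec.info.keys()}
                yield rec.chrom, rec.pos, rec.ref, alt, info
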