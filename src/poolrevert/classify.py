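"""Classify pooled calls and aggregate suppressor evidence.

A call in one mixture is assigned to exactly one category:

* ``anchor_ts`` — the known ts mutation, expected near allele frequency 1 in
  every mixture (internal control);
* ``background_common`` — a parental-strain variant (matches the parental
  VCF) or any other near-fixed allele;
* ``suppressor_candidate`` — everything else above the reporting floor,
  expected near 1/N for a private suppressor;
* ``subthreshold`` — below the floor.

Candidates are then aggregated across the mixtures of a screen: a gene with
at least ``threshold`` independent events (one event per mixture x variant)
is reported, and genes individually below threshold can combine into a
protein-complex-level report when at least two distinct genes of the same
complex contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._codon import substitution_effect
from .poolcall import VariantCall
from .simulate import AnnotationSet, ReferenceGenome

__all__ = ["ClassifierParams", "ClassifiedVariant", "SuppressorReport",
           "AnchorIntegrityWarning", "classify_calls", "annotate_effect",
           "recurrence_filter", "write_classified_tsv", "write_report_tsv",
           "read_complex_map"]


class AnchorIntegrityWarning(UserWarning):
    """The ts anchor is absent or at unexpectedly low frequency."""


@dataclass
class ClassifierParams:
    ts_locus: tuple[str, int, str]          # (chrom, pos, alt)
    anchor_min_af: float = 0.9
    background_min_af: float = 0.8
    min_af: float = 0.02

    def __post_init__(self) -> None:
        if not self.min_af < self.background_min_af <= self.anchor_min_af:
            raise ValueError(
                "need min_af < background_min_af <= anchor_min_af")


@dataclass
class ClassifiedVariant:
    call: VariantCall
    category: str                           # one of the four categories
    gene_id: str | None = None              # None = intergenic
    effect: str = ""

    @property
    def key(self):
        return self.call.key()


@dataclass
class SuppressorReport:
    unit: str                               # "gene" | "complex"
    unit_id: str
    events: list[tuple[str, str]]           # (mixture_id, variant description)
    n_events: int
    n_distinct_variants: int
    intragenic: bool
    genes: tuple[str, ...] = ()             # member genes for complex units


def classify_calls(calls: list[VariantCall], params: ClassifierParams,
                   parental_variants: list | None = None,
                   annotation: AnnotationSet | None = None,
                   genome: ReferenceGenome | None = None) -> list[ClassifiedVariant]:
    """Partition one mixture's calls into the four categories.

    ``parental_variants`` accepts Mutation-like objects or
    (chrom, pos, ref, alt) tuples. When annotation and genome are supplied,
    each classified call is also annotated with its gene and protein effect.
    Emits AnchorIntegrityWarning when no adequate anchor call exists.
    """
    parental_keys = set()
    for v in parental_variants or ():
        parental_keys.add(tuple(v) if isinstance(v, tuple) else v.key())
    ts_chrom, ts_pos, ts_alt = params.ts_locus
    out: list[ClassifiedVariant] = []
    anchor_seen = False
    for call in calls:
        at_ts = (call.chrom, call.pos, call.alt) == (ts_chrom, ts_pos, ts_alt)
        if at_ts and call.af >= params.anchor_min_af:
            category = "anchor_ts"
            anchor_seen = True
        elif call.key() in parental_keys or call.af >= params.background_min_af:
            category = "background_common"
        elif call.af >= params.min_af:
            category = "suppressor_candidate"
        else:
            category = "subthreshold"
        cv = ClassifiedVariant(call, category)
        if annotation is not None and genome is not None:
            cv.gene_id, cv.effect = annotate_effect(call, annotation, genome)
            if cv.gene_id == "intergenic":
                cv.gene_id = None
        out.append(cv)
    if not anchor_seen:
        warnings.warn(
            f"anchor absent at {ts_chrom}:{ts_pos}:{ts_alt} "
            "(possible sample mix-up or revertant loss of ts allele)",
            AnchorIntegrityWarning, stacklevel=2)
    return out


def annotate_effect(variant, annotation: AnnotationSet,
                    genome: ReferenceGenome) -> tuple[str, str]:
    """(gene_id | "intergenic", effect string) for a variant.

    Substitutions in a CDS are named at the protein level ("G338D",
    "Q64Stop", "silent"); insertions as "ins(in-frame)"/"ins(frameshift)"
    by inserted length mod 3. The variant's ref allele (when non-empty and a
    single base) must match the reference genome.
    """
    chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    is_insertion = len(alt) > len(ref)
    if ref and len(ref) == 1 and not is_insertion:
        have = genome.base(chrom, pos)
        if have != ref:
            raise ValueError(
                f"ref base disagreement at {chrom}:{pos}: genome {have}, "
                f"variant {ref}")
    gene = annotation.gene_at(chrom, pos)
    if gene is None:
        return "intergenic", "ins" if is_insertion else "intergenic"
    if is_insertion:
        ins_len = len(alt) - len(ref)
        kind = "in-frame" if ins_len % 3 == 0 else "frameshift"
        return gene.gene_id, f"ins({kind})"
    eff = substitution_effect(genome.sequence(chrom), gene.start, gene.end,
                              gene.strand, pos, alt)
    return gene.gene_id, eff


def recurrence_filter(classified: list[ClassifiedVariant],
                      annotation: AnnotationSet, threshold: int = 2,
                      ts_gene: str | None = None) -> list[SuppressorReport]:
    """Aggregate suppressor candidates across mixtures into reports.

    One event per (mixture, variant); identical substitutions in different
    mixtures are independent events. Genes with n_events >= threshold are
    reported at gene level; genes below threshold pool into their protein
    complex when >= 2 distinct member genes contribute and the complex total
    reaches the threshold. Output is sorted, hence invariant to input order.
    """
    events: dict[str, list[tuple[str, str, tuple]]] = {}
    seen: set[tuple] = set()
    for cv in classified:
        if cv.category != "suppressor_candidate" or cv.gene_id is None:
            continue
        ekey = (cv.call.mixture_id,) + cv.key
        if ekey in seen:
            continue
        seen.add(ekey)
        desc = cv.effect or f"{cv.call.ref}{cv.call.pos}{cv.call.alt}"
        events.setdefault(cv.gene_id, []).append(
            (cv.call.mixture_id, desc, cv.key))

    def _mk(unit, unit_id, evs, genes=()):
        distinct = {k for _, _, k in evs}
        members = set(genes) if genes else {unit_id}
        return SuppressorReport(
            unit, unit_id,
            sorted((m, d) for m, d, _ in evs),
            len(evs), len(distinct),
            intragenic=ts_gene is not None and ts_gene in members,
            genes=tuple(sorted(genes)))

    reports = []
    by_complex: dict[str, list[str]] = {}
    for gid, evs in events.items():
        if len(evs) >= threshold:
            reports.append(_mk("gene", gid, evs))
        complex_id = annotation.complex_map.get(gid)
        if complex_id is not None:
            by_complex.setdefault(complex_id, []).append(gid)
    for cid, gids in by_complex.items():
        evs = [e for g in gids for e in events[g]]
        if len(gids) >= 2 and len(evs) >= threshold:
            reports.append(_mk("complex", cid, evs, genes=gids))
    reports.sort(key=lambda r: (r.unit, -r.n_events, r.unit_id))
    return reports


# ---------------------------------------------------------------------------
# tabular I/O


def write_classified_tsv(classified: list[ClassifiedVariant],
                         path: str | Path) -> None:
    rows = [{
        "mixture": cv.call.mixture_id, "chrom": cv.call.chrom,
        "pos": cv.call.pos, "ref": cv.call.ref, "alt": cv.call.alt,
        "depth": cv.call.depth, "alt_count": cv.call.alt_count,
        "af": round(cv.call.af, 6), "q_value": cv.call.q_value,
        "category": cv.category, "gene_id": cv.gene_id or "intergenic",
        "effect": cv.effect,
    } for cv in classified]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report_tsv(reports: list[SuppressorReport], path: str | Path) -> None:
    rows = [{
        "unit": r.unit, "unit_id": r.unit_id, "n_events": r.n_events,
        "n_distinct_variants": r.n_distinct_variants,
        "intragenic": r.intragenic,
        "genes": ",".join(r.genes) if r.genes else r.unit_id,
        "events": ";".join(f"{m}:{d}" for m, d in r.events),
    } for r in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_complex_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (gene_id, complex_id), optional header."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, cx = line.split("\t")[:2]
            if gene.lower() == "gene_id":
                continue
            out[gene] = cx
    return out
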