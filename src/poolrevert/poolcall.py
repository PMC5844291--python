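"""Pooled variant calling against a binomial sequencing-error null.

At every site each of the three non-reference bases is tested with the exact
binomial upper tail P(X >= alt_count | X ~ Binomial(depth, e/3)): under the
null all non-reference bases are sequencing error, with aggregate per-base
error rate e spread uniformly over the three miscall targets. P-values are
Bonferroni-corrected over 3 x genome length tests (family-wise control), and
a call must additionally clear an allele-frequency floor (default 2%, the
screen's selection cutoff) and a depth floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .align import PooledPileup
from .simulate import ReferenceGenome
from .vcfio import read_vcf_records, write_simple_vcf

__all__ = ["CallerParams", "VariantCall", "site_test", "call_mixture",
           "estimate_error_rate", "write_calls_vcf", "read_calls_vcf"]


@dataclass
class CallerParams:
    """error_rate is the aggregate per-base miscall probability; each
    specific alternate base is hit at error_rate/3."""
    error_rate: float = 0.002
    alpha: float = 0.05
    min_af: float = 0.02
    min_depth: int = 10
    bonferroni: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_af < 1:
            raise ValueError("min_af must be in [0, 1)")
        if self.min_af > 0 and self.error_rate >= self.min_af:
            raise ValueError("error_rate must be below min_af")


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    p_value: float
    q_value: float
    mixture_id: str = "mix0"

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def site_test(depth: int, alt_count: int, e: float) -> float:
    """Exact binomial upper-tail p-value for one alternate base at one site.

    Returns P(X >= alt_count) with X ~ Binomial(depth, e/3); 1.0 when
    alt_count == 0 (the empty tail).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 < e < 1:
        raise ValueError("error rate must be in (0, 1)")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count must lie in [0, depth]")
    return float(stats.binom.sf(alt_count - 1, depth, e / 3.0))


def call_mixture(pileup: PooledPileup, genome: ReferenceGenome,
                 params: CallerParams, mixture_id: str = "mix0") -> list[VariantCall]:
    """Call significant non-reference alleles across the whole pileup.

    The Bonferroni family is 3 alternate bases x total genome length,
    regardless of how many sites have data; an empty call list is valid.
    """
    n_tests = 3 * genome.total_length
    calls: list[VariantCall] = []
    for chrom in genome.chrom_names:
        mat = pileup.counts[chrom]
        depth = mat.sum(axis=1)
        ref_codes = genome.codes(chrom)
        alt_counts = mat.copy()
        alt_counts[np.arange(mat.shape[0]), ref_codes] = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            af = alt_counts / np.maximum(depth, 1)[:, None]
        cand = np.nonzero((alt_counts > 0)
                          & (depth[:, None] >= params.min_depth)
                          & (af >= params.min_af))
        if cand[0].size == 0:
            continue
        p = stats.binom.sf(alt_counts[cand] - 1, depth[cand[0]],
                           params.error_rate / 3.0)
        q = np.minimum(p * n_tests, 1.0) if params.bonferroni else p
        keep = q <= params.alpha
        for i, base_i, pv, qv in zip(cand[0][keep], cand[1][keep],
                                     p[keep], q[keep]):
            calls.append(VariantCall(
                chrom, int(i) + 1, "ACGT"[ref_codes[i]], "ACGT"[base_i],
                int(depth[i]), int(alt_counts[i, base_i]),
                float(pv), float(qv), mixture_id))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


def estimate_error_rate(pileup: PooledPileup, genome: ReferenceGenome,
                        exclusion_mask: dict[str, np.ndarray] | None = None) -> float:
    """Aggregate per-base error estimate from presumed-monomorphic sites.

    e_hat = (non-reference bases) / (all bases) over unmasked covered sites;
    the mask should remove called/planted sites so true variants do not
    inflate the estimate. Requires >= 1000 unmasked sites with coverage.
    """
    nonref = 0
    total = 0
    n_sites = 0
    for chrom in genome.chrom_names:
        mat = pileup.counts[chrom]
        depth = mat.sum(axis=1)
        keep = depth > 0
        if exclusion_mask is not None and chrom in exclusion_mask:
            keep &= ~exclusion_mask[chrom]
        ref_counts = mat[np.arange(mat.shape[0]), genome.codes(chrom)]
        nonref += int((depth[keep] - ref_counts[keep]).sum())
        total += int(depth[keep].sum())
        n_sites += int(keep.sum())
    if n_sites < 1000:
        raise ValueError(f"only {n_sites} unmasked covered sites (< 1000)")
    return nonref / total if total else 0.0


def write_calls_vcf(calls: list[VariantCall], path: str | Path,
                    genome: ReferenceGenome | None = None) -> None:
    records = [(c.chrom, c.pos, c.ref, c.alt,
                {"DP": c.depth, "AC": c.alt_count, "AF": c.af,
                 "PV": c.p_value, "QV": c.q_value, "MIX": c.mixture_id})
               for c in calls]
    write_simple_vcf(records, path, genome)


def read_calls_vcf(path: str | Path, default_mixture: str = "mix0") -> list[VariantCall]:
    """Read calls back, tolerating external VCFs that lack our INFO keys.

    Records without DP/AC get depth 1 and alt_count = round(AF) if AF is
    present, else alt_count 1 (af 1.0) — enough for classification, which
    only consumes coordinates, alleles and allele frequency.
    """
    calls = []
    for chrom, pos, ref, alt, info in read_vcf_records(path):
        dp = int(info.get("DP", 1) or 1)
        if "AC" in info and info["AC"] is not None:
            ac = int(info["AC"])
        elif "AF" in info and info["AF"] is not None:
            af = float(info["AF"])
            ac = max(0, min(dp, math.ceil(af * dp - 0.5)))
        else:
            ac = dp
        calls.append(VariantCall(
            chrom, pos, ref, alt, dp, ac,
            float(info.get("PV", 0.0) or 0.0), float(info.get("QV", 0.0) or 0.0),
            str(info.get("MIX", default_mixture) or default_mixture)))
    return calls
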