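"""Screen-design calculators for pooled suppressor screens.

Quantifies the arithmetic behind the screen: is the observed revertant
frequency inside the usable window (1e-8 .. 1e-6 revertants per cell
plated — below it suppressors tend to be intragenic, above it suppression
is likely weak); how many genomes fit in one sequencing lane; what allele
frequency a suppressor shared by k of N pooled revertants presents; and the
probability that the pooled caller detects it at a given coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WINDOW", "ScreenDesign", "PowerParams", "ScreenRecord",
           "EXAMPLE_SCREENS", "revertant_frequency", "expected_af",
           "lane_multiplex", "detection_power", "summarize_screens"]

#: usable revertant-frequency window (inclusive), revertants per cell plated
WINDOW = (1e-8, 1e-6)


@dataclass
class ScreenDesign:
    cells_plated: float
    revertants_obtained: int
    frequency: float
    verdict: str                 # too_low_intragenic_bias | suitable | too_high_weak_suppression
    window: tuple[float, float] = WINDOW

    @property
    def nearest_power_of_ten(self) -> float | None:
        """10^round(log10 f); None for zero frequency. The strict window
        verdict and this rounded reading are reported side by side because
        frequencies slightly above 1e-6 still round to 1e-6."""
        if self.frequency <= 0:
            return None
        return 10.0 ** round(math.log10(self.frequency))


@dataclass
class ScreenRecord:
    """One screen's conditions and outcome (for summaries and examples)."""
    gene: str
    temperature: float
    cells_plated: float
    revertants_obtained: int
    revertants_sequenced: int
    distinct_suppressors: int


#: three fission-yeast ts-mutant screens (cdc48-G338D, eso1-G799D,
#: htb1-G52D) used as the package's worked example
EXAMPLE_SCREENS = [
    ScreenRecord("cdc48", 37, 3.8e8, 358, 30, 19),
    ScreenRecord("eso1", 37, 6.0e8, 756, 40, 14),
    ScreenRecord("htb1", 36, 4.5e7, 56, 52, 16),
]


def revertant_frequency(revertants: int, cells_plated: float) -> ScreenDesign:
    """Frequency = revertants / cells plated, with a window verdict.

    Window endpoints are inclusive in "suitable".
    """
    if cells_plated <= 0:
        raise ValueError("cells_plated must be positive")
    if revertants < 0:
        raise ValueError("revertants must be >= 0")
    f = revertants / cells_plated
    lo, hi = WINDOW
    if f < lo:
        verdict = "too_low_intragenic_bias"
    elif f > hi:
        verdict = "too_high_weak_suppression"
    else:
        verdict = "suitable"
    return ScreenDesign(cells_plated, revertants, f, verdict)


def expected_af(N: int, k_sharing: int = 1) -> float:
    """Expected pooled allele frequency of a suppressor carried by
    k_sharing of the N equally mixed revertants."""
    if N < 1 or not 1 <= k_sharing <= N:
        raise ValueError("need 1 <= k_sharing <= N")
    return k_sharing / N


def lane_multiplex(n_mixtures: int, pool_size: int) -> int:
    """Genomes sequenced per lane: mixtures barcoded together x pool size."""
    if n_mixtures < 1 or pool_size < 1:
        raise ValueError("both arguments must be >= 1")
    return n_mixtures * pool_size


@dataclass
class PowerParams:
    N: int = 10
    coverage_per_genome: float = 30.0
    error_rate: float = 0.002
    min_af: float = 0.02
    alpha: float = 0.05
    n_tests: float = 3e5
    k_sharing: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.k_sharing <= self.N:
            raise ValueError("need 1 <= k_sharing <= N")
        if self.error_rate >= self.k_sharing / self.N:
            raise ValueError("error rate must be below the true allele fraction")


def _critical_counts(d: np.ndarray, p0: float, q: float) -> np.ndarray:
    """Smallest m per depth with P(X >= m | Binomial(d, p0)) <= q."""
    m = np.ceil(stats.binom.isf(q, d, p0)).astype(np.int64)
    m = np.maximum(m, 0)
    for _ in range(4):  # settle scipy's isf off-by-ones exactly
        too_big = stats.binom.sf(m - 1, d, p0) > q
        m = np.where(too_big, m + 1, m)
        shrinkable = (m > 0) & (stats.binom.sf(m - 2, d, p0) <= q)
        m = np.where(shrinkable, m - 1, m)
    return m


def detection_power(params: PowerParams) -> float:
    """Probability the pooled caller detects the suppressor allele.

    Depth d at the site is Poisson(N x coverage); given d the alternate
    count is Binomial(d, f_eff) with
    f_eff = (k/N)(1 - e) + (1 - k/N)(e/3) — carriers read through with
    probability 1-e, non-carriers miscall to this base at e/3. The site is
    called when the count reaches both the Bonferroni-corrected binomial
    critical value and the allele-frequency floor ceil(min_af x d). The
    Poisson depth sum is truncated at 6 sigma.
    """
    lam = params.N * params.coverage_per_genome
    if lam <= 0:
        return 0.0
    sd = math.sqrt(lam)
    d_lo = max(1, int(math.floor(lam - 6 * sd)))
    d_hi = int(math.ceil(lam + 6 * sd))
    d = np.arange(d_lo, d_hi + 1)
    w = stats.poisson.pmf(d, lam)
    frac = params.k_sharing / params.N
    e = params.error_rate
    f_eff = frac * (1 - e) + (1 - frac) * (e / 3.0)
    crit = _critical_counts(d, e / 3.0, params.alpha / params.n_tests)
    need = np.maximum(crit, np.ceil(params.min_af * d).astype(np.int64))
    p_call = stats.binom.sf(need - 1, d, f_eff)
    return float(np.sum(w * p_call))


def summarize_screens(screens: list[ScreenRecord]) -> dict[str, float | int]:
    """Totals and per-screen frequency verdicts across a set of screens."""
    freqs = [revertant_frequency(s.revertants_obtained, s.cells_plated)
             for s in screens]
    return {
        "n_screens": len(screens),
        "total_revertants_sequenced": sum(s.revertants_sequenced for s in screens),
        "total_distinct_suppressors": sum(s.distinct_suppressors for s in screens),
        "frequencies": [f.frequency for f in freqs],
        "verdicts": [f.verdict for f in freqs],
        "nearest_powers_of_ten": [f.nearest_power_of_ten for f in freqs],
    }
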