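"""Per-population allele and heterozygote frequencies, and prevalence filters.

Definitions on called diploid genotypes only (missing calls drop out of the
denominators): AF = (het + 2*hom_alt) / (2*called), observed heterozygote
frequency HF = het / called, expected heterozygosity 2*AF*(1-AF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .data_io import Variant

__all__ = [
    "PopulationFrequencies",
    "PopulationStats",
    "compute_stats",
    "af_prevalence_filter",
    "het_all_populations_filter",
    "population_specific",
]


@dataclass(frozen=True)
class PopulationFrequencies:
    af: float
    hf_obs: float
    n_called: int

    @property
    def expected_het(self) -> float:
        return 2.0 * self.af * (1.0 - self.af)


@dataclass(frozen=True)
class PopulationStats:
    """Frequency summary of one variant across populations.

    ``n_populations_present`` counts populations where the alternate allele
    was observed at all (AF > 0); populations with zero called genotypes are
    listed in ``missing_populations`` and excluded from that count.
    """

    variant_key: str
    per_population: Mapping[str, PopulationFrequencies]
    global_af: float
    global_hf: float
    missing_populations: tuple[str, ...] = ()

    @property
    def n_populations_present(self) -> int:
        return sum(1 for f in self.per_population.values() if f.af > 0)


def compute_stats(variant: Variant) -> PopulationStats:
    """Per-population and pooled allele/heterozygote frequencies of a variant."""
    per_pop: dict[str, PopulationFrequencies] = {}
    missing = []
    total_alt = total_called = total_het = 0
    for pop, counts in variant.pop_genotype_counts.items():
        if counts.called == 0:
            missing.append(pop)
            continue
        per_pop[pop] = PopulationFrequencies(
            af=counts.alt_alleles / (2 * counts.called),
            hf_obs=counts.het / counts.called,
            n_called=counts.called,
        )
        total_alt += counts.alt_alleles
        total_called += counts.called
        total_het += counts.het
    if total_called == 0:
        raise ValueError(f"{variant.key}: zero called genotypes in all populations")
    return PopulationStats(
        variant_key=variant.key,
        per_population=per_pop,
        global_af=total_alt / (2 * total_called),
        global_hf=total_het / total_called,
        missing_populations=tuple(missing),
    )


def af_prevalence_filter(
    stats: PopulationStats, low: float = 0.005, high: float = 0.995
) -> bool:
    """Keep a variant iff its pooled allele frequency lies in [low, high].

    Both boundaries are inclusive: a variant at exactly 0.5% prevalence is
    kept, one below it (or its mirror above 99.5%) is discarded.
    """
    return low <= stats.global_af <= high


def het_all_populations_filter(
    stats: PopulationStats, min_het: float = 0.05, metric: str = "observed"
) -> bool:
    """Pass iff heterozygosity strictly exceeds ``min_het`` in EVERY population.

    ``metric`` chooses the observed heterozygote genotype fraction (default)
    or the expected Hardy-Weinberg heterozygosity 2p(1-p).  A population with
    no called genotypes means insufficient data: the filter fails.
    """
    if metric not in ("observed", "expected"):
        raise ValueError("metric must be 'observed' or 'expected'")
    if stats.missing_populations or not stats.per_population:
        return False
    for freqs in stats.per_population.values():
        value = freqs.hf_obs if metric == "observed" else freqs.expected_het
        if not value > min_het:
            return False
    return True


def population_specific(stats: PopulationStats) -> bool:
    """True iff the alternate allele was observed in exactly one population.

    A site where the allele was observed nowhere is not segregating and is a
    degenerate input.
    """
    n = stats.n_populations_present
    if n == 0:
        raise ValueError(f"{stats.variant_key}: alternate allele observed in no population")
    return n == 1
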