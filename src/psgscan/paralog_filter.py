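"""Detection of paralog-contaminated gene alignments.

Reads from a diverged gene copy co-mapping onto a single reference gene
mimic heterozygosity, but with telltale signatures that three filters
pick up:

1. *multiallelic*: any site with more than two alleles passing the
   caller's frequency/coverage thresholds (diploids carry at most two);
2. *coverage*: gene mean exon coverage more than 2 SD above the
   genome-wide mean for that species (two co-mapping copies double the
   expected depth);
3. *het skew*: heterozygous-variant frequencies concentrating near
   0.25/0.75 (two-copy mixture) instead of 0.5 (true heterozygote),
   detected by binning variant frequencies into low [0.125, 0.375),
   intermediate [0.375, 0.625) and high [0.625, 0.875] bins and firing
   when either outer bin outnumbers the intermediate one.

A gene is excluded from the single-copy ortholog set if any filter
fires in any species (conservative union rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus_caller import CallStats

logger = logging.getLogger(__name__)

#: variant-frequency bin edges: low, intermediate, high
HET_BIN_EDGES = (0.125, 0.375, 0.625, 0.875)
#: minimum heterozygous sites before the skew filter may fire
MIN_HET_SITES_FOR_SKEW = 3


@dataclass
class ParalogFlags:
    gene_id: str
    species: str
    flag_multiallelic: bool
    flag_coverage: bool
    flag_het_skew: bool
    het_bin_counts: tuple[int, int, int]

    @property
    def any(self) -> bool:
        return (self.flag_multiallelic or self.flag_coverage
                or self.flag_het_skew)


def flag_multiallelic(stats: CallStats) -> bool:
    """True iff any site in this species carries >2 alleles passing the
    caller's thresholds (a single such site suffices)."""
    return stats.n_multiallelic_sites > 0


def flag_coverage(stats: CallStats, genome_mean: float,
                  genome_sd: float) -> bool:
    """True iff gene mean coverage exceeds the genome-wide mean by
    strictly more than 2 SD."""
    if genome_sd <= 0:
        raise ValueError("genome_sd must be positive")
    return stats.mean_coverage > genome_mean + 2.0 * genome_sd


def het_bin_counts(frequencies: Iterable[float]) -> tuple[int, int, int]:
    """Counts of heterozygous variant frequencies in the low /
    intermediate / high bins.  Bins are closed on the left, open on the
    right, except the high bin which includes 0.875."""
    lo = mid = hi = 0
    e = HET_BIN_EDGES
    for f in frequencies:
        if e[0] <= f < e[1]:
            lo += 1
        elif e[1] <= f < e[2]:
            mid += 1
        elif e[2] <= f <= e[3]:
            hi += 1
    return lo, mid, hi


def flag_het_skew(stats: CallStats) -> tuple[bool, tuple[int, int, int]]:
    """True iff more heterozygous variants fall in the low or the high
    frequency bin than in the intermediate bin.  Requires at least
    MIN_HET_SITES_FOR_SKEW heterozygous sites (a lone outer-bin site
    would otherwise flag ordinary genes)."""
    bins = het_bin_counts(stats.het_frequencies)
    if sum(bins) < MIN_HET_SITES_FOR_SKEW:
        return False, bins
    lo, mid, hi = bins
    return (lo > mid) or (hi > mid), bins


def species_flags(stats: CallStats, genome_mean: float,
                  genome_sd: float) -> ParalogFlags:
    skew, bins = flag_het_skew(stats)
    return ParalogFlags(
        gene_id=stats.gene_id, species=stats.species,
        flag_multiallelic=flag_multiallelic(stats),
        flag_coverage=flag_coverage(stats, genome_mean, genome_sd),
        flag_het_skew=skew, het_bin_counts=bins)


def classify_gene(flags: Sequence[ParalogFlags]) -> str:
    """'single_copy' or 'paralogous' (union over species and filters)."""
    triggers = [f for f in flags if f.any]
    if triggers:
        for f in triggers:
            logger.debug("gene %s flagged in %s (multi=%s cov=%s skew=%s)",
                         f.gene_id, f.species, f.flag_multiallelic,
                         f.flag_coverage, f.flag_het_skew)
        return "paralogous"
    return "single_copy"


def genome_coverage_stats(stats_by_gene: Mapping[str, Mapping[str, CallStats]]
                          ) -> dict[str, tuple[float, float]]:
    """Per-species (mean, sd) of per-gene mean exon coverage."""
    per_species: dict[str, list[float]] = {}
    for gene_stats in stats_by_gene.values():
        for sp, st in gene_stats.items():
            per_species.setdefault(sp, []).append(st.mean_coverage)
    out = {}
    for sp, vals in per_species.items():
        arr = np.asarray(vals)
        out[sp] = (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1
                   else 0.0)
    return out


def filter_paralogs(stats_by_gene: Mapping[str, Mapping[str, CallStats]]
                    ) -> pd.DataFrame:
    """Run all three filters on a cohort.

    ``stats_by_gene`` maps gene_id -> species -> CallStats.  Returns a
    disposition table with one row per gene: classification plus the
    per-filter union across species.
    """
    cov_stats = genome_coverage_stats(stats_by_gene)
    rows = []
    for gid, gene_stats in stats_by_gene.items():
        flags = []
        for sp, st in gene_stats.items():
            mean, sd = cov_stats[sp]
            if sd <= 0:
                f = ParalogFlags(gid, sp, flag_multiallelic(st), False,
                                 *flag_het_skew(st))
            else:
                f = species_flags(st, mean, sd)
            flags.append(f)
        rows.append(dict(
            gene_id=gid,
            classification=classify_gene(flags),
            any_multiallelic=any(f.flag_multiallelic for f in flags),
            any_coverage=any(f.flag_coverage for f in flags),
            any_het_skew=any(f.flag_het_skew for f in flags),
            n_species_flagged=sum(f.any for f in flags),
        ))
    return pd.DataFrame(rows)
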