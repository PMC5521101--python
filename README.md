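# psgscan

A genome-wide scan for positively selected genes (PSGs) in clades of
closely related genomes sequenced against a shared reference — the
setting of the strongylocentrotid sea urchins, where short reads from
nine species are anchored to the *Strongylocentrotus purpuratus* gene
models.  The package covers the whole inference chain and ships a
synthetic-data generator so every stage is testable without any
sequencing data.

## What it computes

1. **Consensus calling.**  Per-species read pileups over a reference
   gene model are turned into IUPAC consensus CDS sequences with a
   threshold caller: reads must be properly paired with mapping quality
   ≥ 25 (best-of-duplicate-group retained); a site is called with ≥ 8
   filtered reads; alleles count at frequency ≥ 0.125; two passing
   alleles give a two-base ambiguity code; deletions and uncallable
   sites are missing data (N), with missing/indel runs recorded.
2. **Paralog filtering.**  Reads from a second locus co-mapping onto a
   gene mimic heterozygosity.  Three filters catch it — any site with
   more than two passing alleles, gene coverage above the genome mean
   by > 2 SD, and heterozygous variant frequencies skewed toward
   0.25/0.75 instead of 0.5 — and a gene is excluded if any filter
   fires in any species.
3. **Sites tests.**  For each single-copy gene the Goldman–Yang codon
   model is fitted by maximum likelihood under M7 (beta-distributed
   ω ∈ (0,1)) and M8 (beta plus a selected class with ω_s ≥ 1) with
   F3X4 codon frequencies, κ and ω estimated from the data (initial
   values 1.6 and 0.4).  The statistic is the LRT
   2·(lnL_M8 − lnL_M7).  P-values come from an *empirical null*: genes
   are re-simulated under their own M7 MLEs on their own trees, refit,
   and the observed LRT is referred to the pooled null ecdf
   (add-one corrected).  q-values (Storey) control the FDR; genes with
   q < 0.05 are PSGs.  Positively selected codons (PSCs) are codons
   with Bayes-empirical-Bayes posterior > 0.95 of the ω > 1 class,
   exportable as wiggle tracks scored −log10(1 − posterior).
4. **Branch-site tests.**  Branch-site model A against its ω₂ = 1 null
   on every terminal branch, with the 1:1 mixture of a point mass at 0
   and χ²₁ as reference distribution and per-gene Bonferroni
   correction across branches.
5. **Enrichment and validation.**  Hypergeometric category enrichment
   of PSGs (expected count n·K/N, fold enrichment, 10,000-resample
   empirical P, q-values), one-tailed Fisher tests for a-priori
   candidate sets, and positional-artifact tests asking whether PSCs
   concentrate within 3/5/7 amino acids of exon borders or next to
   missing-data/indel regions.

The synthetic-data module simulates codon alignments under
M0/M7/M8/branch-site A (root drawn from the stationary distribution,
rate matrices scaled to one expected substitution per codon), diploid
pileups with configurable coverage, heterozygosity, mapping-quality
mix and optional diverged-paralog contamination, and gene universes
with category labels — all byte-reproducible under a seed.

## Worked example

Simulate one gene under positive selection, run the M7-vs-M8 test, and
inspect the selected-class recovery:

```python
from psgscan import SimulationConfig, simulate_codon_alignment
from psgscan.selection_inference import sites_test
from psgscan.codon_models import site_posteriors

config = SimulationConfig(seed=7, model="M8", p0=0.9, omega_s=3.0,
                          n_codons=300, tree_length=3.0)
aln, site_class, tree = simulate_codon_alignment(config)
gf = sites_test(aln, tree, n_starts=1, seed=0)
print(f"LRT = {gf.LRT:.1f}")
print(f"p0 = {gf.fit_m8.params.p0:.3f}, "
      f"omega_s = {gf.fit_m8.params.omega_s:.2f}")
beb = site_posteriors(gf.fit_m8, "BEB")
sel = site_class == config.n_classes
print(f"mean BEB posterior: selected sites {beb[sel].mean():.2f}, "
      f"neutral sites {beb[~sel].mean():.2f}")
```

prints

```
LRT = 61.9
p0 = 0.914, omega_s = 2.81
mean BEB posterior: selected sites 0.82, neutral sites 0.03
```

— the test finds strong evidence of selection (an LRT of 61.9 is far
beyond any null quantile), recovers the planted mixture (10% of sites
selected at ω_s = 3), and the BEB posteriors separate the truly
selected codons from the neutral background.

The same flow is available from the shell: `psg-scan simulate`,
`psg-scan call`, `psg-scan filter-paralogs`, `psg-scan test-sites`,
`psg-scan calibrate-null`, `psg-scan test-branches`, `psg-scan enrich`,
`psg-scan validate-psc`, and `psg-scan harness` for a one-command
end-to-end cohort run scored against planted truth.

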