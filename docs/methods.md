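# Methods

This note documents the models, rules and numerical choices behind
psgscan, and what the synthetic-data generator does and does not
emulate.

## Consensus calling

The caller is a deliberate reproduction of a threshold rule, not a
genotype-likelihood model.  After discarding reads that are not
properly paired or have mapping quality < 25 and keeping only the
highest-quality read of each duplicate group, a site with at least 8
retained reads is called from the alleles whose frequency is at least
0.125; the frequency comparison is done in integer arithmetic
(8·count ≥ coverage), so the boundary is exact.  One passing allele
gives the base; two give the IUPAC two-base code; zero or more than
two give N (the latter is also tabulated as a >2-allele site — the
primary paralogy signal).  Deletion-spanning sites are N; insertions
relative to the reference are ignored.  Both thresholds are inclusive
("minimum" read as attainable).  Allele frequencies are computed over
retained reads only; a 0.5/0.5 tie passes both alleles.  Reference
coordinates of every N/indel run are recorded per species for the
downstream positional tests.

Heterozygote frequencies are recorded as the *variant* (non-reference)
allele frequency when the reference base is known, because the paralog
skew filter bins frequencies up to 0.875; without a reference the
minor-allele frequency is recorded (equivalent for the low bin).

## Paralog filters

Three per-species filters, excluded-if-any-fires-anywhere (the
conservative union over filters and species):

* **multiallelic** — existential: one site with >2 passing alleles
  suffices (diploids carry at most two);
* **coverage** — gene mean exon coverage strictly greater than the
  species' genome-wide mean + 2 SD of per-gene mean coverage;
* **het skew** — heterozygous variant frequencies binned into
  low [0.125, 0.375), intermediate [0.375, 0.625) and high
  [0.625, 0.875] (left-closed, 0.875 included so the attainable range
  is covered); the filter fires when either outer bin outnumbers the
  intermediate bin, and requires ≥ 3 heterozygous sites so a lone
  outer-bin site cannot flag an ordinary gene.

A caveat the simulation makes explicit: *fixed* differences between
two co-mapping copies surface at frequency ≈ 0.5 and are
indistinguishable from true heterozygotes, so at low inter-copy
divergence the skew filter is weak and detection rests on the coverage
and multiallelic filters; the skew filter's discriminating signal is
the copies' own polymorphism at ≈ 0.25/0.75.  Relatedly, the planted
contamination fraction in a test cohort must stay modest (we use 10%):
the coverage baseline is estimated from the cohort itself, and heavy
contamination inflates it.

## Codon models

The substitution model is GY94 on the 61 sense codons: off-diagonal
rates are 0 for multi-nucleotide changes and π_j scaled by κ for
transitions and ω for nonsynonymous changes.  Equilibrium frequencies
are F3X4 (position-specific nucleotide frequencies pooled over taxa),
with zero-frequency codons floored at 1e-6 and renormalised so small
alignments keep finite likelihoods.  Rate matrices are normalised so
the mixture-averaged substitution rate is one per codon per unit
branch length (branch-site classes are scaled by their background-ω
mixture average; both the alternative and its null share the
convention, so the LRT is unaffected).

Likelihoods use Felsenstein pruning, vectorised across site classes
and compressed site patterns, with per-node rescaling against
underflow; transition matrices come from the symmetrised
eigendecomposition of the reversible generator.  The beta distribution
of M7/M8 is discretised into 10 equal-probability classes represented
by their exact bin means (incomplete-beta formula).

Fitting is bounded L-BFGS-B on log-transformed parameters
(κ ∈ [0.1, 20], ω ∈ [1e-4, 50], beta shapes ∈ [0.005, 99], selected
ω ≥ 1 via a shifted log), with initial values κ = 1.6 and ω = 0.4 and
multi-start jitter (3 starts by default; pipeline drivers use warm
starts — M8 starts from the M7 optimum, branch-site A from its null —
and a single start at cohort scale).  Convergence is declared at the
optimizer's relative-ftol of 1e-10 (ΔlnL well below 1e-6); abnormal
line-search terminations with a small projected gradient are accepted
as converged.  Branch lengths are fixed at the input tree's values by
default; a single tree-scale factor can be co-estimated
(`optimize_branch_lengths=True`).  Negative LRTs within optimizer
noise are clamped to zero.

Per-gene dN and dS follow the codeml convention: synonymous and
nonsynonymous substitution flows under the fitted mixture divided by
site proportions measured at ω = 1; group-level mean dN/dS is reported
both as ratio-of-means and mean-of-ratios.

**Site posteriors.**  NEB plugs the MLEs into Bayes' rule.  BEB
averages the NEB computation over a 10-point grid prior on the mixture
parameters with the remaining parameters (beta shapes, κ, π, branch
lengths, and the rate scaling) held at their MLEs: for M8, p0 uniform
on (0,1) and ω_s uniform on (1,11); for branch-site A, the class
proportions via a 10×10 grid on (p0+p1, p0/(p0+p1)) and ω₂ uniform on
(1,11) with ω₀ fixed at its MLE.  This follows the published BEB
scheme's structure at grid resolution d = 10; the exact grid geometry
of codeml is not replicated.

## Selection inference

**QC.**  Codon columns with any two-base ambiguity in any taxon are
removed first (heterozygous codons are not fixed differences), then
columns with a gap or N in any taxon (cleandata semantics).  If a stop
codon survives, the last 10 codons of the reference gene are trimmed
and cleaning redone; a persistent stop fails the gene.  The 100-codon
gate applies to the post-cleaning count by default — stricter than
gating the input length, and consistent with the gate's purpose of
guaranteeing test power; `gate="pre_clean"` gives the other ordering.

**Empirical null.**  For a sample of fitted genes (650 × 18 replicates
at full scale; far smaller at desk scale), alignments are re-simulated
under each gene's M7 MLEs — κ, beta shapes, its F3X4 frequencies, its
tree with fitted-scale branch lengths — then M7 and M8 are refit and
the LRTs pooled.  Empirical P-values use the add-one rule
(1 + #{null ≥ LRT})/(1 + n), so the largest observed LRT cannot yield
p = 0; the smallest attainable p is therefore 1/(n_null + 1), which
bounds how many genes can be flagged at a given FDR when the null
sample is small.

**FDR.**  Storey q-values with a smoothed-spline π̂₀ estimate
(λ grid 0.05–0.95).  The R package fdrtool's censored half-normal
empirical-null modelling is intentionally not reproduced; BH is
available as `method="bh"`.

**Branch-site tests.**  LRT of model A vs. the ω₂ = 1 null per
terminal branch; p = 1 at LRT = 0, else half the χ²₁ survival
(the 1:1 mixture of point mass and χ²₁); Bonferroni multiplies by the
number of branches actually tested for that gene (9 unless a fit
failed).

**Summaries.**  Wright's effective number of codons (ENC, 20–61) with
the standard degeneracy-class estimator and the usual fallbacks for
missing classes, GC content, Mann-Whitney U for continuous contrasts,
Fisher exact for binary traits (two-sided by default; the a-priori
category tests are one-tailed).

## Enrichment and positional validation

Category enrichment reports the hypergeometric expectation n·K/N and
fold k/expectation; the empirical P re-draws the K PSG labels without
replacement — implemented as the per-category hypergeometric marginal,
which is distributionally identical and fast — with add-one
correction, and the exact tail is computed alongside.  Genome-wide
tests drop categories with < 20 genes or exactly one PSG; per-branch
tests keep any category with ≥ 1 PSG at FDR 10%.

The positional tests classify every *analysed* (post-QC) codon as
inside or outside a window of w ∈ {3, 5, 7} amino acids around exon
borders (measured along the spliced CDS; a codon split by an intron
belongs to the exon holding its first base; gene ends count as
borders) or around the boundaries of recorded missing/indel runs
("adjacent" is interpreted as the same w-codon window, as no distance
is otherwise defined).  PSC-vs-window association is a pooled
two-sided Fisher 2×2 with the direction reported.  Only analysed
codons enter, since only they can be PSCs.

## Synthetic data: what it emulates and what it does not

The generator replaces evolver for alignments (stationary root,
per-site mixture class, matrix-exponential branch transitions) and a
read simulator for pileups (negative-binomial coverage for
overdispersion, per-read mapping-quality mix, proper-pair flags,
duplicate groups, uniform sequencing error at 1e-3, optional diploid
paralog contamination that inflates coverage by 1/(1−f), and planted
missing-data tracts standing in for indels).  Defaults mirror the
nine-genome study's conditions: 9 taxa, ~40× coverage, mapping
qualities mostly 60 with a minority under the 25 cutoff, 1% per-site
heterozygosity, 300-codon genes, tree length ~3 substitutions/codon.

Not emulated: read-level artifacts (FASTQ, adapters, mapping bias),
alignment error proper (misalignment is only mimicked by missing-data
tracts), indel evolution, GC-biased gene conversion, and rate
variation beyond the fitted model families.  Passing tests therefore
demonstrate the *inference machinery* is correct and calibrated under
the stated generative model — not that real-data artifacts cannot leak
through.

A numerical point discovered during development: simulating with
uniform-over-61 codon frequencies while fitting with F3X4 is
misspecified (a uniform π is not a product of position frequencies)
and biases ω̂_s upward by ~+0.6 under the recovery conditions; the
statistical checks therefore simulate from an F3X4-consistent π with
realistic position-specific nucleotide frequencies, matching how the
empirical-null pipeline feeds fitted codon frequencies back into the
simulator.

## Problem sizes of the shipped checks

Chosen as desk-scale versions of the full design; thresholds are
never adjusted to the scale.

| check | test suite | acceptance script |
| --- | --- | --- |
| M8 recovery (300 codons, 9 taxa, TL 3) | 24 replicates | 50 replicates |
| type-I error, all-M7 cohort | 40 genes (110 codons), null 8×3 | 60 genes (120 codons), null 10×4 |
| paralog filter | 100 genes, 10 contaminated | 100 genes, 10 contaminated |
| branch-site ranking (ω₂ = 6, 200 codons) | 4 replicates | 5 replicates |
| end-to-end harness | 5 genes, 5 taxa | — |

## Known limitations

* Branch lengths are fixed at input-tree values by default; only a
  global scale can be co-estimated, not per-branch lengths.
* ω̂_s at 300 codons with a 10% selected class has intrinsic sampling
  spread of ~0.6; medians over few replicates are noisy.
* The BEB grids follow the published scheme's structure, not codeml's
  exact grid geometry; posterior values can differ in the second
  decimal.
* With small empirical-null samples the attainable P-value floor
  (add-one rule) limits FDR discoveries; the harness reports this
  regime honestly rather than extrapolating the null tail.
* fdrtool's q-value variant is not reproduced (see above).
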