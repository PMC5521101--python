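"""Synthetic inputs for the whole pipeline: codon alignments evolved
under M0/M7/M8/branch-site model A, diploid read pileups with optional
paralog contamination, gene models, and gene universes with category
labels.

The sequence simulator replaces PAML's evolver for the empirical-null
calibration: the root codon is drawn from the stationary distribution
pi, each site draws a mixture class, and states evolve along each
branch by the class's transition matrix exp(Q t) with rates scaled to
one expected substitution per codon per unit branch length.

Default condition values mirror the nine-species sea-urchin study the
pipeline is built around: 9 taxa, ~40x mean read coverage, mapping
qualities mostly at 60 with a minority below the 25 cutoff, per-site
heterozygosity of 1% (strongylocentrotids are highly polymorphic), and
sequencing error 1e-3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import genetic_code as gc
from ._phylo import IndexedTree, random_tree
from .codon_models import (CodonModelParams, SiteClass, mixture_scale,
                           model_site_classes, transition_matrices)
from .consensus_caller import COMPLEMENT, GenePileup, encode_bases
from .io_formats import CodonAlignment, GeneModel

DEFAULT_TAXA = tuple(f"sp{i + 1}" for i in range(9))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_taxa: int = 9
    tree: str = "random"            # Newick string or "random"
    tree_length: float = 3.0        # expected substitutions/codon, summed
    model: str = "M7"
    kappa: float = 2.0
    omega: float = 0.2              # M0
    beta_p: float = 0.5             # M7/M8 beta shapes
    beta_q: float = 1.5
    p0: float = 0.9                 # M8 beta weight / bsA class-0 weight
    omega_s: float = 3.0            # M8 selected-class omega
    p1: float = 0.05                # bsA class-1 weight
    omega0: float = 0.2             # bsA background omega
    omega2: float = 4.0             # bsA foreground omega
    foreground: Optional[str] = None
    codon_freqs: Union[str, np.ndarray] = "uniform"
    n_codons: int = 300
    n_classes: int = 10
    # pileup layer
    heterozygosity: float = 0.01    # per-site heterozygote rate
    coverage_mean: float = 40.0
    coverage_sd: float = 12.0
    error_rate: float = 1e-3
    mapq_values: tuple = (60, 30, 20)
    mapq_probs: tuple = (0.88, 0.07, 0.05)
    proper_pair_rate: float = 0.98
    duplicate_rate: float = 0.05
    # paralog contamination: fraction of reads from a copy diverged by d
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.0
    # missing-data tracts planted per species (indel stand-in)
    n_missing_tracts: float = 0.0
    missing_tract_len: float = 10.0

    def validate(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0 or self.tree_length < 0:
            raise ValueError("kappa must be > 0 and tree_length >= 0")
        if self.model == "M8" and self.omega_s < 1:
            raise ValueError("M8 selected-class omega must be >= 1")
        for p in (self.p0, self.p1, self.heterozygosity, self.error_rate,
                  self.paralog_fraction, self.paralog_divergence,
                  self.proper_pair_rate, self.duplicate_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mapq_probs) - 1.0) > 1e-9:
            raise ValueError("mapq_probs must sum to 1")

    def resolve_pi(self) -> np.ndarray:
        if isinstance(self.codon_freqs, str):
            if self.codon_freqs != "uniform":
                raise ValueError(f"unknown codon_freqs {self.codon_freqs!r}")
            return np.full(gc.N_STATES, 1.0 / gc.N_STATES)
        pi = np.asarray(self.codon_freqs, dtype=float)
        if pi.shape != (gc.N_STATES,) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("codon_freqs must be a 61-vector summing to 1")
        return pi

    def model_params(self, foreground: Optional[str] = None
                     ) -> CodonModelParams:
        return CodonModelParams(
            model=self.model if self.model != "branchsiteA" else "bsA",
            kappa=self.kappa, omega=self.omega, beta_p=self.beta_p,
            beta_q=self.beta_q, p0=self.p0, omega_s=self.omega_s,
            p1=self.p1, omega0=self.omega0, omega2=self.omega2,
            foreground=foreground or self.foreground,
            pi=self.resolve_pi(), n_classes=self.n_classes)


# ---------------------------------------------------------------------------
# Sequence evolution

def resolve_tree(config: SimulationConfig,
                 rng: np.random.Generator) -> IndexedTree:
    if config.tree == "random":
        taxa = list(DEFAULT_TAXA[:config.n_taxa]) if config.n_taxa <= 9 \
            else [f"sp{i + 1}" for i in range(config.n_taxa)]
        return random_tree(taxa, rng, config.tree_length)
    tree = IndexedTree.from_newick(config.tree)
    return tree


def simulate_codon_alignment(config: SimulationConfig,
                             tree: Optional[IndexedTree] = None,
                             gene_id: str = "simgene",
                             rng: Optional[np.random.Generator] = None
                             ) -> tuple[CodonAlignment, np.ndarray,
                                        IndexedTree]:
    """Evolve a codon alignment; returns (alignment, true site-class
    index per codon, tree).  The selected class, when the model has one,
    is the last class index (M8) or classes 2/3 (branch-site A)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if tree is None:
        tree = resolve_tree(config, rng)
    params = config.model_params(
        foreground=config.foreground or tree.tip_labels[0])
    classes = model_site_classes(params, tree)
    pi = params.pi
    scale = mixture_scale(classes, params.kappa, pi)
    if scale <= 0:
        scale = 1.0  # omega=0 with no synonymous moves cannot occur (GY94)
    omegas: list[float] = []
    for c in classes:
        for w in (c.omega, c.fg_omega):
            if w is not None and not any(abs(w - o) < 1e-15 for o in omegas):
                omegas.append(w)
    P = transition_matrices(tree, np.array(omegas), params.kappa, pi, scale)
    Pcum = np.cumsum(P, axis=3)

    def omega_index(w: float) -> int:
        return next(i for i, o in enumerate(omegas) if abs(o - w) < 1e-15)

    n = config.n_codons
    weights = np.array([c.weight for c in classes])
    weights = weights / weights.sum()
    site_class = rng.choice(len(classes), size=n, p=weights)
    states = np.empty((tree.n_nodes, n), dtype=np.int64)
    states[tree.root] = rng.choice(gc.N_STATES, size=n, p=pi)
    for node in tree.postorder[::-1]:
        node = int(node)
        if node == tree.root:
            continue
        parent = tree.parent[node]
        for ci, c in enumerate(classes):
            sites = np.flatnonzero(site_class == ci)
            if len(sites) == 0:
                continue
            w = c.fg_omega if (c.fg_omega is not None
                               and c.fg_edge == node) else c.omega
            rows = Pcum[omega_index(w), node][states[parent, sites]]
            u = rng.random(len(sites)) * rows[:, -1]
            states[node, sites] = (rows < u[:, None]).sum(axis=1)

    seqs = ["".join(gc.SENSE_CODONS[s] for s in states[t])
            for t in range(tree.n_tips)]
    aln = CodonAlignment(gene_id, list(tree.tip_labels), seqs)
    return aln, site_class, tree


def selected_class_mask(config: SimulationConfig,
                        site_class: np.ndarray) -> np.ndarray:
    """Boolean mask of codons whose true class has omega > 1."""
    model = config.model
    if model == "M8":
        return site_class == config.n_classes  # the extra class is last
    if model in ("bsA", "branchsiteA"):
        return site_class >= 2
    return np.zeros_like(site_class, dtype=bool)


# ---------------------------------------------------------------------------
# Diploid pileups

_ALT = {i: [j for j in range(4) if j != i] for i in range(4)}


def _diploid_haplotypes(seq_codes: np.ndarray, het_rate: float,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    hap1 = seq_codes.copy()
    hap2 = seq_codes.copy()
    het = rng.random(len(hap1)) < het_rate
    for i in np.flatnonzero(het):
        hap2[i] = _ALT[hap1[i]][rng.integers(3)]
    return hap1, hap2


def _mutate(seq_codes: np.ndarray, rate: float,
            rng: np.random.Generator) -> np.ndarray:
    out = seq_codes.copy()
    hit = rng.random(len(out)) < rate
    for i in np.flatnonzero(hit):
        out[i] = _ALT[out[i]][rng.integers(3)]
    return out


def simulate_pileups(config: SimulationConfig, truth: CodonAlignment,
                     gene: GeneModel,
                     species: Optional[Sequence[str]] = None,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[dict[str, GenePileup], dict[str, np.ndarray]]:
    """Per-species read pileups over the gene's CDS.

    ``truth`` holds each species' haplotype-1 CDS (transcription order);
    a second haplotype is derived by planting heterozygous sites at the
    configured rate.  Returns (pileups, true diploid genotype codes):
    genotypes are (n_sites, 2) int arrays on the reference strand.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if species is None:
        species = list(truth.taxa)
    positions = np.sort(gene.cds_positions())
    n_sites = len(positions)
    piles: dict[str, GenePileup] = {}
    genotypes: dict[str, np.ndarray] = {}
    mean, sd = config.coverage_mean, config.coverage_sd
    if config.paralog_fraction > 0:
        # co-mapping reads from the second copy inflate depth: a clean
        # fraction (1-f) of the inflated total equals the base coverage
        boost = 1.0 / (1.0 - min(config.paralog_fraction, 0.99))
        mean *= boost
        sd *= boost
    var = sd * sd
    for sp in species:
        seq = truth.sequence_of(sp)
        fwd = seq if gene.strand == "+" else seq[::-1].translate(COMPLEMENT)
        codes = encode_bases(fwd)
        hap1, hap2 = _diploid_haplotypes(codes, config.heterozygosity, rng)
        genotypes[sp] = np.stack([hap1, hap2], axis=1)
        par_haps = None
        if config.paralog_fraction > 0:
            # the contaminating copy is itself diploid: its private
            # heterozygous variants are what surface at ~0.25/0.75
            par_base = _mutate(hap1, config.paralog_divergence, rng)
            par_haps = _diploid_haplotypes(par_base, config.heterozygosity,
                                           rng)

        if var > mean:
            r = mean * mean / (var - mean)
            cov = rng.negative_binomial(r, r / (r + mean), size=n_sites)
        else:
            cov = rng.poisson(mean, size=n_sites)
        site_idx = np.repeat(np.arange(n_sites), cov)
        n_reads = len(site_idx)
        src = rng.random(n_reads)
        hap_pick = rng.integers(0, 2, n_reads)
        base = np.where(hap_pick == 0, hap1[site_idx], hap2[site_idx])
        if par_haps is not None:
            from_par = src < config.paralog_fraction
            par_base_read = np.where(hap_pick == 0,
                                     par_haps[0][site_idx],
                                     par_haps[1][site_idx])
            base = np.where(from_par, par_base_read, base)
        err = rng.random(n_reads) < config.error_rate
        if err.any():
            shift = rng.integers(1, 4, int(err.sum()))
            base = base.copy()
            base[err] = (base[err] + shift) % 4
        mapq = rng.choice(np.asarray(config.mapq_values),
                          p=np.asarray(config.mapq_probs), size=n_reads)
        proper = rng.random(n_reads) < config.proper_pair_rate
        dup_group = np.full(n_reads, -1, dtype=np.int64)
        dup = rng.random(n_reads) < config.duplicate_rate
        n_dup = int(dup.sum())
        if n_dup:
            ids = np.arange(n_dup)
            dup_group[dup] = ids
            site_idx = np.concatenate([site_idx, site_idx[dup]])
            base = np.concatenate([base, base[dup]])
            mapq = np.concatenate([mapq, np.maximum(mapq[dup] - 1, 0)])
            proper = np.concatenate([proper, proper[dup]])
            dup_group = np.concatenate([dup_group, ids])

        deletion = np.zeros(n_sites, dtype=bool)
        n_tracts = rng.poisson(config.n_missing_tracts)
        for _ in range(n_tracts):
            L = max(1, int(rng.geometric(1.0 / config.missing_tract_len)))
            start = rng.integers(0, max(1, n_sites - L))
            deletion[start:start + L] = True

        piles[sp] = GenePileup(
            gene_id=gene.gene_id, species=sp, seq_id=gene.seq_id,
            positions=positions, read_site=site_idx,
            read_base=base.astype(np.int8), read_mapq=mapq.astype(np.int32),
            read_proper=proper, read_dup=dup_group, deletion=deletion)
    return piles, genotypes


# ---------------------------------------------------------------------------
# Gene models

def random_gene_model(gene_id: str, n_codons: int,
                      rng: np.random.Generator, seq_id: str = "chr1",
                      start: int = 0, max_exons: int = 4,
                      strand: Optional[str] = None) -> GeneModel:
    """A random exon structure carrying ``3 * n_codons`` CDS bases."""
    cds_len = 3 * n_codons
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                                  replace=False))
    else:
        cuts = np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [cds_len]]))
    exons = []
    pos = start
    for sz in sizes:
        exons.append((pos, pos + int(sz)))
        pos += int(sz) + int(rng.integers(50, 500))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return GeneModel(gene_id, seq_id, strand, exons)


# ---------------------------------------------------------------------------
# Gene universe with category labels

def simulate_gene_universe(n_genes: int, n_categories: int, psg_rate: float,
                           enrichment_spec: Optional[dict] = None,
                           seed: int = 0,
                           category_sizes: Optional[Sequence[int]] = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene table with planted PSG labels plus category memberships.

    ``enrichment_spec`` maps category id (e.g. "cat003") to a fold
    factor: members of that category receive PSG labels at
    ``fold * psg_rate`` (a gene in several categories takes the largest
    applicable rate).  Returns (genes, memberships, truth).
    """
    if not 0 <= psg_rate <= 1:
        raise ValueError("psg_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cats = [f"cat{i:03d}" for i in range(n_categories)]
    if enrichment_spec:
        unknown = set(enrichment_spec) - set(cats)
        if unknown:
            raise ValueError(f"enrichment_spec references unknown "
                             f"categories {sorted(unknown)}")
    if category_sizes is None:
        category_sizes = rng.integers(10, min(200, max(11, n_genes // 2)),
                                      size=n_categories)
    rows = []
    members: dict[str, list[str]] = {}
    for cat, size in zip(cats, category_sizes):
        sel = rng.choice(n_genes, size=min(int(size), n_genes),
                         replace=False)
        members[cat] = [genes[i] for i in sel]
        rows += [dict(gene_id=genes[i], category_id=cat) for i in sel]
    memberships = pd.DataFrame(rows, columns=["gene_id", "category_id"])

    rate = np.full(n_genes, psg_rate)
    spec = enrichment_spec or {}
    for cat, fold in spec.items():
        idx = [genes.index(g) for g in members[cat]]
        rate[idx] = np.maximum(rate[idx], min(1.0, fold * psg_rate))
    is_psg = rng.random(n_genes) < rate
    gene_table = pd.DataFrame(dict(gene_id=genes, is_psg=is_psg))
    truth = dict(psg_rate=psg_rate, enrichment_spec=dict(spec),
                 n_psg=int(is_psg.sum()))
    return gene_table, memberships, truth
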