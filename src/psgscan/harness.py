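"""One-command synthetic end-to-end exercise of the whole pipeline.

Simulates a cohort of genes (a mixture of purifying/neutral genes
evolved under M7 and positively selected genes under M8, a configurable
fraction contaminated by paralogous reads), pushes every gene through
consensus calling, paralog filtering, alignment QC, the M7/M8 sites
test with empirical-null calibration and q-values, branch-site scans
are exercised separately, category enrichment and the PSC positional
tests — then scores the run against the planted truth.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._phylo import random_tree
from .consensus_caller import build_consensus, consensus_alignment
from .enrichment_validation import (GenePSCData, enrich_categories,
                                    psc_location_test)
from .paralog_filter import filter_paralogs
from .selection_inference import PSC_POSTERIOR, sites_pipeline
from .synthetic_data import (DEFAULT_TAXA, SimulationConfig,
                             random_gene_model, selected_class_mask,
                             simulate_codon_alignment, simulate_pileups)

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Desk-scale defaults: 60 genes of 150-300 codons, 9 taxa, null
    calibration from 15 genes x 4 replicates."""

    n_genes: int = 60
    n_taxa: int = 9
    n_codons_range: tuple[int, int] = (150, 300)
    tree_length: float = 3.0
    frac_selected: float = 0.2
    frac_paralog: float = 0.1
    # selected-gene (M8) regime
    sel_p0: float = 0.85
    sel_omega_s: float = 3.0
    # null (M7) regime
    null_beta_p: float = 0.5
    null_beta_q: float = 1.5
    kappa: float = 2.0
    # pileup layer
    heterozygosity: float = 0.01
    coverage_mean: float = 40.0
    coverage_sd: float = 12.0
    #: sd of the per-gene lognormal coverage factor (mappability/GC)
    coverage_gene_sd: float = 0.15
    paralog_fraction: float = 0.5
    paralog_divergence: float = 0.05
    # inference
    alpha: float = 0.05
    null_n_sample: int = 15
    null_n_reps: int = 4
    n_starts: int = 1
    min_codons: int = 100
    qvalue_method: str = "storey"
    n_categories: int = 8
    n_resamples: int = 2000


@dataclass
class HarnessReport:
    n_genes: int
    n_dropped_paralog: int
    paralog_true_positives: int
    paralog_false_positives: int
    paralog_sensitivity: float
    paralog_specificity: float
    n_tested: int
    n_flagged_psg: int
    psg_precision: float
    psg_recall: float
    psc_site_recall: float
    type_I_error: float
    enrichment_rows: int
    psc_location_rows: int
    runtime: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_cohort(config: CohortConfig, seed: int = 0) -> HarnessReport:
    """Simulate, run every stage, and score against planted truth."""
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()
    runtime: dict[str, float] = {}
    taxa = list(DEFAULT_TAXA[:config.n_taxa])
    ref = taxa[0]

    if config.n_genes == 0:
        return HarnessReport(0, 0, 0, 0, float("nan"), float("nan"), 0, 0,
                             float("nan"), float("nan"), float("nan"),
                             float("nan"), 0, 0, runtime={})

    # ---- simulate ---------------------------------------------------------
    genes = {}
    truth_sel = {}
    truth_paralog = {}
    sel_sites = {}
    offset = 0
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        n_codons = int(rng.integers(config.n_codons_range[0],
                                    config.n_codons_range[1] + 1))
        selected = rng.random() < config.frac_selected
        contaminated = rng.random() < config.frac_paralog
        tree = random_tree(taxa, rng, config.tree_length)
        sim = SimulationConfig(
            model="M8" if selected else "M7", kappa=config.kappa,
            beta_p=config.null_beta_p, beta_q=config.null_beta_q,
            p0=config.sel_p0, omega_s=config.sel_omega_s,
            n_codons=n_codons, tree_length=config.tree_length,
            heterozygosity=config.heterozygosity,
            coverage_mean=config.coverage_mean
            * float(rng.lognormal(0.0, config.coverage_gene_sd)),
            coverage_sd=config.coverage_sd,
            paralog_fraction=config.paralog_fraction if contaminated else 0.0,
            paralog_divergence=config.paralog_divergence)
        aln, site_class, tree = simulate_codon_alignment(
            sim, tree=tree, gene_id=gid, rng=rng)
        model = random_gene_model(gid, n_codons, rng, start=offset)
        offset = model.span()[1] + int(rng.integers(200, 1000))
        genes[gid] = dict(sim=sim, truth=aln, tree=tree, model=model)
        truth_sel[gid] = selected
        truth_paralog[gid] = contaminated
        sel_sites[gid] = np.flatnonzero(selected_class_mask(sim, site_class))
    runtime["simulate"] = time.perf_counter() - t0

    # ---- consensus calling ------------------------------------------------
    t0 = time.perf_counter()
    stats_by_gene = {}
    alignments = {}
    missing_by_gene = {}
    for gid, g in genes.items():
        piles, _ = simulate_pileups(g["sim"], g["truth"], g["model"],
                                    species=taxa[1:], rng=rng)
        ref_cds = g["truth"].sequence_of(ref)
        seqs, stats = build_consensus(g["model"], piles, ref_cds=ref_cds)
        alignments[gid] = consensus_alignment(g["model"], seqs,
                                              (ref, ref_cds))
        stats_by_gene[gid] = stats
        runs = []
        for st in stats.values():
            runs.extend(st.missing_runs)
        missing_by_gene[gid] = runs
    runtime["consensus"] = time.perf_counter() - t0

    # ---- paralog filter ---------------------------------------------------
    t0 = time.perf_counter()
    disposition = filter_paralogs(stats_by_gene)
    dropped = set(disposition.loc[
        disposition.classification == "paralogous", "gene_id"])
    tp = sum(1 for g in dropped if truth_paralog[g])
    fp = len(dropped) - tp
    n_true_par = sum(truth_paralog.values())
    n_clean = config.n_genes - n_true_par
    runtime["paralog_filter"] = time.perf_counter() - t0

    # ---- sites tests ------------------------------------------------------
    t0 = time.perf_counter()
    kept_ids = [gid for gid in genes if gid not in dropped]
    alns = [alignments[gid] for gid in kept_ids]
    trees = [genes[gid]["tree"] for gid in kept_ids]
    records, fits, qcs, _null = sites_pipeline(
        alns, trees, null_n_sample=config.null_n_sample,
        null_n_reps=config.null_n_reps, alpha=config.alpha,
        seed=seed + 31, n_starts=config.n_starts,
        min_codons=config.min_codons,
        qvalue_method=config.qvalue_method)
    runtime["sites_tests"] = time.perf_counter() - t0

    flagged = {r.gene_id for r in records if r.psg_flag}
    tested = [r.gene_id for r in records]
    true_pos = sum(1 for g in flagged if truth_sel[g])
    n_true_sel_tested = sum(1 for g in tested if truth_sel[g])
    n_null_tested = sum(1 for g in tested if not truth_sel[g])
    null_flagged = sum(1 for g in flagged if not truth_sel[g])
    precision = true_pos / len(flagged) if flagged else float("nan")
    recall = (true_pos / n_true_sel_tested if n_true_sel_tested
              else float("nan"))
    type_I = (null_flagged / n_null_tested if n_null_tested
              else float("nan"))

    # PSC site recall among flagged truly selected genes
    qc_by_gene = {q.gene_id: q for q in qcs}
    hits = total = 0
    for r in records:
        if not (r.psg_flag and truth_sel[r.gene_id]):
            continue
        truth_codons = sel_sites[r.gene_id]
        psc_codons = {c for c, _, _, _ in r.psc_list}
        analyzed = set(qc_by_gene[r.gene_id].kept_codon_indices.tolist())
        scoreable = [c for c in truth_codons if c in analyzed]
        total += len(scoreable)
        hits += sum(1 for c in scoreable if c in psc_codons)
    psc_recall = hits / total if total else float("nan")

    # ---- enrichment + positional validation -------------------------------
    t0 = time.perf_counter()
    enrich_rows = 0
    if tested and config.n_categories > 0:
        cats = rng.integers(0, config.n_categories, size=len(tested))
        memberships = pd.DataFrame(dict(
            gene_id=tested,
            category_id=[f"cat{c:03d}" for c in cats]))
        enr = enrich_categories(memberships, flagged, tested,
                                n_resamples=config.n_resamples,
                                seed=seed + 77, test_family="branch")
        enrich_rows = len(enr)
    psc_data = []
    for r in records:
        if not r.psc_list:
            continue
        qc = qc_by_gene[r.gene_id]
        psc_data.append(GenePSCData(
            gene=genes[r.gene_id]["model"],
            analyzed_codons=qc.kept_codon_indices,
            psc_codons=np.array([c for c, _, _, _ in r.psc_list]),
            missing_runs=missing_by_gene[r.gene_id]))
    loc = psc_location_test(psc_data) if psc_data else pd.DataFrame()
    runtime["enrichment_validation"] = time.perf_counter() - t0

    return HarnessReport(
        n_genes=config.n_genes, n_dropped_paralog=len(dropped),
        paralog_true_positives=tp, paralog_false_positives=fp,
        paralog_sensitivity=tp / n_true_par if n_true_par else float("nan"),
        paralog_specificity=((n_clean - fp) / n_clean if n_clean
                             else float("nan")),
        n_tested=len(tested), n_flagged_psg=len(flagged),
        psg_precision=precision, psg_recall=recall,
        psc_site_recall=psc_recall, type_I_error=type_I,
        enrichment_rows=enrich_rows, psc_location_rows=len(loc),
        runtime=runtime)
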