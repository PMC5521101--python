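"""Genome-wide orchestration of the positive-selection tests.

The sites test compares M8 against M7 per gene with the LRT
2*(lnL_M8 - lnL_M7), converts LRTs to P-values against an *empirical*
null distribution (M7-parametric simulations on each gene's own tree
and M7 MLEs), and controls the FDR with q-values.  Branch-site model A
is tested against its omega2=1 null on every terminal branch, with the
1:1 mixture of a point mass at zero and chi-square(1) as the reference
distribution and a per-gene Bonferroni correction across branches.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from . import genetic_code as gc
from ._phylo import IndexedTree
from .codon_models import CodonModelFit, fit_model, site_posteriors
from .io_formats import CodonAlignment, ResultRecord
from .synthetic_data import SimulationConfig, simulate_codon_alignment

logger = logging.getLogger(__name__)

MIN_CODONS = 100
STOP_TRIM = 10        # codons trimmed from the reference gene's end
PSC_POSTERIOR = 0.95  # BEB threshold for a positively selected codon
DEFAULT_FDR = 0.05


# ---------------------------------------------------------------------------
# Alignment QC

@dataclass
class AlignmentQC:
    gene_id: str
    n_codons_input: int
    n_codons_after_ambiguity_removal: int = 0
    n_codons_after_cleandata: int = 0
    stop_trim_applied: bool = False
    passed: bool = False
    reasons: list[str] = field(default_factory=list)
    #: original codon-column index of every retained column
    kept_codon_indices: Optional[np.ndarray] = None


_AMBIG = gc.AMBIGUITY_CODES | frozenset("BDHV")


def _codon_flags(aln: CodonAlignment):
    """(has_ambiguity, has_missing, ) boolean per codon column."""
    n = aln.n_codons
    amb = np.zeros(n, dtype=bool)
    miss = np.zeros(n, dtype=bool)
    for seq in aln.sequences:
        for i in range(n):
            codon = seq[3 * i:3 * i + 3]
            if any(c in _AMBIG for c in codon):
                amb[i] = True
            if "N" in codon or "-" in codon:
                miss[i] = True
    return amb, miss


def _has_stop(aln: CodonAlignment) -> bool:
    for seq in aln.sequences:
        for i in range(aln.n_codons):
            if seq[3 * i:3 * i + 3] in gc.STOP_CODONS:
                return True
    return False


def qc_alignment(aln: CodonAlignment, min_codons: int = MIN_CODONS,
                 gate: str = "post_clean"
                 ) -> tuple[Optional[CodonAlignment], AlignmentQC]:
    """Clean an alignment for likelihood work.

    Codon columns containing any two-base ambiguity code in any taxon
    are removed first (heterozygous codons are not fixed differences);
    then columns containing a gap or N in any taxon (cleandata
    semantics).  If a stop codon survives, the last STOP_TRIM codons of
    the reference gene are trimmed and cleaning is redone; a persistent
    stop fails the gene.  The ``min_codons`` gate applies to the
    post-cleaning count by default (``gate='pre_clean'`` gates the input
    length instead, the laxer ordering).
    """
    if gate not in ("post_clean", "pre_clean"):
        raise ValueError("gate must be 'post_clean' or 'pre_clean'")
    qc = AlignmentQC(gene_id=aln.gene_id, n_codons_input=aln.n_codons)
    if gate == "pre_clean" and aln.n_codons < min_codons:
        qc.reasons.append("fewer_than_min_codons")
        return None, qc

    def clean(a: CodonAlignment):
        amb, miss = _codon_flags(a)
        keep_amb = ~amb
        inter = a.subset_codons(keep_amb)
        amb_idx = np.flatnonzero(keep_amb)
        _, miss2 = _codon_flags(inter)
        keep2 = ~miss2
        final = inter.subset_codons(keep2)
        return inter, final, amb_idx[np.flatnonzero(keep2)]

    inter, cleaned, kept = clean(aln)
    if _has_stop(cleaned) and aln.n_codons > STOP_TRIM:
        qc.stop_trim_applied = True
        trimmed = aln.subset_codons(np.arange(aln.n_codons - STOP_TRIM))
        inter, cleaned, kept = clean(trimmed)
    qc.n_codons_after_ambiguity_removal = inter.n_codons
    qc.n_codons_after_cleandata = cleaned.n_codons
    qc.kept_codon_indices = kept
    if _has_stop(cleaned):
        qc.reasons.append("stop_codon")
        return None, qc
    if gate == "post_clean" and cleaned.n_codons < min_codons:
        qc.reasons.append("fewer_than_min_codons")
        return None, qc
    if cleaned.n_codons < 1:
        qc.reasons.append("empty_after_cleaning")
        return None, qc
    qc.passed = True
    return cleaned, qc


# ---------------------------------------------------------------------------
# Sites test (M7 vs M8)

@dataclass
class GeneFit:
    gene_id: str
    fit_m7: CodonModelFit
    fit_m8: CodonModelFit
    LRT: float
    converged: bool
    tree: IndexedTree
    alignment: CodonAlignment


def sites_test(cleaned: CodonAlignment, tree: IndexedTree,
               n_starts: int = 3, seed: int = 0) -> GeneFit:
    """Fit M7 and M8 (M8 warm-started from the M7 optimum) and form the
    clamped LRT = max(0, 2*(lnL_M8 - lnL_M7))."""
    fit7 = fit_model(cleaned, tree, "M7", n_starts=n_starts, seed=seed)
    init8 = dataclasses.replace(fit7.params, model="M8", p0=0.9, omega_s=2.0)
    fit8a = fit_model(cleaned, tree, "M8", init=init8, n_starts=1,
                      seed=seed + 1)
    fit8 = fit8a
    if n_starts > 1:
        fit8b = fit_model(cleaned, tree, "M8", n_starts=n_starts - 1,
                          seed=seed + 2)
        if fit8b.lnL > fit8.lnL:
            fit8 = fit8b
    lrt = 2.0 * (fit8.lnL - fit7.lnL)
    if lrt < 0:
        if lrt < -1e-2:
            logger.warning("gene %s: LRT %.4g < 0 beyond optimizer noise",
                           cleaned.gene_id, lrt)
        lrt = 0.0
    return GeneFit(cleaned.gene_id, fit7, fit8, lrt,
                   fit7.converged and fit8.converged, tree, cleaned)


def extract_pscs(fit: GeneFit, kept_codon_indices: Optional[np.ndarray],
                 coordinate_map: Optional[np.ndarray] = None,
                 threshold: float = PSC_POSTERIOR
                 ) -> list[tuple[int, float, int, int]]:
    """BEB positively selected codons above ``threshold``, mapped back to
    original codon indices and genomic coordinates when available."""
    beb = site_posteriors(fit.fit_m8, "BEB")
    out = []
    for i in np.flatnonzero(beb > threshold):
        orig = int(kept_codon_indices[i]) if kept_codon_indices is not None \
            else int(i)
        if coordinate_map is not None:
            pos = coordinate_map[orig]
            a, b = int(pos.min()), int(pos.max()) + 1
        else:
            a, b = 3 * orig, 3 * orig + 3
        out.append((orig, float(beb[i]), a, b))
    return out


# ---------------------------------------------------------------------------
# Empirical null calibration

def calibrate_empirical_null(gene_fits: Sequence[GeneFit],
                             n_sample: int = 650, n_reps: int = 18,
                             seed: int = 0, n_starts: int = 1
                             ) -> np.ndarray:
    """Pooled null LRT sample: for ``n_sample`` randomly chosen genes,
    simulate ``n_reps`` alignments under each gene's M7 MLEs on its own
    tree, refit M7 and M8, and collect the LRTs."""
    fits = [g for g in gene_fits if g.converged]
    if not fits:
        raise ValueError("no converged gene fits to calibrate from")
    rng = np.random.default_rng(seed)
    n_sample = min(n_sample, len(fits))
    chosen = rng.choice(len(fits), size=n_sample, replace=False)
    lrts = []
    n_dropped = 0
    for gi in chosen:
        g = fits[gi]
        p7 = g.fit_m7.params
        config = SimulationConfig(
            model="M7", kappa=p7.kappa, beta_p=p7.beta_p, beta_q=p7.beta_q,
            codon_freqs=p7.pi, n_codons=g.fit_m7.n_codons,
            n_classes=p7.n_classes)
        for rep in range(n_reps):
            sub = np.random.default_rng((seed, gi, rep)).integers(2 ** 31)
            aln, _, _ = simulate_codon_alignment(
                config, tree=g.tree, gene_id=f"{g.gene_id}_null{rep}",
                rng=np.random.default_rng(sub))
            try:
                res = sites_test(aln, g.tree, n_starts=n_starts, seed=sub)
            except FloatingPointError:
                n_dropped += 1
                continue
            if res.converged:
                lrts.append(res.LRT)
            else:
                n_dropped += 1
    if n_dropped:
        logger.info("empirical null: dropped %d unconverged replicates",
                    n_dropped)
    if not lrts:
        raise ValueError("empirical null calibration produced no LRTs")
    return np.asarray(lrts)


def empirical_pvalue(lrt, null_sample: np.ndarray):
    """Add-one ecdf P-value: (1 + #{null >= LRT}) / (1 + n_null)."""
    null_sample = np.asarray(null_sample)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    lrt_arr = np.atleast_1d(np.asarray(lrt, dtype=float))
    exceed = (null_sample[None, :] >= lrt_arr[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + null_sample.size)
    return float(p[0]) if np.isscalar(lrt) or np.ndim(lrt) == 0 else p


# ---------------------------------------------------------------------------
# q-values

def _storey_pi0(p: np.ndarray) -> float:
    """Smoothed Storey pi0 estimate (spline through pi0(lambda))."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam))
                      for lam in lambdas])
    if np.allclose(pi0_l, pi0_l[0]):
        pi0 = pi0_l[-1]
    else:
        try:
            spl = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spl(lambdas[-1]))
        except Exception:
            pi0 = float(pi0_l[-1])
    return float(min(max(pi0, 1.0 / m), 1.0))


def compute_qvalues(pvalues, alpha: float = DEFAULT_FDR,
                    method: str = "storey"
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """q-values and PSG flags at FDR ``alpha``.

    ``method='storey'`` (default) uses Storey's q-values with a
    smoothed pi0 estimate; ``method='bh'`` sets pi0 = 1
    (Benjamini-Hochberg).  Returns (q, flags, pi0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "storey":
        pi0 = _storey_pi0(p)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError("method must be 'storey' or 'bh'")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out, out < alpha, pi0


# ---------------------------------------------------------------------------
# Branch-site scan

@dataclass
class BranchSitesResult:
    gene_id: str
    branch: str
    LRT: float
    p_mixture: float
    p_bonferroni: float
    significant: bool
    converged: bool = True


def mixture_pvalue(lrt: float) -> float:
    """P-value under the 1:1 mixture of a point mass at 0 and
    chi-square(1); by convention P(LRT=0) = 1."""
    if lrt <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt, df=1))


def branch_sites_scan(cleaned: CodonAlignment, tree: IndexedTree,
                      n_starts: int = 1, seed: int = 0,
                      alpha: float = 0.05) -> list[BranchSitesResult]:
    """Branch-site model A vs its null on every terminal branch, with a
    per-gene Bonferroni across the branches actually tested."""
    raw = []
    for bi, taxon in enumerate(tree.tip_labels):
        fit0 = fit_model(cleaned, tree, "bsA_null", foreground=taxon,
                         n_starts=n_starts, seed=seed + 101 * bi,
                         compute_posteriors=False)
        init1 = dataclasses.replace(fit0.params, model="bsA", omega2=2.0)
        fit1 = fit_model(cleaned, tree, "bsA", init=init1, foreground=taxon,
                         n_starts=n_starts, seed=seed + 101 * bi + 1,
                         compute_posteriors=False)
        lrt = max(0.0, 2.0 * (fit1.lnL - fit0.lnL))
        raw.append((taxon, lrt, fit0.converged and fit1.converged))
    n_tested = sum(1 for _, _, ok in raw if ok)
    out = []
    for taxon, lrt, ok in raw:
        p = mixture_pvalue(lrt)
        p_bonf = min(1.0, p * max(n_tested, 1))
        out.append(BranchSitesResult(
            gene_id=cleaned.gene_id, branch=taxon, LRT=lrt, p_mixture=p,
            p_bonferroni=p_bonf,
            significant=ok and p_bonf < alpha, converged=ok))
    return out


# ---------------------------------------------------------------------------
# Summaries

_DEG_CLASSES: dict[int, list[str]] = {}
for _aa in set(gc.CODON_AA):
    if _aa == "*":
        continue
    _deg = gc.CODON_AA.count(_aa)
    _DEG_CLASSES.setdefault(_deg, []).append(_aa)


def effective_number_of_codons(seq: str) -> float:
    """Wright's ENC: 20 at maximal codon bias, 61 at uniform usage.

    Codons containing ambiguity/missing symbols and stop codons are
    skipped.  Returns NaN when no degeneracy class is estimable.
    """
    counts: dict[str, dict[str, int]] = {}
    for i in range(len(seq) // 3):
        codon = seq[3 * i:3 * i + 3]
        idx = gc.CODON_INDEX.get(codon)
        if idx is None:
            continue
        aa = gc.CODON_AA[idx]
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1
    f_by_class: dict[int, list[float]] = {}
    for deg, aas in _DEG_CLASSES.items():
        if deg == 1:
            continue
        for aa in aas:
            cc = counts.get(aa, {})
            n = sum(cc.values())
            if n < 2:
                continue
            s = sum((c / n) ** 2 for c in cc.values())
            f = (n * s - 1.0) / (n - 1.0)
            if f > 0:
                f_by_class.setdefault(deg, []).append(f)
    fbar = {deg: np.mean(v) for deg, v in f_by_class.items() if v}
    if 2 not in fbar or 4 not in fbar:
        return float("nan")
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if 6 not in fbar:
        fbar[6] = fbar[4]
    enc = (2.0 + len(_DEG_CLASSES[2]) / fbar[2] + len(_DEG_CLASSES[3]) / fbar[3]
           + len(_DEG_CLASSES[4]) / fbar[4] + len(_DEG_CLASSES[6]) / fbar[6])
    return float(min(enc, 61.0))


def gc_content(seq: str) -> float:
    counted = [c for c in seq if c in "ACGT"]
    if not counted:
        return float("nan")
    return sum(c in "GC" for c in counted) / len(counted)


def summarize_genes(per_gene: pd.DataFrame,
                    binary_traits: Sequence[str] = (),
                    continuous_traits: Sequence[str] = ("n_codons", "dN",
                                                        "dS", "dN_dS"),
                    binary_alternative: str = "two-sided",
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summary (PSG vs non-PSG vs all) and contrast tests.

    ``per_gene`` needs columns gene_id, psg_flag, LRT, dN, dS plus the
    requested trait columns.  Continuous traits are contrasted by
    two-sided Mann-Whitney U; binary traits by Fisher exact (two-sided
    by default, 'greater' for a one-tailed enrichment question).  Mean
    dN/dS is reported both as ratio-of-means (mean dN / mean dS) and
    mean-of-ratios.
    """
    req = {"gene_id", "psg_flag", "LRT", "dN", "dS"}
    missing = req - set(per_gene.columns)
    if missing:
        raise ValueError(f"per_gene table lacks columns {sorted(missing)}")
    groups = {
        "PSGs": per_gene[per_gene.psg_flag],
        "non-PSGs": per_gene[~per_gene.psg_flag.astype(bool)],
        "TOTAL": per_gene,
    }
    rows = []
    for name, df in groups.items():
        row = dict(group=name, n_genes=len(df))
        if len(df):
            row["mean_codons"] = df["n_codons"].mean() \
                if "n_codons" in df else np.nan
            row["mean_LRT"] = df["LRT"].mean()
            row["mean_dN"] = df["dN"].mean()
            row["mean_dS"] = df["dS"].mean()
            row["dN_dS_ratio_of_means"] = (df["dN"].mean() / df["dS"].mean()
                                           if df["dS"].mean() > 0 else np.nan)
            if "dN_dS" in df:
                row["dN_dS_mean_of_ratios"] = df["dN_dS"].mean()
        rows.append(row)
    summary = pd.DataFrame(rows)

    tests = []
    psg = groups["PSGs"]
    non = groups["non-PSGs"]
    for col in continuous_traits:
        if col not in per_gene.columns or not len(psg) or not len(non):
            continue
        a = psg[col].dropna()
        b = non[col].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and \
                set(a.unique()) == set(b.unique()):
            p = 1.0
        elif len(a) and len(b):
            p = float(stats.mannwhitneyu(a, b,
                                         alternative="two-sided").pvalue)
        else:
            continue
        tests.append(dict(trait=col, test="mannwhitneyu", p=p))
    for col in binary_traits:
        if col not in per_gene.columns or not len(psg) or not len(non):
            continue
        table = [[int(psg[col].sum()), int(len(psg) - psg[col].sum())],
                 [int(non[col].sum()), int(len(non) - non[col].sum())]]
        p = float(stats.fisher_exact(table,
                                     alternative=binary_alternative)[1])
        tests.append(dict(trait=col, test=f"fisher_{binary_alternative}",
                          p=p))
    return summary, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# End-to-end sites pipeline over a cohort of cleaned alignments

def sites_pipeline(alignments: Sequence[CodonAlignment],
                   trees: Sequence[IndexedTree],
                   null_n_sample: int = 15, null_n_reps: int = 4,
                   alpha: float = DEFAULT_FDR, seed: int = 0,
                   n_starts: int = 1, qc_gate: str = "post_clean",
                   min_codons: int = MIN_CODONS,
                   qvalue_method: str = "storey",
                   compute_pscs: bool = True):
    """QC, fit, calibrate, test: the genome-wide sites-model scan.

    Returns (records, gene_fits, qcs, null_sample) where ``records`` is
    a list of ResultRecord for every gene that passed QC and converged.
    """
    qcs = []
    fits = []
    kept_maps = {}
    for aln, tree in zip(alignments, trees):
        cleaned, qc = qc_alignment(aln, min_codons=min_codons, gate=qc_gate)
        qcs.append(qc)
        if cleaned is None:
            continue
        gf = sites_test(cleaned, tree, n_starts=n_starts,
                        seed=seed + zlib.crc32(aln.gene_id.encode()) % 10000)
        kept_maps[aln.gene_id] = (qc.kept_codon_indices, aln.coordinate_map)
        fits.append(gf)
    if not fits:
        return [], [], qcs, np.array([])
    null_sample = calibrate_empirical_null(
        fits, n_sample=null_n_sample, n_reps=null_n_reps, seed=seed + 7,
        n_starts=n_starts)
    ok = [g for g in fits if g.converged]
    pvals = empirical_pvalue(np.array([g.LRT for g in ok]), null_sample)
    qvals, flags, _ = compute_qvalues(pvals, alpha=alpha,
                                      method=qvalue_method)
    records = []
    for g, p, q, flag in zip(ok, pvals, qvals, flags):
        kept, cmap = kept_maps[g.gene_id]
        pscs = []
        if compute_pscs and flag:
            pscs = extract_pscs(g, kept, cmap)
        records.append(ResultRecord(
            gene_id=g.gene_id, n_codons_analyzed=g.fit_m8.n_codons,
            lnL_m7=g.fit_m7.lnL, lnL_m8=g.fit_m8.lnL, LRT=g.LRT,
            p_empirical=float(p), q_value=float(q),
            dN=g.fit_m8.dN, dS=g.fit_m8.dS, dN_dS=g.fit_m8.dN_dS,
            psg_flag=bool(flag), psc_list=pscs))
    return records, fits, qcs, null_sample
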