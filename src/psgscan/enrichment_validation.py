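"""Functional enrichment of positively selected genes and positional
validation of positively selected codons.

Category enrichment follows the hypergeometric scheme: the expected
PSG count of a category with n tested genes is n*K/N (K PSGs among N
tested genes), fold enrichment is observed/expected, and the empirical
P-value is obtained by re-drawing the K PSG labels without replacement
(10,000 resamples by default, add-one corrected), with the exact
hypergeometric tail computed alongside.  A-priori candidate categories
get one-tailed Fisher exact tests.

The positional tests ask whether PSCs concentrate within 3/5/7 amino
acids of exon borders or adjacent to indel/missing-data regions — the
signature of alignment or annotation artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .selection_inference import compute_qvalues

logger = logging.getLogger(__name__)

MIN_CATEGORY_GENES = 20   # genome-wide family: smaller categories dropped
DEFAULT_RESAMPLES = 10_000
ENRICH_FDR = 0.10


@dataclass
class EnrichmentRecord:
    category_id: str
    n_tested: int
    n_psg: int
    expected: float
    fold: float
    p_empirical: float
    p_exact: float
    q_value: float = float("nan")


def expected_and_fold(n_tested: int, n_psg: int, K: int, N: int
                      ) -> tuple[float, float]:
    """Hypergeometric expectation n*K/N and fold enrichment; the fold
    uses the unrounded expectation."""
    if N <= 0 or K < 0:
        raise ValueError("need N > 0 and K >= 0")
    expected = n_tested * K / N
    fold = n_psg / expected if expected > 0 else float("nan")
    return expected, fold


def enrich_categories(memberships: pd.DataFrame, psg_set: Iterable[str],
                      universe: Iterable[str],
                      n_resamples: int = DEFAULT_RESAMPLES, seed: int = 0,
                      test_family: str = "genome",
                      alpha: float = ENRICH_FDR) -> pd.DataFrame:
    """Category enrichment of PSGs over a tested gene universe.

    ``memberships`` has columns gene_id, category_id (category_name
    optional).  ``test_family='genome'`` applies the genome-wide sites
    test filters (drop categories with < 20 genes or exactly one PSG);
    ``'branch'`` keeps every category with at least one PSG.  q-values
    are computed on the empirical P-values of the retained categories.
    """
    universe = set(universe)
    psg_set = set(psg_set)
    if not psg_set <= universe:
        raise ValueError("psg_set must be a subset of the universe")
    unknown = set(memberships["gene_id"]) - universe
    if unknown:
        raise ValueError(f"memberships reference genes outside the "
                         f"universe: {sorted(unknown)[:5]} ...")
    if test_family not in ("genome", "branch"):
        raise ValueError("test_family must be 'genome' or 'branch'")
    N, K = len(universe), len(psg_set)
    rng = np.random.default_rng(seed)
    rows = []
    for cat, sub in memberships.groupby("category_id", sort=True):
        genes = set(sub["gene_id"])
        n = len(genes)
        k = len(genes & psg_set)
        if test_family == "genome" and (n < MIN_CATEGORY_GENES or k == 1):
            continue
        if test_family == "branch" and k < 1:
            continue
        expected, fold = expected_and_fold(n, k, K, N)
        # marginal of a without-replacement redraw of the K PSG labels
        draws = rng.hypergeometric(n, N - n, K, size=n_resamples)
        p_emp = (1.0 + (draws >= k).sum()) / (1.0 + n_resamples)
        p_exact = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append(dict(category_id=cat, n_tested=n, n_psg=k,
                         expected=expected, fold=fold,
                         p_empirical=float(p_emp), p_exact=p_exact))
    df = pd.DataFrame(rows)
    if len(df):
        q, flags, _ = compute_qvalues(df["p_empirical"].to_numpy(),
                                      alpha=alpha, method="bh")
        df["q_value"] = q
        df["significant"] = flags
    return df


def fisher_apriori(category_genes: Iterable[str], psg_set: Iterable[str],
                   universe: Iterable[str]) -> float:
    """One-tailed Fisher exact P for PSG enrichment in an a-priori
    candidate category."""
    universe = set(universe)
    category = set(category_genes) & universe
    psg = set(psg_set)
    if not category:
        raise ValueError("empty category")
    k = len(category & psg)
    n = len(category)
    K = len(psg)
    N = len(universe)
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


# ---------------------------------------------------------------------------
# PSC positional tests

@dataclass
class GenePSCData:
    """Per-gene inputs for the positional tests: the gene model, the
    original codon indices that survived QC, the PSC codon indices
    (subset of analyzed), and recorded missing/indel reference runs."""

    gene: GeneModel
    analyzed_codons: np.ndarray
    psc_codons: np.ndarray
    missing_runs: Sequence[tuple[int, int]] = ()


def exon_border_mask(gene: GeneModel, codons: np.ndarray,
                     window: int) -> np.ndarray:
    """True for codons within ``window`` amino acids of an exon border.

    Borders are measured along the spliced CDS; a codon split by an
    intron belongs to the exon containing its first base; both edges of
    every exon count (including the gene's ends).
    """
    exon_of = gene.exon_of_cds_index()
    codon_exon = exon_of[::3][:gene.n_codons]
    # first/last codon (inclusive) of each exon in spliced-CDS order
    firsts: dict[int, int] = {}
    lasts: dict[int, int] = {}
    for i, e in enumerate(codon_exon):
        firsts.setdefault(int(e), i)
        lasts[int(e)] = i
    mask = np.zeros(len(codons), dtype=bool)
    for j, c in enumerate(np.asarray(codons, dtype=int)):
        e = int(codon_exon[c])
        d = min(c - firsts[e], lasts[e] - c)
        mask[j] = d < window
    return mask


def missing_adjacency_mask(gene: GeneModel, codons: np.ndarray,
                           missing_runs: Sequence[tuple[int, int]],
                           window: int) -> np.ndarray:
    """True for codons within ``window`` amino acids (in CDS
    coordinates) of the boundary of a recorded missing/indel run."""
    cds_pos = gene.cds_positions()
    pos_to_cds = {int(p): i for i, p in enumerate(cds_pos)}
    mask = np.zeros(len(codons), dtype=bool)
    codons = np.asarray(codons, dtype=int)
    run_codon_spans = []
    for (a, b) in missing_runs:
        idxs = [pos_to_cds[p] for p in range(a, b) if p in pos_to_cds]
        if not idxs:
            continue
        c_lo = min(idxs) // 3
        c_hi = max(idxs) // 3
        run_codon_spans.append((c_lo, c_hi))
    for j, c in enumerate(codons):
        for c_lo, c_hi in run_codon_spans:
            if c_lo - window <= c <= c_hi + window and not \
                    (c_lo <= c <= c_hi):
                mask[j] = True
                break
            if c_lo <= c <= c_hi:
                # analyzed codons inside a run are rare (partially
                # missing codons); treat as adjacent
                mask[j] = True
                break
    return mask


def psc_location_test(genes_data: Sequence[GenePSCData],
                      windows: Sequence[int] = (3, 5, 7)) -> pd.DataFrame:
    """Fisher 2x2 tests (PSC vs non-PSC x in-window vs out) pooled over
    genes, separately for exon-border windows and missing/indel
    adjacency, for each window size.  Fold > 1 means PSCs are enriched
    in the window; the two-tailed P is reported with the direction.
    """
    rows = []
    for kind in ("exon_border", "missing_adjacent"):
        for w in windows:
            n_in_psc = n_in_non = n_out_psc = n_out_non = 0
            for gd in genes_data:
                analyzed = np.asarray(gd.analyzed_codons, dtype=int)
                if len(analyzed) == 0:
                    continue
                is_psc = np.isin(analyzed, np.asarray(gd.psc_codons,
                                                      dtype=int))
                if kind == "exon_border":
                    in_w = exon_border_mask(gd.gene, analyzed, w)
                else:
                    in_w = missing_adjacency_mask(gd.gene, analyzed,
                                                  gd.missing_runs, w)
                n_in_psc += int((in_w & is_psc).sum())
                n_in_non += int((in_w & ~is_psc).sum())
                n_out_psc += int((~in_w & is_psc).sum())
                n_out_non += int((~in_w & ~is_psc).sum())
            table = [[n_in_psc, n_out_psc], [n_in_non, n_out_non]]
            total_psc = n_in_psc + n_out_psc
            total = n_in_psc + n_in_non + n_out_psc + n_out_non
            frac_in = (n_in_psc + n_in_non) / total if total else np.nan
            exp_in_psc = total_psc * frac_in if total else np.nan
            fold = (n_in_psc / exp_in_psc) if exp_in_psc else np.nan
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(dict(
                test=kind, window=w, n_psc_in=n_in_psc, n_psc_out=n_out_psc,
                n_non_in=n_in_non, n_non_out=n_out_non,
                fold=float(fold) if np.isfinite(fold) else np.nan,
                p_two_tailed=float(p),
                direction=("enriched" if np.isfinite(fold) and fold > 1
                           else "under-enriched")))
    return pd.DataFrame(rows)
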