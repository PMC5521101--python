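"""QC rules, empirical P-values, q-values, branch-site mixture
reference distribution, and gene summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psgscan import selection_inference as si
from psgscan.io_formats import CodonAlignment
from psgscan._phylo import IndexedTree
from psgscan.synthetic_data import SimulationConfig, simulate_codon_alignment


def aln_of(columns: list[str], taxa=None) -> CodonAlignment:
    """Build an alignment from per-taxon codon lists given per column."""
    n_taxa = len(columns[0])
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    seqs = ["".join(col[i] for col in columns) for i in range(n_taxa)]
    return CodonAlignment("g", taxa, seqs)


class TestQC:
    def test_ambiguity_columns_removed_then_gate_applied(self):
        # 120 codons, 25 contain an ambiguity in one taxon -> 95 -> fail
        cols = [["ATG", "ATG"] for _ in range(120)]
        for i in range(25):
            cols[i] = ["ATR", "ATG"]
        cleaned, qc = si.qc_alignment(aln_of(cols))
        assert cleaned is None
        assert qc.n_codons_after_ambiguity_removal == 95
        assert "fewer_than_min_codons" in qc.reasons

    def test_clean_alignment_unchanged(self):
        cols = [["ATG", "ATA"] for _ in range(110)]
        cleaned, qc = si.qc_alignment(aln_of(cols))
        assert qc.passed and cleaned.n_codons == 110
        assert qc.kept_codon_indices.tolist() == list(range(110))

    def test_missing_and_gap_columns_removed(self):
        cols = [["ATG", "ATA"] for _ in range(105)]
        cols[3] = ["ATG", "NNN"]
        cols[7] = ["---", "ATA"]
        cleaned, qc = si.qc_alignment(aln_of(cols))
        assert cleaned.n_codons == 103
        assert 3 not in qc.kept_codon_indices
        assert 7 not in qc.kept_codon_indices

    def test_terminal_stop_triggers_trim_and_passes(self):
        cols = [["ATG", "ATA"] for _ in range(115)]
        cols[-1] = ["TAA", "TAA"]
        cleaned, qc = si.qc_alignment(aln_of(cols))
        assert qc.stop_trim_applied
        assert qc.passed and cleaned.n_codons == 105

    def test_persistent_internal_stop_fails(self):
        cols = [["ATG", "ATA"] for _ in range(120)]
        cols[5] = ["TGA", "TGA"]
        cleaned, qc = si.qc_alignment(aln_of(cols))
        assert cleaned is None and "stop_codon" in qc.reasons

    def test_removing_codons_only_fails_more_genes(self):
        cols = [["ATG", "ATA"] for _ in range(101)]
        ok, _ = si.qc_alignment(aln_of(cols))
        assert ok is not None
        cols[0] = ["ATR", "ATA"]
        cols[1] = ["NNN", "ATA"]
        worse, qc = si.qc_alignment(aln_of(cols))
        assert worse is None


class TestEmpiricalPvalues:
    def test_add_one_rule(self):
        null = np.arange(99, dtype=float)
        assert si.empirical_pvalue(1000.0, null) == pytest.approx(0.01)
        assert si.empirical_pvalue(-1.0, null) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_lrt(self):
        rng = np.random.default_rng(0)
        null = rng.chisquare(1, size=500)
        lrts = np.sort(rng.uniform(0, 10, size=50))
        p = si.empirical_pvalue(lrts, null)
        assert (np.diff(p) <= 1e-12).all()

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            si.empirical_pvalue(1.0, np.array([]))


class TestQValues:
    def test_all_ones_give_all_ones_no_flags(self):
        q, flags, _ = si.compute_qvalues(np.ones(50))
        assert (q == 1.0).all() and not flags.any()

    def test_monotone_in_p_and_bounded_below(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, size=300)
        q, _, pi0 = si.compute_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p * pi0 - 1e-12).all()

    def test_bh_equals_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(0.0001, 1, size=97)
        q, _, _ = si.compute_qvalues(p, method="bh")
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)

    def test_planted_mixture_controls_fdr(self):
        """80% uniform nulls + 20% near-zero signals at n=2000: the
        empirical FDR among flags stays near the nominal level."""
        rng = np.random.default_rng(3)
        n = 2000
        is_null = rng.random(n) < 0.8
        p = np.where(is_null, rng.uniform(0.0005, 1, size=n),
                     rng.uniform(0.0005, 0.002, size=n))
        q, flags, _ = si.compute_qvalues(p, alpha=0.05)
        assert flags.sum() > 0
        fdr = is_null[flags].mean()
        assert fdr <= 1.5 * 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            si.compute_qvalues([])


class TestBranchSiteMixture:
    def test_reference_value_at_2_706(self):
        assert si.mixture_pvalue(2.706) == pytest.approx(0.05, abs=1e-4)

    def test_zero_lrt_gives_p_one(self):
        assert si.mixture_pvalue(0.0) == 1.0

    def test_halved_chi1_tail(self):
        for lrt in (0.5, 1.7, 4.2, 9.3):
            assert si.mixture_pvalue(lrt) == pytest.approx(
                0.5 * stats.chi2.sf(lrt, 1))


class TestSummaries:
    def test_enc_lower_bound_single_codon_per_aa(self):
        # one codon per amino acid, each appearing several times
        from psgscan import genetic_code as gc
        chosen = {}
        for codon, aa in zip(gc.SENSE_CODONS, gc.CODON_AA):
            chosen.setdefault(aa, codon)
        seq = "".join(c * 5 for c in chosen.values())
        assert si.effective_number_of_codons(seq) == pytest.approx(20.0)

    def test_enc_uniform_usage_near_61(self):
        from psgscan import genetic_code as gc
        seq = "".join(c * 10 for c in gc.SENSE_CODONS)
        enc = si.effective_number_of_codons(seq)
        assert enc == pytest.approx(61.0, abs=2.0)

    def test_intronless_contrast_matches_exact_test(self):
        """Reconstructed intronless counts (92/1008 PSG vs 450/5512
        non-PSG) give the Fisher P ~ 0.32 of a no-difference contrast."""
        rows = []
        for i in range(1008):
            rows.append(dict(gene_id=f"p{i}", psg_flag=True, LRT=10.0,
                             dN=0.08, dS=0.33, dN_dS=0.25,
                             n_codons=500, intronless=i < 92))
        for i in range(5512):
            rows.append(dict(gene_id=f"n{i}", psg_flag=False, LRT=1.0,
                             dN=0.05, dS=0.34, dN_dS=0.15,
                             n_codons=342, intronless=i < 450))
        df = pd.DataFrame(rows)
        summary, tests = si.summarize_genes(df, binary_traits=["intronless"])
        p = tests.loc[tests.trait == "intronless", "p"].iloc[0]
        assert p == pytest.approx(0.321, abs=0.002)
        total = summary.loc[summary.group == "TOTAL"].iloc[0]
        assert total.n_genes == 6520

    def test_identical_groups_give_p_one(self):
        rows = [dict(gene_id=f"g{i}", psg_flag=i < 5, LRT=2.0, dN=0.1,
                     dS=0.2, dN_dS=0.5, n_codons=200) for i in range(10)]
        _, tests = si.summarize_genes(pd.DataFrame(rows))
        assert (tests.p == 1.0).all()

    def test_ratio_of_means_reported(self):
        rows = [dict(gene_id=f"g{i}", psg_flag=False, LRT=0.0,
                     dN=0.1 * (i + 1), dS=0.2, dN_dS=0.5 * (i + 1),
                     n_codons=150) for i in range(4)]
        summary, _ = si.summarize_genes(pd.DataFrame(rows))
        total = summary.loc[summary.group == "TOTAL"].iloc[0]
        assert total.dN_dS_ratio_of_means == pytest.approx(
            (0.25) / 0.2)


class TestCalibration:
    def test_seed_reproducibility_and_pooling(self):
        config = SimulationConfig(seed=2, model="M7", n_codons=120,
                                  n_taxa=5, tree_length=2.0)
        aln, _, tree = simulate_codon_alignment(config)
        gf = si.sites_test(aln, tree, n_starts=1, seed=0)
        null1 = si.calibrate_empirical_null([gf], n_sample=1, n_reps=2,
                                            seed=5)
        null2 = si.calibrate_empirical_null([gf], n_sample=1, n_reps=2,
                                            seed=5)
        assert len(null1) == 2
        assert np.array_equal(null1, null2)
        assert (null1 >= 0).all()
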