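"""Generator properties: determinism, selection regimes, stationarity,
pileup composition, paralog mixtures, gene universes."""

import numpy as np
import pytest
from scipy import stats

from psgscan import genetic_code as gc
from psgscan.codon_models import codon_index_matrix
from psgscan.synthetic_data import (SimulationConfig, random_gene_model,
                                    selected_class_mask,
                                    simulate_codon_alignment,
                                    simulate_gene_universe, simulate_pileups)


class TestAlignmentSimulation:
    def test_seed_determinism(self):
        config = SimulationConfig(seed=42, model="M7", n_codons=50)
        a1, c1, t1 = simulate_codon_alignment(config)
        a2, c2, t2 = simulate_codon_alignment(config)
        assert a1.sequences == a2.sequences
        assert (c1 == c2).all()
        assert t1.to_newick() == t2.to_newick()

    def test_omega_zero_evolves_only_synonymously(self):
        config = SimulationConfig(seed=3, model="M0", omega=0.0,
                                  n_codons=200, tree_length=4.0)
        aln, _, _ = simulate_codon_alignment(config)
        ref_aa = [gc.CODON_AA[i] for i in codon_index_matrix(aln)[0]]
        for t in range(1, aln.n_taxa):
            aa = [gc.CODON_AA[i] for i in codon_index_matrix(aln)[t]]
            assert aa == ref_aa

    def test_zero_tree_length_gives_identical_taxa(self):
        config = SimulationConfig(seed=4, model="M0", tree_length=0.0,
                                  n_codons=80)
        aln, _, _ = simulate_codon_alignment(config)
        assert len(set(aln.sequences)) == 1

    def test_m8_selected_class_fraction(self):
        config = SimulationConfig(seed=5, model="M8", p0=0.8, omega_s=3.0,
                                  n_codons=500)
        _, site_class, _ = simulate_codon_alignment(config)
        frac = selected_class_mask(config, site_class).mean()
        # binomial(500, 0.2): 3 sigma band
        se = np.sqrt(0.2 * 0.8 / 500)
        assert abs(frac - 0.2) < 3 * se

    def test_long_m0_run_converges_to_stationary_pi(self):
        """Codon spectrum of the root draw matches pi (chi-square GOF)."""
        config = SimulationConfig(seed=6, model="M0", omega=0.5,
                                  n_codons=10_000, tree_length=1.0)
        aln, _, _ = simulate_codon_alignment(config)
        # a single tip: its marginal is the stationary distribution and
        # its sites are independent (tips are correlated via the tree)
        counts = np.bincount(codon_index_matrix(aln)[0], minlength=61)
        expected = np.full(61, counts.sum() / 61)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=60) > 1e-4

    def test_transition_fraction_increases_with_kappa(self):
        def ts_fraction(kappa):
            config = SimulationConfig(seed=8, model="M0", omega=1.0,
                                      kappa=kappa, n_codons=2000,
                                      tree="(A:0.4,B:0.4);")
            aln, _, _ = simulate_codon_alignment(config)
            m = codon_index_matrix(aln)
            nt = gc.CODON_NT[m]  # (2, n, 3)
            a, b = nt[0].ravel(), nt[1].ravel()
            diff = a != b
            ts = ((a + b) % 4 == 2) & diff
            return ts.sum() / diff.sum()

        fracs = [ts_fraction(k) for k in (0.5, 2.0, 8.0)]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(model="M8", omega_s=0.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_codons=0).validate()


class TestPileups:
    def run(self, **kw):
        defaults = dict(seed=1, model="M0", omega=0.3, n_codons=100,
                        heterozygosity=0.0, error_rate=0.0,
                        coverage_mean=100, coverage_sd=10,
                        duplicate_rate=0.0, proper_pair_rate=1.0,
                        mapq_values=(60,), mapq_probs=(1.0,))
        defaults.update(kw)
        config = SimulationConfig(**defaults)
        aln, _, tree = simulate_codon_alignment(config)
        rng = np.random.default_rng(2)
        gene = random_gene_model("g", config.n_codons, rng, strand="+")
        piles, genotypes = simulate_pileups(config, aln, gene,
                                            species=["sp2"], rng=rng)
        return config, piles["sp2"], genotypes["sp2"]

    def test_no_het_no_error_single_base_columns(self):
        _, pile, _ = self.run()
        for site in range(20):
            col = pile.column(site)
            assert len(np.unique(col.bases)) == 1

    def test_het_sites_near_half_frequency(self):
        _, pile, geno = self.run(heterozygosity=1.0)
        het_sites = np.flatnonzero(geno[:, 0] != geno[:, 1])
        assert len(het_sites) > 50
        freqs = []
        for site in het_sites:
            col = pile.column(int(site))
            counts = np.bincount(col.bases, minlength=4)
            freqs.append(counts[geno[site, 1]] / counts.sum())
        # binomial(cov~100, 0.5) mixture: mean ~0.5, most in (0.35, 0.65)
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.03)
        assert np.mean([(0.375 <= f < 0.625) for f in freqs]) > 0.7

    def test_paralog_mixture_skews_allele_frequencies(self):
        """f=0.5 contamination from a diverged copy: variant alleles
        appear near frequency 0.5 * 0.5 = 0.25 (or 0.75), and 3-4 base
        columns arise."""
        config, pile, geno = self.run(paralog_fraction=0.5,
                                      paralog_divergence=0.2,
                                      heterozygosity=0.3)
        n_multi = 0
        outer = mid = 0
        for site in range(len(pile.positions)):
            col = pile.column(int(site))
            counts = np.bincount(col.bases, minlength=4)
            cov = counts.sum()
            passing = (counts * 8 >= cov) & (counts > 0)
            if passing.sum() > 2:
                n_multi += 1
            if passing.sum() == 2:
                f = counts[passing].min() / cov
                if 0.125 <= f < 0.375:
                    outer += 1
                elif 0.375 <= f < 0.625:
                    mid += 1
        assert n_multi > 0
        assert outer > mid  # mixture mass concentrates at 0.25/0.75

    def test_paralog_contamination_inflates_coverage(self):
        _, clean, _ = self.run()
        _, contam, _ = self.run(paralog_fraction=0.5,
                                paralog_divergence=0.1)
        cov_clean = len(clean.read_site) / len(clean.positions)
        cov_contam = len(contam.read_site) / len(contam.positions)
        assert cov_contam > 1.6 * cov_clean


class TestGeneUniverse:
    def test_unenriched_universe_fold_near_one(self):
        genes, mem, truth = simulate_gene_universe(
            6000, 10, psg_rate=1008 / 6520, seed=1)
        psg = set(genes.loc[genes.is_psg, "gene_id"])
        K, N = len(psg), len(genes)
        folds = []
        for cat, sub in mem.groupby("category_id"):
            n = len(sub)
            k = len(set(sub.gene_id) & psg)
            folds.append(k / (n * K / N))
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)

    def test_planted_enrichment_recovered(self):
        genes, mem, _ = simulate_gene_universe(
            4000, 5, psg_rate=0.05, seed=2,
            enrichment_spec={"cat002": 4.0},
            category_sizes=[100, 100, 400, 100, 100])
        psg = set(genes.loc[genes.is_psg, "gene_id"])
        K, N = len(psg), len(genes)
        sub = mem[mem.category_id == "cat002"]
        k = len(set(sub.gene_id) & psg)
        fold = k / (len(sub) * K / N)
        assert 2.5 < fold < 5.5

    def test_zero_categories_empty_membership(self):
        genes, mem, _ = simulate_gene_universe(100, 0, 0.1, seed=3)
        assert len(mem) == 0 and len(genes) == 100

    def test_unknown_enriched_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_gene_universe(100, 2, 0.1,
                                   enrichment_spec={"cat009": 2.0})
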