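"""Codon substitution machinery: rate matrices, pruning likelihoods,
model fits and site posteriors."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from psgscan import genetic_code as gc
from psgscan import codon_models as cm
from psgscan._phylo import IndexedTree
from psgscan.io_formats import CodonAlignment
from psgscan.synthetic_data import SimulationConfig, simulate_codon_alignment

from conftest import toy_alignment


@pytest.fixture(scope="module")
def uniform_pi():
    return np.full(gc.N_STATES, 1.0 / gc.N_STATES)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_rate(self, uniform_pi):
        Q = cm.rate_matrix(2.0, 0.5, uniform_pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -(uniform_pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(gc.N_STATES))
        Q = cm.rate_matrix(3.1, 0.7, pi)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_pi):
        Q = cm.rate_matrix(2.0, 0.0, uniform_pi, scale=1.0)
        nonsyn = gc.SINGLE_STEP & ~gc.SYNONYMOUS
        assert np.abs(Q[nonsyn]).max() == 0.0

    def test_symmetric_rates_under_neutral_uniform(self, uniform_pi):
        """omega=1, kappa=1, uniform pi: every single-step rate equal."""
        Q = cm.rate_matrix(1.0, 1.0, uniform_pi)
        vals = Q[gc.SINGLE_STEP]
        assert np.allclose(vals, vals[0])
        assert np.abs(Q[~gc.SINGLE_STEP & ~np.eye(61, dtype=bool)]).max() == 0

    def test_transition_matrix_semigroup(self, uniform_pi):
        """exp(Qt) rows sum to 1 and P(t1+t2) = P(t1) P(t2)."""
        tree = IndexedTree.from_newick("(A:0.3,B:0.5);")
        P = cm.transition_matrices(tree, np.array([0.4]), 2.0, uniform_pi,
                                   1.0)
        Pa, Pb = P[0, 0], P[0, 1]
        assert np.abs(Pa.sum(1) - 1).max() < 1e-10
        tree2 = IndexedTree.from_newick("(A:0.8,B:0.1);")
        Pab = cm.transition_matrices(tree2, np.array([0.4]), 2.0,
                                     uniform_pi, 1.0)[0, 0]
        assert np.abs(Pa @ Pb - Pab).max() < 1e-10


class TestF3X4:
    def test_uniform_usage_gives_uniform_pi(self):
        # all four bases equally often at each position
        seq = "".join(a + b + c for a in "ACGT" for b in "ACGT"
                      for c in "ACGT")
        aln = CodonAlignment("g", ["A"], [seq])
        pi = cm.f3x4_frequencies(aln)
        assert np.allclose(pi, 1.0 / gc.N_STATES, atol=1e-6)

    def test_matches_hand_computed_products(self):
        # 2 taxa x 5 codons, counted by hand
        aln = toy_alignment({"A": "ATGATGAAACCCGGG", "B": "ATGATGAAACCAGGG"})
        pi = cm.f3x4_frequencies(aln)
        # position 1 counts over 10 codons: A x 6, C x 2, G x 2
        f1 = {"A": 0.6, "C": 0.2, "G": 0.2, "T": 0.0}
        f2 = {"T": 0.4, "A": 0.2, "C": 0.2, "G": 0.2}
        f3 = {"G": 0.6, "A": 0.3, "C": 0.1, "T": 0.0}
        raw = np.array([f1[c[0]] * f2[c[1]] * f3[c[2]]
                        for c in gc.SENSE_CODONS])
        raw /= raw.sum()
        raw = np.maximum(raw, cm.PI_FLOOR)
        raw /= raw.sum()
        assert np.allclose(pi, raw, atol=1e-12)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            cm.f3x4_frequencies(toy_alignment({"A": "NNN"}))


def brute_force_loglik(aln, tree_newick, params):
    """Independent oracle: sum over all internal-node states with
    scipy expm, for the rooted 3-taxon topology ((A,B),C)."""
    import re
    m = re.match(r"\(\((\w+):([\d.]+),(\w+):([\d.]+)\):([\d.]+),"
                 r"(\w+):([\d.]+)\);", tree_newick)
    a, ta, b, tb, tab, c, tc = m.groups()
    pi = params.pi
    classes = cm.model_site_classes(params, None)
    scale = cm.mixture_scale(classes, params.kappa, pi)
    total = 0.0
    for s in range(aln.n_codons):
        site = 0.0
        states = {t: gc.CODON_INDEX[aln.sequence_of(t)[3 * s:3 * s + 3]]
                  for t in (a, b, c)}
        for cl in classes:
            Q = cm.rate_matrix(params.kappa, cl.omega, pi, scale=scale)
            Pa, Pb = expm(Q * float(ta)), expm(Q * float(tb))
            Pab, Pc = expm(Q * float(tab)), expm(Q * float(tc))
            lik = 0.0
            for root in range(gc.N_STATES):
                for mid in range(gc.N_STATES):
                    lik += (pi[root] * Pab[root, mid]
                            * Pa[mid, states[a]] * Pb[mid, states[b]]
                            * Pc[root, states[c]])
            site += cl.weight * lik
        total += np.log(site)
    return total


class TestLikelihood:
    NEWICK = "((A:0.2,B:0.35):0.15,C:0.4);"

    @pytest.mark.parametrize("model,kw", [
        ("M0", dict(omega=0.4)),
        ("M0", dict(omega=2.5)),
        ("M7", dict(beta_p=0.6, beta_q=1.4, n_classes=4)),
    ])
    def test_pruning_matches_brute_force_enumeration(self, model, kw):
        aln = toy_alignment({"A": "ATGAAA", "B": "ATAAAG", "C": "CTGAAA"})
        pi = cm.f3x4_frequencies(aln)
        params = cm.CodonModelParams(model=model, kappa=1.8, pi=pi, **kw)
        tree = IndexedTree.from_newick(self.NEWICK)
        got = cm.log_likelihood(aln, tree, params)
        want = brute_force_loglik(aln, self.NEWICK, params)
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_taxon_likelihood_is_stationary(self):
        aln = toy_alignment({"A": "ATGAAA"})
        pi = cm.f3x4_frequencies(aln)
        params = cm.CodonModelParams(model="M0", kappa=2.0, omega=0.5, pi=pi)
        tree = IndexedTree.from_newick("A;")
        got = cm.log_likelihood(aln, tree, params)
        want = sum(np.log(pi[gc.CODON_INDEX[aln.sequences[0][i:i + 3]]])
                   for i in (0, 3))
        assert got == pytest.approx(want, abs=1e-10)

    def test_duplicated_columns_double_lnl(self, three_taxon_tree):
        aln = toy_alignment({"A": "ATGAAA", "B": "ATAAAG", "C": "CTGAAA"})
        dup = toy_alignment({t: s + s for t, s in zip(aln.taxa,
                                                      aln.sequences)})
        pi = cm.f3x4_frequencies(aln)
        params = cm.CodonModelParams(model="M0", kappa=2.0, omega=0.5, pi=pi)
        l1 = cm.log_likelihood(aln, three_taxon_tree, params)
        l2 = cm.log_likelihood(dup, three_taxon_tree, params)
        assert l2 == pytest.approx(2 * l1, abs=1e-8)

    def test_taxon_order_invariance(self, three_taxon_tree):
        seqs = {"A": "ATGAAA", "B": "ATAAAG", "C": "CTGAAA"}
        aln1 = toy_alignment(seqs)
        aln2 = CodonAlignment("toy", ["C", "A", "B"],
                              [seqs["C"], seqs["A"], seqs["B"]])
        params = cm.CodonModelParams(model="M0", kappa=2.0, omega=0.5,
                                     pi=cm.f3x4_frequencies(aln1))
        l1 = cm.log_likelihood(aln1, three_taxon_tree, params)
        l2 = cm.log_likelihood(aln2, three_taxon_tree, params)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_rerooting_invariance(self):
        """A reversible model's likelihood does not depend on root
        placement on the unrooted tree."""
        seqs = {"A": "ATGAAACCC", "B": "ATAAAGCCA", "C": "CTGAAACCC"}
        aln = toy_alignment(seqs)
        params = cm.CodonModelParams(model="M0", kappa=2.0, omega=0.5,
                                     pi=cm.f3x4_frequencies(aln))
        t1 = IndexedTree.from_newick("((A:0.2,B:0.35):0.15,C:0.4);")
        t2 = IndexedTree.from_newick("((A:0.2,C:0.55):0.0,B:0.35);")
        l1 = cm.log_likelihood(aln, t1, params)
        l2 = cm.log_likelihood(aln, t2, params)
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestBetaClasses:
    def test_bin_means_average_to_distribution_mean(self):
        om = cm.beta_class_omegas(0.7, 1.9, 10)
        assert om.mean() == pytest.approx(0.7 / 2.6, abs=1e-9)
        assert (np.diff(om) > 0).all()
        assert ((om > 0) & (om < 1)).all()


class TestFitting:
    def test_m0_parameter_recovery(self):
        config = SimulationConfig(seed=1, model="M0", omega=0.2, kappa=2.5,
                                  n_codons=500, tree_length=3.0)
        aln, _, tree = simulate_codon_alignment(config)
        fit = cm.fit_model(aln, tree, "M0", n_starts=1)
        assert fit.converged
        assert fit.params.omega == pytest.approx(0.2, abs=0.05)
        assert fit.params.kappa == pytest.approx(2.5, abs=0.5)
        assert fit.dN_dS == pytest.approx(fit.params.omega, rel=1e-6)

    def test_m8_contains_m7(self, m8_sites_fit):
        """M7 is M8 at p0=1, so lnL(M8) >= lnL(M7) up to optimizer
        noise; and the true selected-class proportion is recovered."""
        gf = m8_sites_fit
        assert gf.fit_m8.lnL >= gf.fit_m7.lnL - 1e-6
        assert gf.LRT >= 0.0
        assert 1 - gf.fit_m8.params.p0 == pytest.approx(0.1, abs=0.06)

    def test_site_posterior_rows_normalised(self, m8_sites_fit):
        post = m8_sites_fit.fit_m8.site_posteriors
        assert np.abs(post.sum(axis=1) - 1).max() < 1e-8

    def test_posteriors_separate_selected_sites(self, nine_taxon_m8,
                                                m8_sites_fit):
        config, _, site_class, _ = nine_taxon_m8
        beb = cm.site_posteriors(m8_sites_fit.fit_m8, "BEB")
        neb = cm.site_posteriors(m8_sites_fit.fit_m8, "NEB")
        sel = site_class == config.n_classes
        assert beb[sel].mean() > beb[~sel].mean() + 0.3
        assert neb[sel].mean() > neb[~sel].mean() + 0.3
        # strongly informative data: the two empirical-Bayes variants
        # agree closely on average
        assert np.abs(neb - beb).mean() < 0.05

    def test_posteriors_rejected_for_models_without_selected_class(self):
        aln = toy_alignment({"A": "ATGAAA", "B": "ATAAAG", "C": "CTGAAA"})
        tree = IndexedTree.from_newick("((A:0.2,B:0.35):0.15,C:0.4);")
        fit = cm.fit_model(aln, tree, "M0", n_starts=1)
        with pytest.raises(ValueError):
            cm.site_posteriors(fit, "BEB")
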