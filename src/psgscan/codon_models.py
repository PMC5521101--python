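"""Goldman-Yang codon substitution models and maximum-likelihood fitting.

Implements the machinery behind the site-model tests for positive
selection: F3X4 equilibrium codon frequencies, the GY94 rate matrix, a
vectorised Felsenstein pruning likelihood over the 61 sense codons,
bounded quasi-Newton fitting of the site models M0, M7 (beta) and M8
(beta + selected class) and of branch-site model A with its null, and
NEB/BEB posterior probabilities that a codon belongs to the positively
selected class.

Conventions
-----------
* Branch lengths are in expected substitutions per codon; rate matrices
  are rescaled so the mixture-averaged substitution rate is 1.
* The beta distribution of M7/M8 is discretised into ``n_classes``
  (default 10) equal-probability bins, each represented by its mean.
* Branch lengths are taken from the input tree and held fixed during
  fitting by default (``optimize_branch_lengths=True`` co-estimates a
  single tree-scale factor).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import betainc, logsumexp
from scipy.stats import beta as beta_dist

from . import genetic_code as gc
from ._phylo import IndexedTree

logger = logging.getLogger(__name__)

MODELS = ("M0", "M7", "M8", "bsA", "bsA_null")

_TS_SYN = gc.SINGLE_STEP & gc.TRANSITION & gc.SYNONYMOUS
_TV_SYN = gc.SINGLE_STEP & ~gc.TRANSITION & gc.SYNONYMOUS
_TS_NS = gc.SINGLE_STEP & gc.TRANSITION & ~gc.SYNONYMOUS
_TV_NS = gc.SINGLE_STEP & ~gc.TRANSITION & ~gc.SYNONYMOUS

PI_FLOOR = 1e-6  # floor for F3X4 zero-frequency codons
LRT_CLAMP = 1e-6  # negative LRTs larger than this in magnitude are optimizer failures

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 50.0)
SHAPE_BOUNDS = (0.005, 99.0)
PROP_EPS = 1e-6


# ---------------------------------------------------------------------------
# Parameters and fits

@dataclass
class CodonModelParams:
    """Parameters of one codon substitution model.

    Which fields are meaningful depends on ``model``:
    M0 uses ``omega``; M7 uses ``beta_p, beta_q``; M8 adds ``p0`` (beta
    weight) and ``omega_s >= 1``; bsA/bsA_null use ``p0, p1`` (site-class
    proportions), ``omega0``, ``omega2`` and ``foreground`` (a terminal
    taxon name).
    """

    model: str
    kappa: float = 1.6
    omega: float = 0.4
    beta_p: float = 1.0
    beta_q: float = 1.0
    p0: float = 0.9
    omega_s: float = 2.0
    p1: float = 0.05
    omega0: float = 0.2
    omega2: float = 2.0
    foreground: Optional[str] = None
    pi: Optional[np.ndarray] = None
    n_classes: int = 10

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.pi is not None:
            pi = np.asarray(self.pi)
            if pi.shape != (gc.N_STATES,):
                raise ValueError("pi must be a 61-vector")
            if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
                raise ValueError("pi must be a probability vector")
        if self.model == "M8" and self.omega_s < 1:
            raise ValueError("M8 selected-class omega must be >= 1")
        if self.model in ("bsA", "bsA_null"):
            if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1
                    and self.p0 + self.p1 <= 1 + 1e-12):
                raise ValueError("branch-site proportions invalid")


@dataclass
class CodonModelFit:
    params: CodonModelParams
    lnL: float
    converged: bool
    n_codons: int
    #: per-codon posterior over site classes (n_codons x n_classes), NEB at MLE
    site_posteriors: Optional[np.ndarray] = None
    dN: float = np.nan
    dS: float = np.nan
    dN_dS: float = np.nan
    tree: Optional[IndexedTree] = None
    alignment_taxa: Optional[list] = None
    _engine: object = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# Frequencies and rate matrices

def f3x4_frequencies(alignment) -> np.ndarray:
    """F3X4 equilibrium codon frequencies from position-specific
    nucleotide frequencies pooled across all taxa.

    Non-ACGT symbols are ignored in the counts.  Zero-frequency sense
    codons receive a floor of ``PI_FLOOR`` before renormalisation so the
    likelihood stays finite on small alignments.
    """
    counts = np.zeros((3, 4))
    n_any = 0
    for seq in alignment.sequences:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for p in range(3):
            col = arr[p::3]
            for b, nt in enumerate(gc.NUCLEOTIDES):
                counts[p, b] += int((col == ord(nt)).sum())
        n_any += len(seq)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = (freqs[0, gc.CODON_NT[:, 0]]
          * freqs[1, gc.CODON_NT[:, 1]]
          * freqs[2, gc.CODON_NT[:, 2]])
    pi = pi / pi.sum()
    pi = np.maximum(pi, PI_FLOOR)
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                scale: Optional[float] = None) -> np.ndarray:
    """GY94 generator Q.

    Off-diagonal rates: 0 for multi-nucleotide changes; pi_j for a
    synonymous transversion; kappa*pi_j for a synonymous transition;
    omega and omega*kappa times pi_j for the nonsynonymous counterparts.
    Rows sum to zero.  ``scale=None`` normalises so the expected rate
    -sum_i pi_i q_ii equals 1; pass an explicit scale to normalise a
    mixture of matrices jointly.
    """
    R = (_TV_SYN + kappa * _TS_SYN + omega * (_TV_NS + kappa * _TS_NS))
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    if scale is None:
        scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("non-positive rate scale")
    return Q / scale


def expected_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time of the unscaled Q."""
    Q = rate_matrix(kappa, omega, pi, scale=1.0)
    return -(pi * np.diag(Q)).sum()


def syn_nonsyn_flows(kappa: float, omega: float, pi: np.ndarray
                     ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution flow of the unscaled Q."""
    syn = ((_TV_SYN + kappa * _TS_SYN) * pi[None, :] * pi[:, None]).sum()
    nonsyn = (omega * (_TV_NS + kappa * _TS_NS) * pi[None, :] * pi[:, None]).sum()
    return float(syn), float(nonsyn)


def beta_class_omegas(p: float, q: float, n_classes: int = 10) -> np.ndarray:
    """Means of ``n_classes`` equal-probability bins of Beta(p, q)."""
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, n_classes + 1), p, q)
    cdf1 = betainc(p + 1.0, q, np.clip(edges, 0.0, 1.0))
    means = (p / (p + q)) * (cdf1[1:] - cdf1[:-1]) * n_classes
    return np.clip(means, 1e-8, 1.0)


# ---------------------------------------------------------------------------
# Site classes

@dataclass(frozen=True)
class SiteClass:
    """One mixture component: a weight and either a single omega for all
    branches or a (background, foreground) pair with a foreground edge."""
    weight: float
    omega: float
    fg_omega: Optional[float] = None
    fg_edge: int = -1


def model_site_classes(params: CodonModelParams,
                       tree: Optional[IndexedTree] = None) -> list[SiteClass]:
    m = params.model
    K = params.n_classes
    if m == "M0":
        return [SiteClass(1.0, params.omega)]
    if m == "M7":
        om = beta_class_omegas(params.beta_p, params.beta_q, K)
        return [SiteClass(1.0 / K, w) for w in om]
    if m == "M8":
        om = beta_class_omegas(params.beta_p, params.beta_q, K)
        cls = [SiteClass(params.p0 / K, w) for w in om]
        cls.append(SiteClass(1.0 - params.p0, params.omega_s))
        return cls
    if m in ("bsA", "bsA_null"):
        if tree is None or params.foreground is None:
            raise ValueError("branch-site models need a tree and foreground taxon")
        fg = tree.tip_index(params.foreground)
        w2 = 1.0 if m == "bsA_null" else params.omega2
        p0, p1 = params.p0, params.p1
        rest = max(1.0 - p0 - p1, 0.0)
        tot = p0 + p1 if p0 + p1 > 0 else 1.0
        p2a = rest * p0 / tot
        p2b = rest * p1 / tot
        return [
            SiteClass(p0, params.omega0),
            SiteClass(p1, 1.0),
            SiteClass(p2a, params.omega0, fg_omega=w2, fg_edge=fg),
            SiteClass(p2b, 1.0, fg_omega=w2, fg_edge=fg),
        ]
    raise ValueError(f"unknown model {m!r}")


def mixture_scale(classes: Sequence[SiteClass], kappa: float,
                  pi: np.ndarray) -> float:
    """Joint normalisation so the weighted expected rate (background
    omegas) is 1 substitution/codon per unit branch length."""
    return float(sum(c.weight * expected_rate(kappa, c.omega, pi)
                     for c in classes))


# ---------------------------------------------------------------------------
# Pruning engine

def codon_index_matrix(alignment) -> np.ndarray:
    """(n_taxa, n_codons) matrix of sense-codon indices.

    Requires a cleaned alignment: every codon in every taxon must be an
    unambiguous sense codon.
    """
    n = alignment.n_codons
    out = np.empty((len(alignment.taxa), n), dtype=np.int64)
    for t, seq in enumerate(alignment.sequences):
        seq = seq.upper()
        for s in range(n):
            codon = seq[3 * s:3 * s + 3]
            idx = gc.CODON_INDEX.get(codon)
            if idx is None:
                raise ValueError(
                    f"taxon {alignment.taxa[t]!r} codon {s}: {codon!r} is not "
                    "an unambiguous sense codon (alignment not cleaned?)")
            out[t, s] = idx
    return out


def _eig_batch(Qs: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a stack of reversible generators via the
    symmetrised form diag(sqrt(pi)) Q diag(1/sqrt(pi))."""
    sq = np.sqrt(pi)
    S = Qs * (sq[None, :, None] / sq[None, None, :])
    S = 0.5 * (S + np.swapaxes(S, 1, 2))
    lam, U = np.linalg.eigh(S)
    A = U / sq[None, :, None]      # D^-1 U
    B = np.swapaxes(U, 1, 2) * sq[None, None, :]  # U^T D
    return lam, A, B


def transition_matrices(tree: IndexedTree, omegas: np.ndarray, kappa: float,
                        pi: np.ndarray, scale: float) -> np.ndarray:
    """(n_omegas, n_nodes, 61, 61) transition matrices exp(Q t_e), where
    entry e is the branch above node e (identity for the root)."""
    Qs = np.stack([rate_matrix(kappa, w, pi, scale=scale) for w in omegas])
    lam, A, B = _eig_batch(Qs, pi)
    t = tree.length  # (n_nodes,)
    E = np.exp(lam[:, None, :] * t[None, :, None])
    P = np.einsum("oik,onk,okj->onij", A, E, B, optimize=True)
    np.clip(P, 0.0, None, out=P)
    return P


class PruningEngine:
    """Felsenstein pruning over 61 codon states, vectorised across site
    classes and compressed site patterns."""

    def __init__(self, tree: IndexedTree, tip_states: np.ndarray):
        if tip_states.shape[0] != tree.n_tips:
            raise ValueError("tip state matrix does not match tree tips")
        if (tree.length[np.arange(tree.n_nodes) != tree.root] < 0).any():
            raise ValueError("tree has negative branch lengths")
        self.tree = tree
        patterns, inverse, counts = np.unique(
            tip_states, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns            # (n_tips, n_pat)
        self.pattern_of_site = inverse
        self.weights = counts.astype(float)
        self.n_sites = tip_states.shape[1]
        self.n_pat = patterns.shape[1]

    # -- likelihood ---------------------------------------------------------

    def class_site_logliks(self, classes: Sequence[SiteClass], kappa: float,
                           pi: np.ndarray, scale: Optional[float] = None
                           ) -> np.ndarray:
        """log L(pattern | class) for every class; shape (C, n_pat)."""
        if scale is None:
            scale = mixture_scale(classes, kappa, pi)
        omegas = []
        for c in classes:
            for w in (c.omega, c.fg_omega):
                if w is not None and not any(abs(w - o) < 1e-15 for o in omegas):
                    omegas.append(w)
        omega_idx = {w: i for i, w in enumerate(omegas)}

        def oi(w):
            return next(i for o, i in omega_idx.items() if abs(o - w) < 1e-15)

        Pall = transition_matrices(self.tree, np.array(omegas), kappa, pi,
                                   scale)
        tree = self.tree
        n_edges_sel = np.arange(tree.n_nodes)
        C = len(classes)
        # per-class per-edge omega index
        eidx = np.empty((C, tree.n_nodes), dtype=np.int64)
        for ci, c in enumerate(classes):
            eidx[ci, :] = oi(c.omega)
            if c.fg_omega is not None:
                eidx[ci, c.fg_edge] = oi(c.fg_omega)
        Pc = Pall[eidx, n_edges_sel[None, :]]  # (C, n_nodes, 61, 61)

        if tree.n_tips == 1:
            # no evolution: the site likelihood is the stationary frequency
            ll = np.log(pi[self.patterns[0]])
            return np.broadcast_to(ll, (C, self.n_pat)).copy()

        logscale = np.zeros((C, self.n_pat))
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            node = int(node)
            if node < tree.n_tips:
                continue
            acc = np.ones((C, self.n_pat, gc.N_STATES))
            for child in tree.children[node]:
                P = Pc[:, child]  # (C, 61, 61)
                if child < tree.n_tips:
                    states = self.patterns[child]
                    contrib = np.swapaxes(P[:, :, states], 1, 2)
                else:
                    contrib = np.matmul(partial.pop(child),
                                        np.swapaxes(P, 1, 2))
                acc *= contrib
            m = acc.max(axis=2)
            m = np.where(m <= 0, 1.0, m)  # zero columns surface at the root
            acc /= m[:, :, None]
            logscale += np.log(m)
            partial[node] = acc
        root_partial = partial[tree.root]
        site = root_partial @ pi
        with np.errstate(divide="ignore"):
            ll = np.log(site) + logscale
        if not np.isfinite(ll).all():
            bad_pat = np.argwhere(~np.isfinite(ll))
            raise FloatingPointError(
                f"zero site likelihood at pattern(s) {bad_pat[:, 1].tolist()}")
        return ll

    def log_likelihood(self, classes: Sequence[SiteClass], kappa: float,
                       pi: np.ndarray, scale: Optional[float] = None) -> float:
        ll = self.class_site_logliks(classes, kappa, pi, scale)
        w = np.log(np.maximum([c.weight for c in classes], 1e-300))
        site_ll = logsumexp(ll + w[:, None], axis=0)
        return float(site_ll @ self.weights)

    def site_class_posteriors(self, classes, kappa, pi,
                              scale=None) -> np.ndarray:
        """NEB posterior over classes for every site; (n_sites, C)."""
        ll = self.class_site_logliks(classes, kappa, pi, scale)
        w = np.log(np.maximum([c.weight for c in classes], 1e-300))
        joint = ll + w[:, None]
        joint -= logsumexp(joint, axis=0, keepdims=True)
        post = np.exp(joint).T  # (n_pat, C)
        return post[self.pattern_of_site]


def log_likelihood(alignment, tree: IndexedTree,
                   params: CodonModelParams) -> float:
    """Mixture log-likelihood of a cleaned codon alignment on a tree."""
    params.validate()
    pi = params.pi if params.pi is not None else f3x4_frequencies(alignment)
    states = codon_index_matrix(alignment)
    order = [alignment.taxa.index(lbl) for lbl in tree.tip_labels]
    engine = PruningEngine(tree, states[order])
    classes = model_site_classes(params, tree)
    return engine.log_likelihood(classes, params.kappa, pi)


# ---------------------------------------------------------------------------
# Fitting

def _pack_bounds(model: str):
    lk = tuple(np.log(KAPPA_BOUNDS))
    lo_ = tuple(np.log(OMEGA_BOUNDS))
    ls = tuple(np.log(SHAPE_BOUNDS))
    lu = (float(np.log(1e-6)), float(np.log(OMEGA_BOUNDS[1] - 1.0)))
    pp = (PROP_EPS, 1.0 - PROP_EPS)
    if model == "M0":
        return [lk, lo_]
    if model == "M7":
        return [lk, ls, ls]
    if model == "M8":
        return [lk, ls, ls, pp, lu]
    if model == "bsA":
        return [lk, (np.log(1e-4), 0.0), pp, pp, lu]
    if model == "bsA_null":
        return [lk, (np.log(1e-4), 0.0), pp, pp]
    raise ValueError(model)


def _params_to_x(p: CodonModelParams) -> np.ndarray:
    m = p.model
    if m == "M0":
        return np.array([np.log(p.kappa), np.log(p.omega)])
    if m == "M7":
        return np.array([np.log(p.kappa), np.log(p.beta_p), np.log(p.beta_q)])
    if m == "M8":
        return np.array([np.log(p.kappa), np.log(p.beta_p), np.log(p.beta_q),
                         p.p0, np.log(max(p.omega_s - 1.0, 1e-6))])
    s = p.p0 + p.p1
    s = min(max(s, PROP_EPS), 1 - PROP_EPS)
    r = p.p0 / s if s > 0 else 0.5
    r = min(max(r, PROP_EPS), 1 - PROP_EPS)
    base = [np.log(p.kappa), np.log(max(p.omega0, 1e-4)), s, r]
    if m == "bsA":
        base.append(np.log(max(p.omega2 - 1.0, 1e-6)))
    return np.array(base)


def _x_to_params(x: np.ndarray, model: str, template: CodonModelParams
                 ) -> CodonModelParams:
    p = dataclasses.replace(template, model=model)
    p.kappa = float(np.exp(x[0]))
    if model == "M0":
        p.omega = float(np.exp(x[1]))
    elif model == "M7":
        p.beta_p, p.beta_q = float(np.exp(x[1])), float(np.exp(x[2]))
    elif model == "M8":
        p.beta_p, p.beta_q = float(np.exp(x[1])), float(np.exp(x[2]))
        p.p0 = float(x[3])
        p.omega_s = 1.0 + float(np.exp(x[4]))
    else:
        p.omega0 = float(np.exp(x[1]))
        s, r = float(x[2]), float(x[3])
        p.p0, p.p1 = s * r, s * (1.0 - r)
        p.omega2 = 1.0 if model == "bsA_null" else 1.0 + float(np.exp(x[4]))
    return p


_DEFAULT_INIT = dict(kappa=1.6, omega=0.4, beta_p=0.5, beta_q=1.2,
                     p0=0.9, omega_s=2.0, p1=0.05, omega0=0.2, omega2=2.0)


def fit_model(alignment, tree: IndexedTree, model: str,
              init: Optional[CodonModelParams] = None,
              n_starts: int = 3, seed: int = 0,
              foreground: Optional[str] = None,
              n_classes: int = 10,
              optimize_branch_lengths: bool = False,
              compute_posteriors: bool = True) -> CodonModelFit:
    """Maximum-likelihood fit of one codon model to a cleaned alignment.

    ``n_starts`` controls multi-start optimisation: the first start is
    ``init`` (or the package defaults, kappa=1.6 / omega=0.4), the rest
    are log-normally jittered.  Branch lengths are fixed at the input
    tree's values unless ``optimize_branch_lengths``, which co-estimates
    a single tree scale factor.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if alignment.n_codons < 1:
        raise ValueError("empty alignment")
    pi = f3x4_frequencies(alignment)
    states = codon_index_matrix(alignment)
    order = [alignment.taxa.index(lbl) for lbl in tree.tip_labels]
    engine = PruningEngine(tree, states[order])

    template = CodonModelParams(model=model, pi=pi, n_classes=n_classes,
                                foreground=foreground, **_DEFAULT_INIT)
    if init is not None:
        template = dataclasses.replace(
            init, model=model, pi=pi, n_classes=n_classes,
            foreground=foreground or init.foreground)
    bounds = _pack_bounds(model)
    x0 = _params_to_x(template)
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    rng = np.random.default_rng(seed)

    scale_x = [0.0] if optimize_branch_lengths else []

    def negloglik(x):
        if optimize_branch_lengths:
            tree_fac = float(np.exp(x[-1]))
            x = x[:-1]
        else:
            tree_fac = 1.0
        p = _x_to_params(x, model, template)
        classes = model_site_classes(p, tree)
        eng = engine
        if tree_fac != 1.0:
            eng = PruningEngine(tree.scaled(tree_fac), engine.patterns)
            eng.weights = engine.weights
            eng.pattern_of_site = engine.pattern_of_site
        try:
            return -eng.log_likelihood(classes, p.kappa, pi)
        except FloatingPointError:
            return 1e10

    full_bounds = bounds + ([( -3.0, 3.0)] if optimize_branch_lengths else [])
    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            xs = np.concatenate([x0, scale_x])
        else:
            jitter = rng.normal(0.0, 0.35, size=len(x0))
            xs = np.concatenate([x0, scale_x])
            for i, b in enumerate(bounds):
                if b == (PROP_EPS, 1.0 - PROP_EPS):
                    xs[i] = float(np.clip(x0[i] + rng.normal(0, 0.1),
                                          *b))
                else:
                    xs[i] = float(np.clip(x0[i] + jitter[i], *b))
        res = optimize.minimize(negloglik, xs, method="L-BFGS-B",
                                bounds=full_bounds,
                                options=dict(ftol=1e-10, maxiter=300,
                                             eps=1e-5))
        if best is None or res.fun < best.fun:
            best = res
    # L-BFGS-B line searches can terminate abnormally right at the
    # optimum when finite-difference gradients turn noisy; accept the
    # result when the projected gradient is small.
    grad_ok = best.jac is not None and np.max(np.abs(best.jac)) < 0.5
    converged = bool(best.success) or best.status == 0 or grad_ok
    xb = best.x[:-1] if optimize_branch_lengths else best.x
    params = _x_to_params(xb, model, template)
    fit_tree = tree
    if optimize_branch_lengths:
        fit_tree = tree.scaled(float(np.exp(best.x[-1])))
        engine = PruningEngine(fit_tree, states[order])
    classes = model_site_classes(params, fit_tree)
    post = None
    if compute_posteriors:
        post = engine.site_class_posteriors(classes, params.kappa, pi)
    dN, dS = _dn_ds(params, classes, fit_tree)
    fit = CodonModelFit(params=params, lnL=-float(best.fun),
                        converged=converged, n_codons=alignment.n_codons,
                        site_posteriors=post, dN=dN, dS=dS,
                        dN_dS=dN / dS if dS > 0 else np.nan,
                        tree=fit_tree, alignment_taxa=list(alignment.taxa))
    fit._engine = engine
    if not converged:
        logger.warning("fit of %s did not converge (status %s)", model,
                       best.status)
    return fit


def _dn_ds(params: CodonModelParams, classes: Sequence[SiteClass],
           tree: IndexedTree) -> tuple[float, float]:
    """Per-gene dN and dS from the fitted mixture (codeml convention:
    syn/nonsyn flows under the model over syn/nonsyn site proportions
    measured at omega=1)."""
    pi = params.pi
    rho = mixture_scale(classes, params.kappa, pi)
    fS = fN = 0.0
    for c in classes:
        s, n = syn_nonsyn_flows(params.kappa, c.omega, pi)
        fS += c.weight * s / rho
        fN += c.weight * n / rho
    s1, n1 = syn_nonsyn_flows(params.kappa, 1.0, pi)
    pS = s1 / (s1 + n1)
    pN = 1.0 - pS
    T = tree.tree_length
    dS = T * fS / (3.0 * pS)
    dN = T * fN / (3.0 * pN)
    return float(dN), float(dS)


# ---------------------------------------------------------------------------
# Site posteriors (NEB / BEB)

def site_posteriors(fit: CodonModelFit, method: str = "BEB") -> np.ndarray:
    """Posterior probability, per codon, of the omega>1 class.

    NEB plugs the MLEs into Bayes' rule; BEB additionally averages over a
    10-point grid prior on the mixture parameters (p0 and omega_s for M8;
    class proportions and omega2 for branch-site model A), with the
    remaining parameters held at their MLEs.
    """
    m = fit.params.model
    if m not in ("M8", "bsA"):
        raise ValueError(f"model {m} has no positively selected class")
    if method not in ("NEB", "BEB"):
        raise ValueError("method must be NEB or BEB")
    if not fit.converged:
        raise ValueError("cannot compute site posteriors from an unconverged fit")
    engine: PruningEngine = fit._engine
    params = fit.params
    pi = params.pi
    if method == "NEB":
        if m == "M8":
            return fit.site_posteriors[:, -1].copy()
        return fit.site_posteriors[:, 2:].sum(axis=1)
    if m == "M8":
        return _beb_m8(engine, params, pi)
    return _beb_bsa(engine, params, pi, fit.tree)


_BEB_GRID = 10


def _grid_mid(lo: float, hi: float, d: int = _BEB_GRID) -> np.ndarray:
    return lo + (hi - lo) * (2 * np.arange(1, d + 1) - 1) / (2.0 * d)


def _beb_average(ll_grid: np.ndarray, sel_part: np.ndarray,
                 weights: np.ndarray) -> np.ndarray:
    """Average P(selected | site, grid point) over the grid posterior.

    ll_grid: (G, n_pat) log site likelihoods per grid point;
    sel_part:  (G, n_pat) log weighted selected-class contribution.
    """
    log_grid_post = ll_grid @ weights
    log_grid_post -= logsumexp(log_grid_post)
    p_sel = np.exp(sel_part - ll_grid)  # (G, n_pat)
    return np.exp(log_grid_post)[:, None] * p_sel


def _beb_m8(engine: PruningEngine, params: CodonModelParams,
            pi: np.ndarray) -> np.ndarray:
    K = params.n_classes
    beta_om = beta_class_omegas(params.beta_p, params.beta_q, K)
    ws_grid = _grid_mid(1.0, 11.0)
    p0_grid = _grid_mid(0.0, 1.0)
    classes = [SiteClass(1.0 / K, w) for w in beta_om] + \
              [SiteClass(0.0, w) for w in ws_grid]
    mle_classes = model_site_classes(params, None)
    scale = mixture_scale(mle_classes, params.kappa, pi)
    ll = engine.class_site_logliks(classes, params.kappa, pi, scale=scale)
    beta_ll = logsumexp(ll[:K] - np.log(K), axis=0)   # (n_pat,)
    sel_ll = ll[K:]                                    # (10, n_pat)
    G = len(p0_grid) * len(ws_grid)
    ll_grid = np.empty((G, engine.n_pat))
    sel_part = np.empty((G, engine.n_pat))
    g = 0
    for p0 in p0_grid:
        for j in range(len(ws_grid)):
            a = np.log(p0) + beta_ll
            b = np.log1p(-p0) + sel_ll[j]
            ll_grid[g] = np.logaddexp(a, b)
            sel_part[g] = b
            g += 1
    contrib = _beb_average(ll_grid, sel_part, engine.weights)
    post = contrib.sum(axis=0)
    return np.clip(post[engine.pattern_of_site], 0.0, 1.0)


def _beb_bsa(engine: PruningEngine, params: CodonModelParams,
             pi: np.ndarray, tree: IndexedTree) -> np.ndarray:
    fg = tree.tip_index(params.foreground)
    w0 = params.omega0
    w2_grid = _grid_mid(1.0, 11.0)
    s_grid = _grid_mid(0.0, 1.0)
    r_grid = _grid_mid(0.0, 1.0)
    classes = [SiteClass(0.0, w0), SiteClass(0.0, 1.0)]
    for w2 in w2_grid:
        classes.append(SiteClass(0.0, w0, fg_omega=w2, fg_edge=fg))
    for w2 in w2_grid:
        classes.append(SiteClass(0.0, 1.0, fg_omega=w2, fg_edge=fg))
    mle_classes = model_site_classes(params, tree)
    scale = mixture_scale(mle_classes, params.kappa, pi)
    ll = engine.class_site_logliks(classes, params.kappa, pi, scale=scale)
    ll0, ll1 = ll[0], ll[1]
    ll2a, ll2b = ll[2:2 + _BEB_GRID], ll[2 + _BEB_GRID:]
    rows = []
    sel_rows = []
    for s in s_grid:
        for r in r_grid:
            p0, p1 = s * r, s * (1 - r)
            p2a, p2b = (1 - s) * r, (1 - s) * (1 - r)
            for j in range(_BEB_GRID):
                parts = np.stack([
                    np.log(max(p0, 1e-300)) + ll0,
                    np.log(max(p1, 1e-300)) + ll1,
                    np.log(max(p2a, 1e-300)) + ll2a[j],
                    np.log(max(p2b, 1e-300)) + ll2b[j],
                ])
                rows.append(logsumexp(parts, axis=0))
                sel_rows.append(logsumexp(parts[2:], axis=0))
    ll_grid = np.stack(rows)
    sel_part = np.stack(sel_rows)
    contrib = _beb_average(ll_grid, sel_part, engine.weights)
    post = contrib.sum(axis=0)
    return np.clip(post[engine.pattern_of_site], 0.0, 1.0)
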