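"""GY94 codon-model likelihoods, site and branch-site fits, LRTs.

Likelihoods are computed by Felsenstein pruning over site patterns with
per-site rescaling, on a fixed tree topology.  The supported models are
the standard site-model ladder — M0 (one ratio), M1a (nearly neutral),
M2a (positive selection), M3 (discrete, 3 classes), M7 (beta), M8
(beta & omega) — and branch-site model A with its omega2 = 1 null, in
which class-2 sites switch to a foreground omega on flagged branches.

Fitting strategy: branch lengths (and the kappa initial value) come from
an M0 fit by quasi-Newton optimization over log-transformed lengths,
kappa and omega; the mixture models are then fitted with branch lengths
fixed, optimizing the omega-side parameters by deterministic multi-start
Nelder-Mead while the class proportions are profiled out exactly by an
inner EM (the weight problem is concave for simplex-free models; the
branch-site 2x2 product weights use the same EM with multiple inner
starts).  Each class rate matrix is scaled to unit expected rate at
stationarity, the same convention the simulator uses, so simulated and
inferred branch lengths are commensurable.

Positive-selection sites are identified by naive empirical Bayes (NEB)
posteriors by default, or by a coarse-grid Bayes empirical Bayes variant
that averages posteriors over a 10-point uniform grid per free mixture
proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betainc, logsumexp

from .alignment import CodonAlignment
from .codata import N_CODONS, codon_indices
from .errors import InputError, OptimizationError
from .gy94 import SpectralQ, empirical_position_freqs, f3x4_frequencies
from .trees import PhyloTree

OMEGA0_BOUNDS = (1e-4, 0.9999)
OMEGA2_BOUNDS = (1.0, 999.0)
OMEGA_FREE_BOUNDS = (1e-4, 999.0)
KAPPA_BOUNDS = (0.05, 99.0)
BETA_BOUNDS = (5e-3, 99.0)
N_BETA_CATEGORIES = 10

SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8")
BRANCH_SITE_MODELS = ("bsA", "bsA_null")


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    p: float


def lrt(lnl_alt: float, lnl_null: float, df: int) -> LRTResult:
    """Likelihood-ratio test: 2*delta-lnL against a chi-square upper tail."""
    if df < 1:
        raise InputError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return LRTResult(stat=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def classify_selection(omega: float) -> str:
    """Strict classification of an omega value against 1."""
    if omega < 0:
        raise InputError("omega must be >= 0")
    if omega < 1.0:
        return "purifying"
    if omega == 1.0:
        return "neutral"
    return "positive"


@dataclass
class ModelFit:
    model: str
    lnL: float
    params: dict
    kappa: float
    pi: np.ndarray
    branch_lengths: dict
    proportions: np.ndarray
    class_omegas: tuple          # (background, foreground) omega per class
    site_posteriors: np.ndarray | None = None   # classes x sites
    positively_selected_sites: list = field(default_factory=list)
    converged: bool = True
    # private state for empirical-Bayes reanalysis
    _class_loglik: np.ndarray | None = None     # classes x patterns
    _pattern_counts: np.ndarray | None = None
    _site_to_pattern: np.ndarray | None = None

    @property
    def positive_classes(self) -> list[int]:
        return [c for c, (bg, fg) in enumerate(self.class_omegas) if max(bg, fg) > 1.0]


# --------------------------------------------------------------------
# likelihood engine
# --------------------------------------------------------------------


class LikelihoodEngine:
    """Pattern-compressed pruning likelihoods for one alignment on one tree.

    Foreground flags are read from the tree's nodes at evaluation time,
    so re-labeling the foreground clade between calls is allowed.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, pi: np.ndarray | None = None):
        if set(tree.leaf_names) != set(aln.ids):
            raise InputError("tree leaves do not match alignment rows")
        self.tree = tree
        k = 0
        for node in tree.postorder():  # unnamed internal nodes get unique keys
            if node.name is None:
                node.name = f"_n{k}"
                k += 1
        self.leaves = tree.leaves
        row_by_id = {r.id: r for r in aln.rows}
        codes = np.stack(
            [codon_indices(row_by_id[l.name].cds) for l in self.leaves]
        )
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns            # n_leaves x n_patterns
        self.counts = counts.astype(float)
        self.site_to_pattern = inverse
        self.n_sites = codes.shape[1]
        self.leaf_row = {l.name: i for i, l in enumerate(self.leaves)}
        self.branch_nodes = [n for n in tree.postorder() if n is not tree.root]
        self.pi = (
            np.asarray(pi, float)
            if pi is not None
            else f3x4_frequencies(empirical_position_freqs(codes))
        )
        self._decomps: dict = {}

    # ---- rate-matrix cache ----------------------------------------

    def _decomp(self, kappa: float, omega: float) -> SpectralQ:
        """Unscaled-Q decomposition; rate scaling enters via branch lengths."""
        key = (round(float(kappa), 12), round(float(omega), 12))
        if key not in self._decomps:
            if len(self._decomps) > 512:
                self._decomps.clear()
            self._decomps[key] = SpectralQ(kappa, omega, self.pi, scale=False)
        return self._decomps[key]

    def mean_rate(self, kappa: float, omega: float) -> float:
        return self._decomp(kappa, omega).rate

    # ---- core pruning ----------------------------------------------

    def class_pattern_loglik(
        self,
        kappa: float,
        omega_bg: float,
        omega_fg: float | None,
        lengths: dict,
        scale: float = 1.0,
    ) -> np.ndarray:
        """log-likelihood per site pattern for one omega class.

        ``scale`` multiplies every branch length; passing the reciprocal
        of the mixture-average rate makes branch lengths mean expected
        substitutions per codon site averaged over classes.
        """
        dq_bg = self._decomp(kappa, omega_bg)
        dq_fg = dq_bg if omega_fg is None or omega_fg == omega_bg else self._decomp(kappa, omega_fg)
        P = self.patterns.shape[1]
        logscale = np.zeros(P)
        partial: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                continue
            part = np.ones((N_CODONS, P))
            for child in node.children:
                dq = dq_fg if child.foreground else dq_bg
                Pm = dq.transition_matrix(max(lengths[child.name], 0.0) * scale)
                if child.is_leaf:
                    row = self.patterns[self.leaf_row[child.name]]
                    msg = np.ones((N_CODONS, P))
                    valid = row >= 0
                    msg[:, valid] = Pm[:, row[valid]]
                else:
                    msg = Pm @ partial.pop(id(child))
                part *= msg
            mx = part.max(axis=0)
            mx = np.where(mx > 0.0, mx, 1e-300)
            part /= mx
            logscale += np.log(mx)
            partial[id(node)] = part
        if self.tree.root.is_leaf:
            raise InputError("tree root cannot be a leaf")
        L = self.pi @ partial[id(self.tree.root)]
        return np.log(np.maximum(L, 1e-300)) + logscale

    def mixture_lnl(self, weights, class_loglik) -> float:
        lw = np.log(np.maximum(np.asarray(weights, float), 1e-300))
        return float(np.dot(self.counts, logsumexp(class_loglik + lw[:, None], axis=0)))

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array back to per-site order (last axis)."""
        return per_pattern[..., self.site_to_pattern]


def site_log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    *,
    kappa: float,
    classes,
    pi: np.ndarray | None = None,
) -> float:
    """Mixture codon log-likelihood on a tree whose node lengths are used.

    ``classes`` is a sequence of (proportion, omega) or (proportion,
    omega_background, omega_foreground) tuples; proportions must sum to 1.
    """
    classes = [(c[0], c[1], c[2] if len(c) > 2 else c[1]) for c in classes]
    props = np.array([c[0] for c in classes], float)
    if abs(props.sum() - 1.0) > 1e-6 or np.any(props < 0):
        raise InputError("class proportions must be non-negative and sum to 1")
    engine = LikelihoodEngine(aln, tree, pi=pi)
    lengths = {n.name: n.length for n in engine.branch_nodes}
    # branch lengths mean substitutions per codon averaged over classes
    mu_bar = float(sum(p * engine.mean_rate(kappa, bg) for p, bg, _ in classes))
    scale = 1.0 / mu_bar
    logs = np.stack(
        [engine.class_pattern_loglik(kappa, bg, fg, lengths, scale) for _, bg, fg in classes]
    )
    return engine.mixture_lnl(props, logs)


# --------------------------------------------------------------------
# inner EM for mixture proportions
# --------------------------------------------------------------------


def _em_simplex(class_loglik, counts, w0, n_iter=500, tol=1e-12):
    """Exact (concave) weight optimization for a free simplex mixture."""
    shift = class_loglik.max(axis=0)
    L = np.exp(class_loglik - shift)
    w = np.asarray(w0, float)
    w = np.maximum(w, 1e-8)
    w /= w.sum()
    total = counts.sum()
    for _ in range(n_iter):
        num = w[:, None] * L
        tot = num.sum(axis=0)
        resp = num / np.maximum(tot, 1e-300)
        w_new = (resp * counts).sum(axis=1) / total
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    tot = (w[:, None] * L).sum(axis=0)
    lnl = float(np.dot(counts, np.log(np.maximum(tot, 1e-300)) + shift))
    return w, lnl


def _em_product(class_loglik, counts, starts=((0.85, 0.9), (0.5, 0.5), (0.3, 0.95))):
    """Branch-site 2x2 product weights (a, b): w = (ab, (1-a)b, a(1-b), (1-a)(1-b)).

    a = p0/(p0+p1), b = p0+p1.  EM from several starts, best kept.
    """
    shift = class_loglik.max(axis=0)
    L = np.exp(class_loglik - shift)
    total = counts.sum()
    best = None
    for a0, b0 in starts:
        a, b = a0, b0
        for _ in range(500):
            w = np.array([a * b, (1 - a) * b, a * (1 - b), (1 - a) * (1 - b)])
            num = w[:, None] * L
            tot = num.sum(axis=0)
            resp = num / np.maximum(tot, 1e-300)
            mass = (resp * counts).sum(axis=1) / total
            a_new = np.clip(mass[0] + mass[2], 1e-8, 1 - 1e-8)
            b_new = np.clip(mass[0] + mass[1], 1e-8, 1 - 1e-8)
            if abs(a_new - a) < 1e-12 and abs(b_new - b) < 1e-12:
                a, b = a_new, b_new
                break
            a, b = a_new, b_new
        w = np.array([a * b, (1 - a) * b, a * (1 - b), (1 - a) * (1 - b)])
        tot = (w[:, None] * L).sum(axis=0)
        lnl = float(np.dot(counts, np.log(np.maximum(tot, 1e-300)) + shift))
        if best is None or lnl > best[0]:
            best = (lnl, a, b, w)
    lnl, a, b, w = best
    return w, (a, b), lnl


# --------------------------------------------------------------------
# parameter transforms (unbounded <-> bounded)
# --------------------------------------------------------------------


def _to_bounded(x, lo, hi):
    v = lo + (hi - lo) / (1.0 + math.exp(-x))
    # snap to the bound when the optimizer pushes against it, so bound
    # hits are reported exactly at the bound (e.g. omega2 = 999.0)
    span = hi - lo
    if v > hi - 1e-4 * span:
        return hi
    if v < lo + 1e-6 * span:
        return lo
    return v


def _from_bounded(v, lo, hi):
    v = min(max(v, lo + 1e-12), hi - 1e-12)
    z = (v - lo) / (hi - lo)
    return math.log(z / (1.0 - z))


def beta_category_means(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Means of k equal-probability categories of a Beta(p, q) distribution."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    I = betainc(p + 1.0, q, np.clip(edges, 0.0, 1.0))
    means = (I[1:] - I[:-1]) * (p / (p + q)) * k
    return np.clip(means, 1e-6, 1.0 - 1e-6)


# --------------------------------------------------------------------
# M0
# --------------------------------------------------------------------


def fit_m0(
    aln: CodonAlignment,
    tree: PhyloTree,
    *,
    pi: np.ndarray | None = None,
    init_kappa: float = 2.0,
    init_omega: float = 0.2,
    engine: LikelihoodEngine | None = None,
    maxiter: int = 200,
) -> ModelFit:
    """One-ratio GY94 fit: joint branch lengths, kappa and omega."""
    eng = engine or LikelihoodEngine(aln, tree, pi=pi)
    nodes = eng.branch_nodes
    bl0 = np.array([n.length if n.length > 1e-6 else 0.1 for n in nodes])
    nb = len(nodes)
    x0 = np.concatenate([
        np.log(bl0),
        [math.log(init_kappa), math.log(init_omega)],
    ])
    bounds = [(math.log(1e-6), math.log(30.0))] * nb + [
        (math.log(KAPPA_BOUNDS[0]), math.log(KAPPA_BOUNDS[1])),
        (math.log(OMEGA_FREE_BOUNDS[0]), math.log(OMEGA_FREE_BOUNDS[1])),
    ]

    names = [n.name for n in nodes]

    def neg_lnl(x):
        lengths = dict(zip(names, np.exp(x[:nb])))
        kappa, omega = math.exp(x[nb]), math.exp(x[nb + 1])
        scale = 1.0 / eng.mean_rate(kappa, omega)
        logs = eng.class_pattern_loglik(kappa, omega, None, lengths, scale)
        return -float(np.dot(eng.counts, logs))

    res = optimize.minimize(
        neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 20 * maxiter * (nb + 2)},
    )
    lengths = dict(zip(names, np.exp(res.x[:nb])))
    kappa, omega = math.exp(res.x[nb]), math.exp(res.x[nb + 1])
    lnl = -float(res.fun)
    if not np.isfinite(lnl):
        raise OptimizationError("M0 optimization produced a non-finite likelihood")
    fit = ModelFit(
        model="M0",
        lnL=lnl,
        params={"omega": omega, "kappa": kappa, "tree_length": float(np.exp(res.x[:nb]).sum())},
        kappa=kappa,
        pi=eng.pi,
        branch_lengths=lengths,
        proportions=np.array([1.0]),
        class_omegas=((omega, omega),),
        converged=bool(res.success) or res.status == 1,
    )
    fit._pattern_counts = eng.counts
    fit._site_to_pattern = eng.site_to_pattern
    return fit


# --------------------------------------------------------------------
# mixture models
# --------------------------------------------------------------------


def _model_structure(model, theta, fix_kappa):
    """Decode an outer parameter vector into kappa and per-class omegas.

    Returns (kappa_or_None, class omega pairs, weight mode, extras).
    weight mode: 'free' (simplex EM), 'fixed' (equal beta categories),
    'm8' (two-block EM), 'product' (branch-site 2x2).
    """
    i = 0
    if fix_kappa:
        kappa = None
    else:
        kappa = math.exp(theta[0])
        i = 1
    if model == "M1a":
        w0 = _to_bounded(theta[i], *OMEGA0_BOUNDS)
        return kappa, [(w0, w0), (1.0, 1.0)], "free", {"omega0": w0}
    if model == "M2a":
        w0 = _to_bounded(theta[i], *OMEGA0_BOUNDS)
        w2 = _to_bounded(theta[i + 1], *OMEGA2_BOUNDS)
        return kappa, [(w0, w0), (1.0, 1.0), (w2, w2)], "free", {"omega0": w0, "omega2": w2}
    if model == "M3":
        ws = sorted(math.exp(t) for t in theta[i:i + 3])
        return kappa, [(w, w) for w in ws], "free", {f"omega{j}": w for j, w in enumerate(ws)}
    if model == "M7":
        p = min(max(math.exp(theta[i]), BETA_BOUNDS[0]), BETA_BOUNDS[1])
        q = min(max(math.exp(theta[i + 1]), BETA_BOUNDS[0]), BETA_BOUNDS[1])
        cats = beta_category_means(p, q)
        return kappa, [(w, w) for w in cats], "fixed", {"p": p, "q": q}
    if model == "M8":
        p = min(max(math.exp(theta[i]), BETA_BOUNDS[0]), BETA_BOUNDS[1])
        q = min(max(math.exp(theta[i + 1]), BETA_BOUNDS[0]), BETA_BOUNDS[1])
        ws = _to_bounded(theta[i + 2], *OMEGA2_BOUNDS)
        cats = beta_category_means(p, q)
        return kappa, [(w, w) for w in cats] + [(ws, ws)], "m8", {"p": p, "q": q, "omega_s": ws}
    if model == "bsA":
        w0 = _to_bounded(theta[i], *OMEGA0_BOUNDS)
        w2 = _to_bounded(theta[i + 1], *OMEGA2_BOUNDS)
        return (
            kappa,
            [(w0, w0), (1.0, 1.0), (w0, w2), (1.0, w2)],
            "product",
            {"omega0": w0, "omega2": w2},
        )
    if model == "bsA_null":
        w0 = _to_bounded(theta[i], *OMEGA0_BOUNDS)
        return (
            kappa,
            [(w0, w0), (1.0, 1.0), (w0, 1.0), (1.0, 1.0)],
            "product",
            {"omega0": w0, "omega2": 1.0},
        )
    raise InputError(f"unknown model {model!r}")


def _starts_for(model, m0_omega, fix_kappa, kappa0):
    w0_init = _from_bounded(min(max(m0_omega, 0.01), 0.9), *OMEGA0_BOUNDS)
    head = [] if fix_kappa else [math.log(kappa0)]
    if model == "M1a":
        return [head + [w0_init], head + [_from_bounded(0.1, *OMEGA0_BOUNDS)]]
    if model == "M2a":
        return [
            head + [w0_init, _from_bounded(2.0, *OMEGA2_BOUNDS)],
            head + [w0_init, _from_bounded(20.0, *OMEGA2_BOUNDS)],
        ]
    if model == "M3":
        w = max(m0_omega, 1e-3)
        return [
            head + [math.log(0.3 * w), math.log(w), math.log(3.0 * w + 0.2)],
            head + [math.log(0.05), math.log(0.3), math.log(1.2)],
        ]
    if model == "M7":
        return [head + [math.log(0.4), math.log(2.5)], head + [0.0, 0.0]]
    if model == "M8":
        return [
            head + [math.log(0.4), math.log(2.5), _from_bounded(2.0, *OMEGA2_BOUNDS)],
            head + [math.log(0.4), math.log(2.5), _from_bounded(20.0, *OMEGA2_BOUNDS)],
        ]
    if model in ("bsA", "bsA_null"):
        base = [head + [w0_init]]
        if model == "bsA":
            return [
                head + [w0_init, _from_bounded(2.0, *OMEGA2_BOUNDS)],
                head + [w0_init, _from_bounded(20.0, *OMEGA2_BOUNDS)],
            ]
        return base
    raise InputError(f"unknown model {model!r}")


def _weights_and_lnl(mode, class_loglik, counts, engine):
    if mode == "free":
        k = class_loglik.shape[0]
        w, lnl = _em_simplex(class_loglik, counts, np.full(k, 1.0 / k))
        return w, lnl, {}
    if mode == "fixed":
        k = class_loglik.shape[0]
        w = np.full(k, 1.0 / k)
        lnl = engine.mixture_lnl(w, class_loglik)
        return w, lnl, {}
    if mode == "m8":
        nb = class_loglik.shape[0] - 1
        beta_block = logsumexp(class_loglik[:nb], axis=0) - math.log(nb)
        two = np.stack([beta_block, class_loglik[-1]])
        (w_beta, w_s), lnl = _em_simplex(two, counts, np.array([0.95, 0.05]))
        w = np.concatenate([np.full(nb, w_beta / nb), [w_s]])
        return w, lnl, {"p0": w_beta, "p1": w_s}
    if mode == "product":
        w, (a, b), lnl = _em_product(class_loglik, counts)
        return w, lnl, {"a": a, "b": b}
    raise InputError(mode)


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    *,
    branch_lengths: str | dict = "m0",
    m0_fit: ModelFit | None = None,
    pi: np.ndarray | None = None,
    fix_kappa: bool = False,
    engine: LikelihoodEngine | None = None,
    posterior_threshold: float = 0.95,
    maxiter: int = 300,
) -> ModelFit:
    """Fit a site or branch-site codon model by maximum likelihood.

    ``model`` is one of M0, M1a, M2a, M3, M7, M8, branch-site-A ("bsA")
    or its null ("bsA_null").  Branch lengths are taken from an M0 fit
    (default; pass ``m0_fit`` to reuse one), from the tree
    (``branch_lengths="tree"``), or from an explicit dict.
    """
    name_map = {"branch-site-A": "bsA", "branch-site-A-null": "bsA_null",
                "modelA": "bsA", "modelA_null": "bsA_null"}
    model = name_map.get(model, model)
    eng = engine or LikelihoodEngine(aln, tree, pi=pi)
    if model == "M0":
        return fit_m0(aln, tree, pi=pi, engine=eng)
    if model not in SITE_MODELS + BRANCH_SITE_MODELS:
        raise InputError(f"unknown model {model!r}")
    if isinstance(branch_lengths, dict):
        lengths = dict(branch_lengths)
        kappa0 = m0_fit.kappa if m0_fit is not None else 2.0
        m0_omega = m0_fit.params["omega"] if m0_fit is not None else 0.2
    elif branch_lengths == "tree":
        lengths = {n.name: n.length for n in eng.branch_nodes}
        kappa0 = m0_fit.kappa if m0_fit is not None else 2.0
        m0_omega = m0_fit.params["omega"] if m0_fit is not None else 0.2
    else:
        if m0_fit is None:
            m0_fit = fit_m0(aln, tree, pi=pi, engine=eng)
        lengths = m0_fit.branch_lengths
        kappa0, m0_omega = m0_fit.kappa, m0_fit.params["omega"]

    kappa_fixed = kappa0 if fix_kappa else None
    cache: dict = {}

    def class_logs(kappa, omega_pairs, scale):
        out = []
        for bg, fg in omega_pairs:
            key = (round(kappa, 12), round(bg, 12), round(fg, 12), round(scale, 12))
            if key not in cache:
                if len(cache) > 256:
                    cache.clear()
                cache[key] = eng.class_pattern_loglik(kappa, bg, fg, lengths, scale)
            out.append(cache[key])
        return np.stack(out)

    def neg_profile_lnl(theta):
        kappa, omega_pairs, mode, _ = _model_structure(model, theta[:-1], fix_kappa)
        k = kappa_fixed if kappa is None else kappa
        logs = class_logs(k, omega_pairs, math.exp(theta[-1]))
        _, lnl, _ = _weights_and_lnl(mode, logs, eng.counts, eng)
        return -lnl

    def with_scale_start(x0):
        """Append a rate-scale start: reciprocal mixture-average rate at
        plausible class weights for this start's omega values."""
        kappa, omega_pairs, mode, _ = _model_structure(model, x0, fix_kappa)
        k = kappa_fixed if kappa is None else kappa
        c = len(omega_pairs)
        if mode == "fixed" or c == 1:
            w = np.full(c, 1.0 / c)
        else:
            w = np.concatenate([[0.8], np.full(c - 1, 0.2 / (c - 1))])
        mu_bar = float(sum(wi * eng.mean_rate(k, bg) for wi, (bg, _) in zip(w, omega_pairs)))
        return list(x0) + [-math.log(max(mu_bar, 1e-8))]

    best = None
    for base in _starts_for(model, m0_omega, fix_kappa, kappa0):
        x0 = with_scale_start(base)
        res = optimize.minimize(
            neg_profile_lnl, np.asarray(x0, float), method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4},
        )
        if best is None or res.fun < best[1] - 1e-12:
            best = (res.x, res.fun)
    theta, _neg = best
    scale_final = math.exp(theta[-1])
    kappa, omega_pairs, mode, extras = _model_structure(model, theta[:-1], fix_kappa)
    kappa_final = kappa_fixed if kappa is None else kappa
    logs = class_logs(kappa_final, omega_pairs, scale_final)
    weights, lnl, weight_info = _weights_and_lnl(mode, logs, eng.counts, eng)

    params = dict(extras)
    params["kappa"] = kappa_final
    params["rate_scale"] = scale_final
    if mode == "free":
        for j, wj in enumerate(weights):
            params[f"p{j}"] = float(wj)
    elif mode == "m8":
        params["p0"] = weight_info["p0"]
        params["p1"] = weight_info["p1"]
    elif mode == "product":
        a, b = weight_info["a"], weight_info["b"]
        params.update(
            p0=float(weights[0]), p1=float(weights[1]),
            p2a=float(weights[2]), p2b=float(weights[3]),
        )

    fit = ModelFit(
        model=model,
        lnL=lnl,
        params=params,
        kappa=kappa_final,
        pi=eng.pi,
        branch_lengths=lengths,
        proportions=np.asarray(weights),
        class_omegas=tuple(omega_pairs),
        _class_loglik=logs,
        _pattern_counts=eng.counts,
        _site_to_pattern=eng.site_to_pattern,
    )
    fit.site_posteriors = _neb_posteriors(fit)
    fit.positively_selected_sites = selected_sites(fit, threshold=posterior_threshold)
    return fit


# --------------------------------------------------------------------
# empirical Bayes site identification
# --------------------------------------------------------------------


def _neb_posteriors(fit: ModelFit) -> np.ndarray:
    lw = np.log(np.maximum(fit.proportions, 1e-300))[:, None]
    post = fit._class_loglik + lw
    post = np.exp(post - logsumexp(post, axis=0, keepdims=True))
    return post[:, fit._site_to_pattern]


def _weight_grid(fit: ModelFit, n: int = 10):
    """Uniform grid over the free mixture proportions of a fitted model."""
    g = (np.arange(n) + 0.5) / n
    model = fit.model
    if model in ("M2a", "M3", "M1a"):
        if len(fit.proportions) == 2:
            return [np.array([b, 1 - b]) for b in g]
        # 3 classes via product coordinates (a, b): (ab, (1-a)b, 1-b)
        return [np.array([a * b, (1 - a) * b, 1 - b]) for a in g for b in g]
    if model == "M8":
        nb = len(fit.proportions) - 1
        return [np.concatenate([np.full(nb, p0 / nb), [1 - p0]]) for p0 in g]
    if model in ("bsA", "bsA_null"):
        return [
            np.array([a * b, (1 - a) * b, a * (1 - b), (1 - a) * (1 - b)])
            for a in g for b in g
        ]
    raise InputError(f"BEB grid unavailable for model {model!r}")


def site_posteriors(fit: ModelFit, method: str = "NEB", threshold: float = 0.95):
    """Per-site class posteriors and selected sites, NEB or grid BEB.

    BEB averages the class posteriors over a uniform 10-point grid per
    free mixture proportion, weighting each grid point by its data
    likelihood (omega values held at their MLEs).
    """
    if len(fit.proportions) < 2:
        raise InputError("empirical Bayes needs a mixture model fit")
    if fit._class_loglik is None:
        raise InputError("fit carries no per-class site likelihoods")
    if method.upper() == "NEB":
        post = _neb_posteriors(fit)
    elif method.upper() in ("BEB", "BEB-GRID"):
        counts = fit._pattern_counts
        grid = _weight_grid(fit)
        log_marg = np.array([
            np.dot(counts, logsumexp(
                fit._class_loglik + np.log(np.maximum(w, 1e-300))[:, None], axis=0))
            for w in grid
        ])
        grid_post = np.exp(log_marg - logsumexp(log_marg))
        post_p = np.zeros_like(fit._class_loglik)
        for gw, w in zip(grid_post, grid):
            z = fit._class_loglik + np.log(np.maximum(w, 1e-300))[:, None]
            post_p += gw * np.exp(z - logsumexp(z, axis=0, keepdims=True))
        post = post_p[:, fit._site_to_pattern]
    else:
        raise InputError(f"unknown method {method!r}")
    sites = _select(post, fit.positive_classes, threshold)
    return post, sites


def _select(post, positive_classes, threshold):
    if not positive_classes:
        return []
    mass = post[positive_classes].sum(axis=0)
    return [(int(s) + 1, float(mass[s])) for s in np.flatnonzero(mass > threshold)]


def selected_sites(fit: ModelFit, threshold: float = 0.95):
    """Sites whose positive-selection-class posterior exceeds the threshold."""
    if fit.site_posteriors is None:
        if fit._class_loglik is None:
            return []
        fit.site_posteriors = _neb_posteriors(fit)
    return _select(fit.site_posteriors, fit.positive_classes, threshold)


# --------------------------------------------------------------------
# branch-site scan
# --------------------------------------------------------------------


def branch_site_scan(
    aln: CodonAlignment,
    tree: PhyloTree,
    clades: list[str] | None = None,
    *,
    pi: np.ndarray | None = None,
    fix_kappa: bool = True,
    alpha: float = 0.05,
    posterior_threshold: float = 0.95,
    eb_method: str = "NEB",
    m0_fit: ModelFit | None = None,
):
    """Branch-site model A scan: each labeled clade foreground in turn.

    Returns a list of per-clade records with alternative and null fits,
    the df=1 LRT, and empirical-Bayes selected sites for clades whose
    LRT is significant at ``alpha``.
    """
    labels = clades if clades is not None else sorted(tree.clade_labels)
    if not labels:
        raise InputError("tree carries no labeled clades")
    eng = LikelihoodEngine(aln, tree, pi=pi)
    if m0_fit is None:
        m0_fit = fit_m0(aln, tree, pi=pi, engine=eng)
    rows = []
    for label in labels:
        tree.set_foreground_clade(label)
        alt = fit_model(
            aln, tree, "bsA", m0_fit=m0_fit, engine=eng,
            fix_kappa=fix_kappa, posterior_threshold=posterior_threshold,
        )
        null = fit_model(
            aln, tree, "bsA_null", m0_fit=m0_fit, engine=eng, fix_kappa=fix_kappa,
        )
        test = lrt(alt.lnL, null.lnL, df=1)
        sites = []
        if test.p <= alpha:
            _, sites = site_posteriors(alt, method=eb_method, threshold=posterior_threshold)
        rows.append({
            "clade": label,
            "lnL_alt": alt.lnL,
            "lnL_null": null.lnL,
            "stat": test.stat,
            "p": test.p,
            "alt": alt,
            "null": null,
            "selected_sites": sites,
        })
    tree.clear_foreground()
    return rows
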