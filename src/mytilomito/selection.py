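"""Codon-model selection screen: branch and branch-site fits with LRTs.

Implements the standard screen for shifts in selective pressure:

* one-ratio — a single dN/dS ratio (omega) over the whole tree;
* branch models — one omega per branch class (e.g. shallow-sea, deep-sea,
  freshwater), sharing kappa and branch lengths;
* branch-site model A — four site classes (0: omega0 on all branches,
  1: neutral, 2a/2b: omega2 on the foreground with omega0/1 elsewhere) and
  its null with omega2 fixed at 1;
* likelihood-ratio tests of nested pairs against chi-square;
* naive empirical Bayes (NEB) site posteriors at the ML estimates —
  reported explicitly as NEB so they are not mistaken for BEB values.

Columns containing a gap or ambiguity in any taxon are removed before
fitting (the count is recorded on the fit).  Optimization is multi-start
bounded quasi-Newton over log/logit-transformed parameters with analytic
branch-length gradients; all randomness sits behind one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon_alignment import CodonAlignment
from .codon_model import (
    CodonModelError,
    PhyloTree,
    _leaf_partials,
    branch_length_gradient,
    codon_frequencies,
    compress_patterns,
    edge_classes,
    gy94_rate_matrix,
    mean_rate,
    outside_partials,
    prune,
    spectral,
)
from .genetic_code import get_genetic_code

log = logging.getLogger(__name__)

_BL_BOUNDS = (1e-6, 20.0)
_KAPPA_BOUNDS = (0.05, 100.0)
_OMEGA_BOUNDS = (1e-4, 50.0)
_REL_STEP = 1e-5  # finite-difference step for the rate parameters


@dataclass
class FitConfig:
    freq_model: str = "F3x4"  # {F1x4, F3x4, uniform}
    n_starts: int = 3
    seed: int = 0
    tol: float = 1e-6  # convergence tolerance in lnL units
    max_iter: int = 400


@dataclass
class CodonModelParams:
    kappa: float
    codon_freqs: np.ndarray
    omega_map: dict  # branch class (or site-class label) -> omega
    branch_lengths: dict  # edge node id -> substitutions per codon site


@dataclass
class ModelFit:
    lnL: float
    params: CodonModelParams
    n_free_params: int
    converged: bool
    model_tag: str  # one_ratio | three_ratios | branch | branch_site_alt | branch_site_null
    n_dropped_columns: int = 0
    edge_class: dict = field(default_factory=dict)


@dataclass
class BranchSiteFit(ModelFit):
    p0: float = 0.0
    p1: float = 0.0
    p2a: float = 0.0
    p2b: float = 0.0
    omega0: float = 0.0
    omega1: float = 1.0
    omega2: float = 1.0
    foreground: tuple = ()


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float


@dataclass
class SiteClassPosterior:
    site_columns: np.ndarray  # original column indices (post-cleaning map)
    posteriors: np.ndarray  # (n_sites, 4) over classes 0, 1, 2a, 2b
    flagged: np.ndarray  # site columns with P(2a u 2b) > threshold
    threshold: float
    method: str = "NEB"


# ---------------------------------------------------------------------------
# shared machinery


class _Data:
    """Cleaned, pattern-compressed alignment bound to a tree."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, freq_model: str):
        missing = set(tree.taxa) - set(aln.taxa)
        if missing:
            raise CodonModelError(f"taxa in tree but not alignment: {sorted(missing)}")
        clean, dropped = aln.drop_incomplete_columns()
        self.n_dropped = dropped
        self.code = get_genetic_code(aln.code_id)
        self.pi = codon_frequencies(clean, freq_model)
        order = [aln.taxa.index(t) for t in tree.taxa]
        mat = clean.codons[order]
        self.patterns, self.weights, self.inverse = compress_patterns(mat)
        self.leafs = _leaf_partials(self.patterns, self.code.n_sense)
        self.kept_columns = np.flatnonzero((aln.codons >= 0).all(axis=0))
        self.tree = tree
        self.code_id = aln.code_id
        self.n_sites = mat.shape[1]


def _class_site_likelihood(data: _Data, kappa, omega_by_edge, lengths, rate_ref=None):
    """Per-pattern likelihoods and gradient pieces for one omega assignment.

    With ``rate_ref=None`` each omega's generator is scaled to one expected
    substitution per codon site (branch models: absorbed per branch).  In a
    site mixture the classes must share one time scale, so ``rate_ref``
    names the omega whose unscaled rate defines the unit (omega0 here);
    sites in faster classes then genuinely accumulate more substitutions.
    """
    if rate_ref is None:
        specs = {
            w: spectral(
                gy94_rate_matrix(kappa, w, data.pi, data.code_id), data.pi
            )
            for w in set(omega_by_edge.values())
        }
    else:
        mu = mean_rate(kappa, rate_ref, data.pi, data.code_id)
        specs = {
            w: spectral(
                gy94_rate_matrix(kappa, w, data.pi, data.code_id, scale=False) / mu,
                data.pi,
            )
            for w in set(omega_by_edge.values())
        }
    tree = data.tree.with_lengths(lengths)
    P = {v: specs[omega_by_edge[v]].transition(lengths[v]) for v in tree.edges()}
    Q = {v: specs[omega_by_edge[v]].Q for v in tree.edges()}
    res = prune(tree, data.leafs, P, data.pi)
    return res, Q, tree


def _pack_log(values, bounds):
    return np.log(np.clip(values, *bounds))


def _logit(p, lo=1e-4):
    p = np.clip(p, lo, 1 - lo)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _run_optimizer(fun_grad, x0, bounds, cfg: FitConfig):
    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": cfg.max_iter,
            "ftol": cfg.tol * 1e-4,  # relative; lnL magnitudes are >= 1e2
            "gtol": 1e-6,
        },
    )
    return res


def _multi_start(fun_grad, x0, bounds, cfg: FitConfig):
    rng = np.random.default_rng(cfg.seed)
    best = _run_optimizer(fun_grad, x0, bounds, cfg)
    for _ in range(max(0, cfg.n_starts - 1)):
        xs = x0 + rng.normal(0.0, 0.3, size=len(x0))
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        res = _run_optimizer(fun_grad, xs, bounds, cfg)
        if res.fun < best.fun - 1e-9:
            best = res
    return best


# ---------------------------------------------------------------------------
# branch models (one omega per branch class; one-ratio is the 1-class case)


def fit_one_ratio(
    aln: CodonAlignment, tree: PhyloTree, config: FitConfig | None = None
) -> ModelFit:
    """Single omega over all branches (the null of the branch screen)."""
    cfg = config or FitConfig()
    classes = {v: "all" for v in tree.edges()}
    fit = _fit_branch_like(aln, tree, classes, cfg, tag="one_ratio")
    return fit


def fit_branch_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    partition: dict,
    config: FitConfig | None = None,
    init: ModelFit | None = None,
) -> ModelFit:
    """One omega per branch class (CODEML's model=2, NSsites=0 analogue).

    ``partition`` maps either edge ids or taxon labels to class names;
    taxon maps are lifted onto branches (internal branches inherit a class
    when all their leaves share it).
    """
    cfg = config or FitConfig()
    classes = _as_edge_classes(tree, partition)
    n_classes = len(set(classes.values()))
    tag = "three_ratios" if n_classes == 3 else "branch"
    if n_classes == 1:
        tag = "one_ratio"
    return _fit_branch_like(aln, tree, classes, cfg, tag=tag, init=init)


def _as_edge_classes(tree: PhyloTree, partition: dict) -> dict:
    if all(isinstance(k, (int, np.integer)) for k in partition):
        missing = [v for v in tree.edges() if v not in partition]
        if missing:
            raise CodonModelError(f"branches without a class label: {missing}")
        return {v: partition[v] for v in tree.edges()}
    return edge_classes(tree, partition)


def _fit_branch_like(aln, tree, classes, cfg, tag, init=None):
    data = _Data(aln, tree, cfg.freq_model)
    edges = tree.edges()
    class_names = sorted(set(classes.values()))
    nE, nC = len(edges), len(class_names)

    def decode(x):
        bl = np.zeros(tree.n_nodes)
        for e, v in zip(edges, np.exp(x[:nE])):
            bl[e] = v
        kappa = float(np.exp(x[nE]))
        omegas = {c: float(np.exp(x[nE + 1 + i])) for i, c in enumerate(class_names)}
        return bl, kappa, omegas

    def lnl_only(bl, kappa, omegas):
        omega_by_edge = {v: omegas[classes[v]] for v in edges}
        res, _, _ = _class_site_likelihood(data, kappa, omega_by_edge, bl)
        sl = res.site_likelihoods
        if (sl <= 0).any():
            return -np.inf
        return float(data.weights @ np.log(sl))

    def fun_grad(x):
        bl, kappa, omegas = decode(x)
        omega_by_edge = {v: omegas[classes[v]] for v in edges}
        res, Q, t = _class_site_likelihood(data, kappa, omega_by_edge, bl)
        sl = res.site_likelihoods
        if (sl <= 0).any() or not np.isfinite(sl).all():
            return 1e10, np.zeros_like(x)
        lnl = float(data.weights @ np.log(sl))
        G = outside_partials(t, res, data.pi)
        dsl = branch_length_gradient(t, res, G, Q)
        grad = np.zeros_like(x)
        wr = data.weights / sl
        for k, v in enumerate(edges):
            grad[k] = (wr @ dsl[v]) * bl[v]  # chain rule through log
        # rate parameters by forward finite differences in log space
        for k, (name, val) in enumerate(
            [("kappa", kappa)] + [(c, omegas[c]) for c in class_names]
        ):
            h = _REL_STEP
            if name == "kappa":
                up = lnl_only(bl, kappa * np.exp(h), omegas)
            else:
                om2 = dict(omegas)
                om2[name] = val * np.exp(h)
                up = lnl_only(bl, kappa, om2)
            grad[nE + k] = (up - lnl) / h
        return -lnl, -grad

    # starting point: input branch lengths, kappa=2, omega from config or init
    if init is not None:
        bl0 = np.array(
            [init.params.branch_lengths.get(v, 0.1) for v in edges]
        )
        kappa0 = init.params.kappa
        om_init = np.mean(list(init.params.omega_map.values()))
    else:
        bl0 = np.array([tree.lengths[v] if tree.lengths[v] > 0 else 0.1 for v in edges])
        kappa0, om_init = 2.0, 0.2
    x0 = np.concatenate(
        [
            _pack_log(bl0, _BL_BOUNDS),
            _pack_log([kappa0], _KAPPA_BOUNDS),
            _pack_log([om_init] * nC, _OMEGA_BOUNDS),
        ]
    )
    bounds = (
        [tuple(np.log(_BL_BOUNDS))] * nE
        + [tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_OMEGA_BOUNDS))] * nC
    )
    res = _multi_start(fun_grad, x0, bounds, cfg)
    bl, kappa, omegas = decode(res.x)
    params = CodonModelParams(
        kappa=kappa,
        codon_freqs=data.pi,
        omega_map=omegas,
        branch_lengths={v: float(bl[v]) for v in edges},
    )
    return ModelFit(
        lnL=-float(res.fun),
        params=params,
        n_free_params=nE + 1 + nC,
        converged=bool(res.success),
        model_tag=tag,
        n_dropped_columns=data.n_dropped,
        edge_class=dict(classes),
    )


# ---------------------------------------------------------------------------
# branch-site model A


def _branch_site_class_maps(edges, foreground, omega0, omega2):
    fg = set(foreground)
    return [
        {v: omega0 for v in edges},  # class 0
        {v: 1.0 for v in edges},  # class 1
        {v: (omega2 if v in fg else omega0) for v in edges},  # class 2a
        {v: (omega2 if v in fg else 1.0) for v in edges},  # class 2b
    ]


def _mixture_proportions(q, r):
    return np.array([q * r, q * (1 - r), (1 - q) * r, (1 - q) * (1 - r)])


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground,
    null: bool = False,
    config: FitConfig | None = None,
    init: ModelFit | None = None,
) -> BranchSiteFit:
    """Branch-site model A (alternative) or its omega2=1 null.

    ``foreground`` is a set of edge ids, or a taxon->class map together
    with... — pass either an iterable of edge node ids or a dict mapping
    taxon labels to truthy values, lifted to branches via
    :func:`~mytilomito.codon_model.edge_classes`.
    """
    cfg = config or FitConfig()
    edges = tree.edges()
    fg = _foreground_edges(tree, foreground)
    if not fg or set(fg) >= set(edges):
        raise CodonModelError("foreground must be a non-empty proper subset of branches")
    data = _Data(aln, tree, cfg.freq_model)
    nE = len(edges)
    n_free = nE + (4 if null else 5)  # bl + kappa + q + r + omega0 (+ omega2)

    def decode(x):
        bl = np.zeros(tree.n_nodes)
        for e, v in zip(edges, np.exp(x[:nE])):
            bl[e] = v
        kappa = float(np.exp(x[nE]))
        q = float(_expit(x[nE + 1]))
        r = float(_expit(x[nE + 2]))
        omega0 = float(_expit(x[nE + 3]))
        omega2 = 1.0 if null else 1.0 + float(np.exp(x[nE + 4]))
        return bl, kappa, q, r, omega0, omega2

    def class_likelihoods(bl, kappa, omega0, omega2, want_grad=False):
        maps = _branch_site_class_maps(edges, fg, omega0, omega2)
        Ls, grads = [], []
        for m in maps:
            res, Q, t = _class_site_likelihood(data, kappa, m, bl, rate_ref=omega0)
            Ls.append(res.site_likelihoods)
            if want_grad:
                G = outside_partials(t, res, data.pi)
                grads.append(branch_length_gradient(t, res, G, Q))
        return np.array(Ls), grads

    def fun_grad(x):
        bl, kappa, q, r, omega0, omega2 = decode(x)
        props = _mixture_proportions(q, r)
        Ls, grads = class_likelihoods(bl, kappa, omega0, omega2, want_grad=True)
        sl = props @ Ls
        if (sl <= 0).any() or not np.isfinite(sl).all():
            return 1e10, np.zeros_like(x)
        lnl = float(data.weights @ np.log(sl))
        wr = data.weights / sl
        grad = np.zeros_like(x)
        for k, v in enumerate(edges):
            d = sum(p * g[v] for p, g in zip(props, grads))
            grad[k] = (wr @ d) * bl[v]
        # mixture proportions: analytic through the logit transforms
        dpdq = np.array([r, 1 - r, -r, -(1 - r)])
        dpdr = np.array([q, -q, 1 - q, -(1 - q)])
        grad[nE + 1] = (wr @ (dpdq @ Ls)) * q * (1 - q)
        grad[nE + 2] = (wr @ (dpdr @ Ls)) * r * (1 - r)
        # kappa, omega0, omega2: finite differences (full recompute)
        def lnl_at(kap, o0, o2):
            L2, _ = class_likelihoods(bl, kap, o0, o2)
            s = props @ L2
            if (s <= 0).any():
                return -np.inf
            return float(data.weights @ np.log(s))

        h = _REL_STEP
        grad[nE] = (lnl_at(kappa * np.exp(h), omega0, omega2) - lnl) / h
        o0_up = _expit(x[nE + 3] + h)
        grad[nE + 3] = (lnl_at(kappa, o0_up, omega2) - lnl) / h
        if not null:
            o2_up = 1.0 + np.exp(x[nE + 4] + h)
            grad[nE + 4] = (lnl_at(kappa, omega0, o2_up) - lnl) / h
        return -lnl, -grad

    if init is not None:
        bl0 = np.array([init.params.branch_lengths.get(v, 0.1) for v in edges])
        kappa0 = init.params.kappa
    else:
        bl0 = np.array([tree.lengths[v] if tree.lengths[v] > 0 else 0.1 for v in edges])
        kappa0 = 2.0
    x0 = np.concatenate(
        [
            _pack_log(bl0, _BL_BOUNDS),
            _pack_log([kappa0], _KAPPA_BOUNDS),
            [_logit(0.8), _logit(0.9), _logit(0.1)],
            [] if null else [np.log(1.0)],  # omega2 = 2
        ]
    )
    bounds = (
        [tuple(np.log(_BL_BOUNDS))] * nE
        + [tuple(np.log(_KAPPA_BOUNDS))]
        + [(-9.2, 9.2), (-9.2, 9.2), (-9.2, 9.2)]
        + ([] if null else [(-10.0, 7.0)])
    )
    res = _multi_start(fun_grad, x0, bounds, cfg)
    bl, kappa, q, r, omega0, omega2 = decode(res.x)
    p0, p1, p2a, p2b = _mixture_proportions(q, r)
    params = CodonModelParams(
        kappa=kappa,
        codon_freqs=data.pi,
        omega_map={"0": omega0, "1": 1.0, "2": omega2},
        branch_lengths={v: float(bl[v]) for v in edges},
    )
    return BranchSiteFit(
        lnL=-float(res.fun),
        params=params,
        n_free_params=n_free,
        converged=bool(res.success),
        model_tag="branch_site_null" if null else "branch_site_alt",
        n_dropped_columns=data.n_dropped,
        edge_class={v: ("foreground" if v in fg else "background") for v in edges},
        p0=float(p0),
        p1=float(p1),
        p2a=float(p2a),
        p2b=float(p2b),
        omega0=omega0,
        omega2=omega2,
        foreground=tuple(sorted(fg)),
    )


def _foreground_edges(tree: PhyloTree, foreground) -> set:
    if isinstance(foreground, dict):
        classes = edge_classes(
            tree, {t: "foreground" for t, flag in foreground.items() if flag}
        )
        return {v for v, c in classes.items() if c == "foreground"}
    fg = set(foreground)
    if fg and all(isinstance(v, str) for v in fg):
        classes = edge_classes(tree, {t: "foreground" for t in fg})
        return {v for v, c in classes.items() if c == "foreground"}
    return fg


# ---------------------------------------------------------------------------
# LRT and NEB


def lrt(null: ModelFit, alt: ModelFit, df: int, tolerance: float = 0.1) -> LrtResult:
    """2*(lnL_alt - lnL_null) against chi-square(df), clamped at 0.

    A deficit beyond ``tolerance`` lnL units signals optimizer failure and
    raises rather than reporting a meaningless p-value.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = alt.lnL - null.lnL
    if delta < -tolerance:
        raise CodonModelError(
            f"alternative lnL {alt.lnL:.4f} below null {null.lnL:.4f}: "
            "optimizer failure"
        )
    stat = max(0.0, 2.0 * delta)
    return LrtResult(stat=stat, df=df, p_value=float(chi2.sf(stat, df)))


def neb_site_posteriors(
    fit: BranchSiteFit,
    aln: CodonAlignment,
    tree: PhyloTree,
    threshold: float = 0.95,
    config: FitConfig | None = None,
) -> SiteClassPosterior:
    """Naive empirical Bayes posteriors over the four site classes.

    Posterior(site, class) is proportional to the class proportion times the
    site likelihood under that class, all at the ML point estimates.
    """
    cfg = config or FitConfig()
    data = _Data(aln, tree, cfg.freq_model)
    edges = tree.edges()
    fg = set(fit.foreground)
    bl = np.zeros(tree.n_nodes)
    for v, t in fit.params.branch_lengths.items():
        bl[v] = t
    maps = _branch_site_class_maps(edges, fg, fit.omega0, fit.omega2)
    Ls = []
    for m in maps:
        res, _, _ = _class_site_likelihood(
            data, fit.params.kappa, m, bl, rate_ref=fit.omega0
        )
        Ls.append(res.site_likelihoods[data.inverse])  # expand patterns -> sites
    Ls = np.array(Ls)  # (4, n_sites)
    props = np.array([fit.p0, fit.p1, fit.p2a, fit.p2b])
    joint = props[:, None] * Ls
    total = joint.sum(axis=0)
    post = (joint / total).T  # (n_sites, 4)
    flagged = data.kept_columns[(post[:, 2] + post[:, 3]) > threshold]
    return SiteClassPosterior(
        site_columns=data.kept_columns,
        posteriors=post,
        flagged=flagged,
        threshold=threshold,
    )
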