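"""Site-class codon model fitting and positive-selection inference.

Implements the CODEML-style site models M0 (one ratio), M1 (nearly
neutral), M2 (positive selection), M3 (discrete, 3 classes), M7 (beta)
and M8 (beta plus a class with omega >= 1); likelihood ratio tests for
the nested pairs M1-M2, M0-M3 and M7-M8; naive empirical Bayes (NEB)
and Bayes empirical Bayes (BEB) per-site posteriors of positive
selection; and a random-effects (REL-style) analysis in which the
synonymous and nonsynonymous rates vary across sites independently.

All models share the Goldman-Yang rate matrix of :mod:`codon_engine`;
kappa and (by default) branch lengths are estimated by maximum
likelihood jointly with the site-model parameters, using bounded
quasi-Newton optimization on transformed parameters (log for rates,
logistic/stick-breaking for proportions) with deterministic multistart,
because site-class likelihood surfaces are multimodal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .codon_engine import (
    PhyloTree,
    TreeLikelihood,
    build_class_matrices,
    estimate_frequencies,
)

logger = logging.getLogger(__name__)

SUPPORTED_MODELS = ("M0", "M1", "M2", "M3", "M7", "M8")
#: nested LRT pairs (null, alternative) -> degrees of freedom
NESTED_PAIRS = {("M1", "M2"): 2, ("M0", "M3"): 4, ("M7", "M8"): 2}
#: free site-model parameters, as CODEML counts them for these LRTs
N_SITE_PARAMS = {"M0": 1, "M1": 2, "M2": 4, "M3": 5, "M7": 2, "M8": 4}

_POSITIVE_EPS = 1e-9  # a class is "positive" when omega > 1 + eps


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class SiteClassModel:
    """A site-class mixture: discrete classes with proportions and omegas.

    For M7/M8 the beta distribution is represented by its K
    equal-probability discretized classes; ``beta_params`` keeps (p, q)
    and, for M8, ``extra_class`` keeps (p1, omega_s).
    """

    model_id: str
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    beta_params: tuple[float, float] | None = None
    extra_class: tuple[float, float] | None = None
    n_discrete: int = 10

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("class proportions must be a probability vector")
        self.class_proportions = np.clip(p, 0.0, 1.0)
        self.class_omegas = np.asarray(self.class_omegas, dtype=float)

    @property
    def positive_classes(self) -> np.ndarray:
        return np.flatnonzero(self.class_omegas > 1.0 + _POSITIVE_EPS)

    def mean_omega(self) -> float:
        return float(self.class_proportions @ self.class_omegas)


@dataclass
class FitResult:
    model: SiteClassModel
    lnL: float
    kappa_hat: float
    tree: PhyloTree            # with fitted (or input) branch lengths
    pi: np.ndarray
    converged: bool
    n_free_params: int
    n_starts: int = 1
    message: str = ""


@dataclass
class LRTResult:
    null_id: str
    alt_id: str
    stat: float
    df: int
    p_value: float


@dataclass
class SitePosteriorTable:
    """Per-codon class posteriors; ``p_positive`` is the posterior mass of
    omega > 1 classes. Sites are reported 1-based."""

    method: str
    class_omegas: np.ndarray
    posteriors: np.ndarray      # (n_sites, n_classes)
    p_positive: np.ndarray      # (n_sites,)
    mean_omega_per_site: np.ndarray | None = None

    def positive_sites(self, threshold: float = 0.95) -> list[tuple[int, float]]:
        """1-based codon positions with p_positive >= threshold."""
        return [
            (i + 1, float(p))
            for i, p in enumerate(self.p_positive)
            if p >= threshold
        ]


# ---------------------------------------------------------------------------
# Beta discretization
# ---------------------------------------------------------------------------

def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """Means of the K equal-probability quantile slices of Beta(p, q).

    Each slice has prior weight 1/K; the mean of slice k is
    K * mu * (I(x_k; p+1, q) - I(x_{k-1}; p+1, q)) with mu = p/(p+q) and
    x_k the k/K quantile of Beta(p, q), so the overall mean is exactly mu.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    mu = p / (p + q)
    mass_above = stats.beta.cdf(edges, p + 1, q)
    means = K * mu * np.diff(mass_above)
    # guard against round-off in extreme tails
    return np.clip(means, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


class _ModelSpec:
    """Mapping between a free site-parameter vector and (weights, omegas)."""

    def __init__(self, model_id: str, n_discrete: int = 10):
        if model_id not in SUPPORTED_MODELS:
            raise ValueError(f"unsupported model {model_id!r}")
        self.model_id = model_id
        self.K = n_discrete
        self.n_params = {
            "M0": 1, "M1": 2, "M2": 4, "M3": 5, "M7": 2, "M8": 4
        }[model_id]

    def unpack(self, x) -> SiteClassModel:
        m = self.model_id
        if m == "M0":
            return SiteClassModel("M0", [1.0], [np.exp(x[0])])
        if m == "M1":
            p0 = _sigmoid(x[0])
            w0 = _sigmoid(x[1])
            return SiteClassModel("M1", [p0, 1 - p0], [w0, 1.0])
        if m == "M2":
            p0 = _sigmoid(x[0])
            p1 = (1 - p0) * _sigmoid(x[1])
            p2 = 1 - p0 - p1
            w0 = _sigmoid(x[2])
            w2 = 1.0 + np.exp(x[3])
            return SiteClassModel("M2", [p0, p1, p2], [w0, 1.0, w2])
        if m == "M3":
            p0 = _sigmoid(x[0])
            p1 = (1 - p0) * _sigmoid(x[1])
            p2 = 1 - p0 - p1
            omegas = np.exp(x[2:5])
            order = np.argsort(omegas)
            props = np.array([p0, p1, p2])[order]
            return SiteClassModel("M3", props, omegas[order])
        if m == "M7":
            p, q = np.exp(x[0]), np.exp(x[1])
            means = discretize_beta(p, q, self.K)
            return SiteClassModel(
                "M7", np.full(self.K, 1.0 / self.K), means, beta_params=(p, q)
            )
        # M8
        p0 = _sigmoid(x[0])
        p, q = np.exp(x[1]), np.exp(x[2])
        w_s = 1.0 + np.exp(x[3])
        means = discretize_beta(p, q, self.K)
        props = np.append(np.full(self.K, p0 / self.K), 1 - p0)
        omegas = np.append(means, w_s)
        return SiteClassModel(
            "M8", props, omegas, beta_params=(p, q), extra_class=(1 - p0, w_s)
        )

    def starts(self) -> list[np.ndarray]:
        """Deterministic multistart points in transformed coordinates."""
        m = self.model_id
        if m == "M0":
            return [np.log([w]) for w in (0.1, 0.4, 1.2)]
        if m == "M1":
            return [
                np.array([_logit(p0), _logit(w0)])
                for p0, w0 in ((0.7, 0.2), (0.5, 0.5), (0.9, 0.05))
            ]
        if m == "M2":
            return [
                np.array([_logit(p0), _logit(0.8), _logit(w0), np.log(w2 - 1)])
                for p0, w0, w2 in ((0.6, 0.2, 3.0), (0.5, 0.1, 1.5), (0.8, 0.4, 6.0))
            ]
        if m == "M3":
            return [
                np.array([_logit(0.3), _logit(0.6),
                          np.log(a), np.log(b), np.log(c)])
                for a, b, c in ((0.05, 0.3, 2.0), (0.1, 0.5, 1.2), (0.02, 0.2, 5.0))
            ]
        if m == "M7":
            return [
                np.log([p, q])
                for p, q in ((0.7, 1.3), (0.3, 0.5), (1.5, 3.0))
            ]
        return [
            np.array([_logit(p0), np.log(p), np.log(q), np.log(ws - 1)])
            for p0, p, q, ws in (
                (0.85, 0.7, 1.3, 2.3), (0.95, 0.3, 0.5, 1.5), (0.7, 1.0, 1.0, 4.0)
            )
        ]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_BL_MIN, _BL_MAX = 1e-6, 20.0


def fit_site_model(
    aln,
    tree: PhyloTree,
    model_id: str,
    *,
    pi: np.ndarray | None = None,
    freq_scheme: str = "F3x4",
    n_discrete: int = 10,
    optimize_branch_lengths: bool = True,
    kappa: float | None = None,
    n_starts: int = 3,
    maxiter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit of one site-class model.

    ``kappa=None`` estimates kappa; a float fixes it. Branch lengths start
    from the input tree and are re-estimated unless
    ``optimize_branch_lengths=False``. Multistart is deterministic.
    """
    if pi is None:
        pi = estimate_frequencies(aln, freq_scheme)
    pi = np.asarray(pi, dtype=float)
    spec = _ModelSpec(model_id, n_discrete)
    tl = TreeLikelihood(aln, tree)
    edge_nodes = tree.edge_nodes()
    bl0 = np.clip(tree.edge_length[edge_nodes], _BL_MIN, _BL_MAX)

    fit_kappa = kappa is None
    n_site = spec.n_params
    n_extra = (1 if fit_kappa else 0) + (len(bl0) if optimize_branch_lengths else 0)

    def split(x):
        xs = x[:n_site]
        i = n_site
        if fit_kappa:
            kap = float(np.exp(x[i]))
            i += 1
        else:
            kap = float(kappa)
        if optimize_branch_lengths:
            bl = np.exp(x[i:])
        else:
            bl = bl0
        return xs, kap, bl

    def negloglik(x):
        xs, kap, bl = split(x)
        try:
            model = spec.unpack(xs)
        except (ValueError, FloatingPointError):
            return 1e10
        mats = build_class_matrices(
            kap, model.class_omegas, model.class_proportions, pi
        )
        try:
            lnl = tl.log_likelihood(
                mats, model.class_proportions, pi,
                bl if optimize_branch_lengths else None,
            )
        except np.linalg.LinAlgError:
            return 1e10
        if not np.isfinite(lnl):
            return 1e10
        return -lnl

    bounds = [(-12.0, 8.0)] * n_site
    if fit_kappa:
        bounds.append((np.log(0.05), np.log(50.0)))
    if optimize_branch_lengths:
        bounds.extend([(np.log(_BL_MIN), np.log(_BL_MAX))] * len(bl0))

    best = None
    starts = spec.starts()[:max(1, n_starts)]
    for site_start in starts:
        x0 = list(site_start)
        if fit_kappa:
            x0.append(np.log(2.0))
        if optimize_branch_lengths:
            x0.extend(np.log(bl0))
        res = optimize.minimize(
            negloglik,
            np.asarray(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "maxfun": 200000},
        )
        if best is None or res.fun < best.fun:
            best = res

    xs, kap, bl = split(best.x)
    model = spec.unpack(xs)
    fitted_tree = tree.with_edge_lengths(bl) if optimize_branch_lengths else tree
    converged = bool(best.success) and best.fun < 1e9
    if not converged:
        logger.warning("fit of %s did not converge cleanly: %s",
                       model_id, best.message)
    return FitResult(
        model=model,
        lnL=float(-best.fun),
        kappa_hat=kap,
        tree=fitted_tree,
        pi=pi,
        converged=converged,
        n_free_params=N_SITE_PARAMS[model_id],
        n_starts=len(starts),
        message=str(best.message),
    )


def lrt(null: FitResult, alt: FitResult) -> LRTResult:
    """Likelihood ratio test for one of the nested pairs M1-M2, M0-M3, M7-M8.

    stat = max(0, 2(lnL_alt - lnL_null)) compared against chi^2 with df equal
    to the difference in free site-model parameters.
    """
    pair = (null.model.model_id, alt.model.model_id)
    if pair not in NESTED_PAIRS:
        raise ValueError(
            f"{pair[0]} is not the supported null of {pair[1]}; "
            f"supported pairs: {sorted(NESTED_PAIRS)}"
        )
    df = NESTED_PAIRS[pair]
    stat = max(0.0, 2.0 * (alt.lnL - null.lnL))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(pair[0], pair[1], stat, df, p)


# ---------------------------------------------------------------------------
# Empirical Bayes site posteriors
# ---------------------------------------------------------------------------

def _site_class_posteriors(tl: TreeLikelihood, model: SiteClassModel,
                           kappa: float, pi: np.ndarray):
    mats = build_class_matrices(
        kappa, model.class_omegas, model.class_proportions, pi
    )
    lik, logscale = tl.site_class_likelihoods(mats, pi)
    w = model.class_proportions[:, None]
    m = logscale.max(axis=0)
    num = w * lik * np.exp(logscale - m)
    denom = num.sum(axis=0)
    denom[denom == 0] = 1.0
    return (num / denom).T  # (n_sites, n_classes)


def neb_posteriors(fit: FitResult, aln, tree: PhyloTree | None = None
                   ) -> SitePosteriorTable:
    """Naive empirical Bayes: class posteriors at the MLEs,
    P(k | site) = p_k L_k(site) / sum_j p_j L_j(site)."""
    model = fit.model
    if len(model.class_omegas) < 1:
        raise ValueError("model has no site classes")
    tl = TreeLikelihood(aln, tree or fit.tree)
    post = _site_class_posteriors(tl, model, fit.kappa_hat, fit.pi)
    p_pos = post[:, model.positive_classes].sum(axis=1)
    mean_w = post @ model.class_omegas
    return SitePosteriorTable("NEB", model.class_omegas, post, p_pos, mean_w)


def _grid_midpoints(n: int, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * (2 * np.arange(1, n + 1) - 1) / (2 * n)


def beb_posteriors(fit: FitResult, aln, tree: PhyloTree | None = None,
                   grid_size: int = 10,
                   grids: dict[str, np.ndarray] | None = None
                   ) -> SitePosteriorTable:
    """Bayes empirical Bayes for M2 or M8.

    Integrates the class posteriors over a uniform-prior grid on the
    site-model parameters, with kappa, branch lengths and the rate-matrix
    scale fixed at the MLEs. Default grids are equal-width midpoints
    (proportions on (0,1), beta parameters on (0,2), the selected-class
    omega on (1,11)); ``grids`` overrides individual dimensions
    (M8: ``p0``, ``p``, ``q``, ``w_sel``; M2: ``u``, ``v``, ``w0``,
    ``w2``, where p0=u and p1=(1-u)v). A grid collapsed onto the MLE
    point reduces to NEB.
    """
    model = fit.model
    if model.model_id not in ("M2", "M8"):
        raise ValueError("BEB is defined for models M2 and M8 only")
    tl = TreeLikelihood(aln, tree or fit.tree)
    pi = fit.pi
    n = grid_size

    # fix the rate-matrix scale at the MLE mixture so branch lengths keep
    # their fitted meaning across grid points
    from .codon_engine import _unscaled_rate_matrix, expected_rate

    mle_mats_unscaled = [
        _unscaled_rate_matrix(fit.kappa_hat, w, pi) for w in model.class_omegas
    ]
    scale = sum(
        p * expected_rate(q, pi)
        for p, q in zip(model.class_proportions, mle_mats_unscaled)
    )

    def site_liks_at(omegas):
        """(n_omegas, n_sites) likelihoods under single-omega classes,
        all at the MLE-fixed scale; returned in log space."""
        mats = [
            _unscaled_rate_matrix(fit.kappa_hat, w, pi) / scale for w in omegas
        ]
        lik, logscale = tl.site_class_likelihoods(mats, pi)
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale

    grids = grids or {}
    if model.model_id == "M8":
        w_beta = _grid_midpoints(n, 0.0, 1.0)          # beta-part omega bins
        w_sel = np.atleast_1d(grids.get("w_sel", _grid_midpoints(n, 1.0, 11.0)))
        p0_g = np.atleast_1d(grids.get("p0", _grid_midpoints(n, 0.0, 1.0)))
        p_g = np.atleast_1d(grids.get("p", _grid_midpoints(n, 0.0, 2.0)))
        q_g = np.atleast_1d(grids.get("q", _grid_midpoints(n, 0.0, 2.0)))
        logf = site_liks_at(np.concatenate([w_beta, w_sel]))
        # bin masses of Beta(p,q) over the n equal-width bins of (0,1)
        edges = np.linspace(0.0, 1.0, n + 1)
        beta_mass = np.array([
            np.diff(stats.beta.cdf(edges, p, q)) for p in p_g for q in q_g
        ])
        beta_mass /= beta_mass.sum(axis=1, keepdims=True)
        n_pq = beta_mass.shape[0]
        n_sel = len(w_sel)
        rows, rows_pos = [], []
        for p0 in p0_g:
            for ipq in range(n_pq):
                for isel in range(n_sel):
                    w = np.zeros(n + n_sel)
                    w[:n] = p0 * beta_mass[ipq]
                    w[n + isel] = 1 - p0
                    wp = np.zeros(n + n_sel)
                    wp[n + isel] = 1 - p0
                    rows.append(w)
                    rows_pos.append(wp)
        W = np.array(rows)
        Wpos = np.array(rows_pos)
        prior = None
    else:  # M2
        w0_g = np.atleast_1d(grids.get("w0", _grid_midpoints(n, 0.0, 1.0)))
        w2_g = np.atleast_1d(grids.get("w2", _grid_midpoints(n, 1.0, 11.0)))
        u_g = np.atleast_1d(grids.get("u", _grid_midpoints(n, 0.0, 1.0)))
        v_g = np.atleast_1d(grids.get("v", _grid_midpoints(n, 0.0, 1.0)))
        n0, n2 = len(w0_g), len(w2_g)
        logf = site_liks_at(np.concatenate([w0_g, [1.0], w2_g]))
        rows = []
        prior = []
        for u in u_g:          # p0 = u, (p1,p2) split (1-u) by v; prior ~ (1-u)
            for v in v_g:
                for i0 in range(n0):
                    for i2 in range(n2):
                        w = np.zeros(n0 + 1 + n2)
                        w[i0] = u
                        w[n0] = (1 - u) * v
                        w[n0 + 1 + i2] = (1 - u) * (1 - v)
                        rows.append(w)
                        prior.append(1 - u)
        W = np.array(rows)
        Wpos = np.zeros_like(W)
        Wpos[:, n0 + 1:] = W[:, n0 + 1:]
        prior = np.array(prior)

    # site likelihood per grid combo, in a numerically safe way
    shift = logf.max(axis=0)
    f = np.exp(logf - shift)           # (n_omegas, sites)
    F = W @ f                          # (n_combos, sites)
    Npos = Wpos @ f
    with np.errstate(divide="ignore"):
        logL = (np.log(F) + shift).sum(axis=1)
    if prior is not None:
        logL = logL + np.log(np.clip(prior, 1e-300, None))
    logL -= logL.max()
    post_grid = np.exp(logL)
    post_grid /= post_grid.sum()
    ratio = np.where(F > 0, Npos / np.where(F > 0, F, 1.0), 0.0)
    p_pos = post_grid @ ratio          # (sites,)

    post = np.column_stack([1 - p_pos, p_pos])
    return SitePosteriorTable(
        "BEB", np.array([model.class_omegas.min(), model.class_omegas.max()]),
        post, p_pos,
    )


# ---------------------------------------------------------------------------
# REL-style analysis
# ---------------------------------------------------------------------------

@dataclass
class RELResult:
    syn_rates: np.ndarray
    syn_weights: np.ndarray
    nonsyn_rates: np.ndarray
    nonsyn_weights: np.ndarray
    kappa_hat: float
    lnL: float
    mean_omega: float
    posteriors: SitePosteriorTable
    converged: bool


def rel_analysis(aln, tree: PhyloTree, K_s: int = 3, K_n: int = 3, *,
                 pi: np.ndarray | None = None, freq_scheme: str = "F3x4",
                 kappa: float | None = None, maxiter: int = 400) -> RELResult:
    """Random-effects site analysis with independent synonymous and
    nonsynonymous rate distributions (K_s x K_n category grid).

    The synonymous distribution is normalized to mean 1 (identifiability),
    so the reported mean omega is the mean of the nonsynonymous
    distribution. Branch lengths are taken from the input tree (fit M0
    first to obtain them in substitutions/codon). Per-site output is the
    empirical-Bayes posterior that the site's nonsynonymous rate exceeds
    its synonymous rate.
    """
    if pi is None:
        pi = estimate_frequencies(aln, freq_scheme)
    pi = np.asarray(pi, dtype=float)
    tl = TreeLikelihood(aln, tree)

    if all(r == aln.columns[0] for r in aln.columns):
        logger.warning("REL: alignment has no variation; degenerate fit")
        zeros = np.zeros(aln.n_codons)
        table = SitePosteriorTable(
            "REL", np.array([0.0]), np.ones((aln.n_codons, 1)), zeros, zeros
        )
        return RELResult(
            np.ones(K_s), np.full(K_s, 1 / K_s), np.ones(K_n),
            np.full(K_n, 1 / K_n), 1.0, float("nan"), 1.0, table, False,
        )

    fit_kappa = kappa is None

    def unpack(x):
        i = 0
        s_raw = np.exp(x[i:i + K_s]); i += K_s
        sw = _stick(x[i:i + K_s - 1]); i += K_s - 1
        n_raw = np.exp(x[i:i + K_n]); i += K_n
        nw = _stick(x[i:i + K_n - 1]); i += K_n - 1
        kap = float(np.exp(x[i])) if fit_kappa else float(kappa)
        s = s_raw / (sw @ s_raw)  # E[syn rate] = 1
        return s, sw, n_raw, nw, kap

    def negloglik(x):
        s, sw, nr, nw, kap = unpack(x)
        syn = np.repeat(s, K_n)
        non = np.tile(nr, K_s)
        weights = np.repeat(sw, K_n) * np.tile(nw, K_s)
        mats = build_class_matrices(kap, non, weights, pi, syn_rates=syn)
        try:
            lnl = tl.log_likelihood(mats, weights, pi)
        except np.linalg.LinAlgError:
            return 1e10
        return -lnl if np.isfinite(lnl) else 1e10

    n_par = (2 * K_s - 1) + (2 * K_n - 1) + (1 if fit_kappa else 0)
    x0 = np.zeros(n_par)
    # spread starting categories
    x0[:K_s] = np.linspace(-1.0, 1.0, K_s)
    x0[2 * K_s - 1:2 * K_s - 1 + K_n] = np.linspace(-2.0, 1.0, K_n)
    if fit_kappa:
        x0[-1] = np.log(2.0)
    bounds = [(-10.0, 6.0)] * n_par
    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-9},
    )
    s, sw, nr, nw, kap = unpack(res.x)
    syn = np.repeat(s, K_n)
    non = np.tile(nr, K_s)
    weights = np.repeat(sw, K_n) * np.tile(nw, K_s)
    mats = build_class_matrices(kap, non, weights, pi, syn_rates=syn)
    lik, logscale = tl.site_class_likelihoods(mats, pi)
    m = logscale.max(axis=0)
    num = weights[:, None] * lik * np.exp(logscale - m)
    denom = num.sum(axis=0)
    denom[denom == 0] = 1.0
    post = (num / denom).T
    positive = non > syn * (1 + _POSITIVE_EPS)
    p_pos = post[:, positive].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        site_omega = post @ np.where(syn > 0, non / syn, np.inf)
    table = SitePosteriorTable("REL", non / syn, post, p_pos, site_omega)
    mean_omega = float(nw @ nr)  # E[syn] normalized to 1
    return RELResult(s, sw, nr, nw, kap, float(-res.fun), mean_omega,
                     table, bool(res.success))


def _stick(x) -> np.ndarray:
    """Stick-breaking map from R^{k-1} to the open k-simplex."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    w = []
    rest = 1.0
    for xi in x:
        f = _sigmoid(xi)
        w.append(rest * f)
        rest *= 1 - f
    w.append(rest)
    return np.array(w)
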