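"""Brownian-motion and Ornstein-Uhlenbeck trait models on phylogenies.

The OU process ``dX = alpha (theta - X) dt + sigma dW`` models stabilizing
selection toward an optimum ``theta``; in the multi-optimum (OUM) variants
``theta`` varies over the regimes painted on the tree by a
:class:`~ouregimes.regime_mapping.RegimeMap` while a single ``alpha`` and
``sigma^2`` are shared across regimes.  Likelihoods are exact multivariate-
normal densities built from the closed-form OU mean and covariance; the
general non-ultrametric form is used throughout so fossil tips need no
special casing, and polytomies are handled natively by the covariance
construction.

Multivariate models (on principal-component scores) use a diagonal
``alpha`` (one pull rate per dimension, shared across regimes), a full
symmetric positive-definite diffusion matrix ``sigma^2``, and per-regime
optimum vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from .phylo import Phylogeny
from .regime_mapping import RegimeMap

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelComparison",
    "ou_expected_mean",
    "ou_covariance",
    "bm_covariance",
    "ou_loglik",
    "bm_loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "half_life",
    "compare_models",
]

_LOG2PI = np.log(2.0 * np.pi)
_JITTERS = (0.0, 1e-12, 1e-10, 1e-8)


# ---------------------------------------------------------------- model spec

@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family BM / OU1 / OUM, regime painting, root convention.

    ``root_mode`` is ``"theta"`` (root value pinned to the root regime's
    optimum; OU default) or ``"free"`` (root state estimated by GLS; always
    used for BM).
    """

    family: str  # BM | OU1 | OUM
    scheme: str | None = None  # painting scheme name, OUM only (labelling)
    root_mode: str = "theta"

    def __post_init__(self):
        if self.family not in ("BM", "OU1", "OUM"):
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def name(self) -> str:
        if self.family == "OUM" and self.scheme:
            return f"OUM_{self.scheme}"
        return self.family


@dataclass
class FitResult:
    """One maximum-likelihood fit of a trait model.

    ``alpha`` is a scalar (univariate) or per-dimension array; ``sigma2`` a
    scalar or full matrix; ``theta`` maps regime label to optimum (scalar or
    d-vector).  ``half_lives`` is ``ln(2)/alpha`` per dimension.
    """

    spec: ModelSpec
    alpha: object
    sigma2: object
    theta: dict
    root_value: object
    log_likelihood: float
    k: int
    n: int
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)

    @property
    def half_lives(self) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        return np.array([half_life(x) if x > 0 else np.inf for x in a])

    def to_record(self) -> dict:
        sig = np.asarray(self.sigma2)
        return {
            "model": self.spec.name,
            "alpha": np.atleast_1d(np.asarray(self.alpha, float)).tolist(),
            "sigma2": sig.tolist() if sig.ndim else float(sig),
            "theta": {r: (np.asarray(v, float).tolist() if np.ndim(v) else float(v))
                      for r, v in self.theta.items()},
            "root_value": (np.asarray(self.root_value, float).tolist()
                           if np.ndim(self.root_value) else float(self.root_value)),
            "logL": float(self.log_likelihood),
            "k": self.k,
            "n": self.n,
            "AICc": float(self.aicc),
            "half_life": [float(h) for h in self.half_lives],
            "converged": self.converged,
            **self.meta,
        }


# ----------------------------------------------------- means and covariances

def ou_expected_mean(tree: Phylogeny, rmap: RegimeMap, alpha: float,
                     theta: dict, root_value: float) -> np.ndarray:
    """Expected tip values of a univariate OU with piecewise-constant optima.

    Each segment of the root-to-tip regime history contributes its optimum
    weighted by the OU decay over its residence interval; the root value
    carries the remaining weight ``exp(-alpha T)``.  ``alpha = 0`` returns
    the root value for every tip (the BM limit).
    """
    tips = tree.tips
    out = np.empty(len(tips))
    for a, t in enumerate(tips):
        T = tree.depths[t]
        if alpha == 0:
            out[a] = root_value
            continue
        val = root_value * np.exp(-alpha * T)
        for state, t0, t1 in rmap.tip_path_segments(int(t)):
            w = np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
            val += theta[state] * w
        out[a] = val
    return out


def bm_covariance(tree: Phylogeny, tmat: np.ndarray | None = None) -> np.ndarray:
    """Shared root-to-MRCA path time per tip pair (BM covariance at sigma2=1)."""
    return tree.mrca_depth_matrix() if tmat is None else tmat


def ou_covariance(tree: Phylogeny, alpha: float,
                  tmat: np.ndarray | None = None) -> np.ndarray:
    """OU tip covariance at ``sigma2 = 1`` for a non-random root.

    ``V_ij = exp(-alpha d_ij) (1 - exp(-2 alpha t_ij)) / (2 alpha)`` with
    ``t_ij`` the shared path time from the root and ``d_ij`` the tip-to-tip
    divergence time; valid for non-ultrametric trees and continuous in
    ``alpha`` down to the BM limit at 0.
    """
    t = bm_covariance(tree, tmat)
    if alpha == 0:
        return t.copy()
    T = np.diag(t)
    d = T[:, None] + T[None, :] - 2.0 * t
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)


def _chol_solve(V: np.ndarray, *rhs):
    """Cholesky factor + solves, climbing a jitter ladder on failure."""
    scale = float(np.mean(np.diag(V)))
    for j in _JITTERS:
        try:
            L = np.linalg.cholesky(V + j * scale * np.eye(len(V)))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError(
            "covariance matrix not positive definite after jitter ladder")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    sols = []
    for r in rhs:
        z = solve_triangular(L, r, lower=True)
        sols.append(solve_triangular(L.T, z, lower=False))
    return L, logdet, sols


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    r = y - mean
    _, logdet, (Vr,) = _chol_solve(V, r)
    return -0.5 * (len(y) * _LOG2PI + logdet + float(r @ Vr))


def ou_loglik(tree: Phylogeny, rmap: RegimeMap, traits: dict, alpha: float,
              sigma2: float, theta: dict, root_value: float) -> float:
    """Log-likelihood of tip values under a (multi-optimum) univariate OU."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    y = np.array([traits[lab] for lab in tree.tip_labels], dtype=float)
    mean = ou_expected_mean(tree, rmap, alpha, theta, root_value)
    V = sigma2 * ou_covariance(tree, alpha)
    return _mvn_loglik(y, mean, V)


def bm_loglik(tree: Phylogeny, traits: dict, sigma2: float,
              root_value: float) -> float:
    """Log-likelihood of tip values under univariate Brownian motion."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    y = np.array([traits[lab] for lab in tree.tip_labels], dtype=float)
    V = sigma2 * bm_covariance(tree)
    return _mvn_loglik(y, np.full(len(y), float(root_value)), V)


# ------------------------------------------------------ information criteria

def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 logL + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative support ``exp(-delta_i/2) / sum exp(-delta_j/2)``."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ``ln(2)/alpha`` (Myr); undefined for BM."""
    if alpha <= 0:
        raise ValueError("half-life requires alpha > 0 (BM has none)")
    return float(np.log(2.0) / alpha)


# ------------------------------------------------------------------- fitting

def _regime_weight_arrays(tree: Phylogeny, rmap: RegimeMap, regimes: tuple):
    """Per-regime segment tables for vectorized design-matrix evaluation."""
    tips = tree.tips
    T = tree.depths[tips]
    tables = {r: ([], [], []) for r in regimes}  # tip row, t0, t1
    for row, t in enumerate(tips):
        for state, t0, t1 in rmap.tip_path_segments(int(t)):
            rows, a0, a1 = tables[state]
            rows.append(row)
            a0.append(t0)
            a1.append(t1)
    out = {}
    for r, (rows, a0, a1) in tables.items():
        out[r] = (np.array(rows, dtype=int), np.array(a0), np.array(a1))
    return T, out


def _design_matrix(T, tables, regimes, alpha, root_regime, root_mode):
    """Tips x parameters OU mean design at pull rate ``alpha``."""
    n = len(T)
    W = np.zeros((n, len(regimes) + (1 if root_mode == "free" else 0)))
    if alpha == 0:
        # all weight collapses onto the root term
        if root_mode == "free":
            W[:, -1] = 1.0
        else:
            W[:, regimes.index(root_regime)] = 1.0
        return W
    for c, r in enumerate(regimes):
        rows, t0, t1 = tables[r]
        if len(rows) == 0:
            continue
        w = np.exp(-alpha * (T[rows] - t1)) - np.exp(-alpha * (T[rows] - t0))
        np.add.at(W[:, c], rows, w)
    root_w = np.exp(-alpha * T)
    if root_mode == "free":
        W[:, -1] = root_w
    else:
        W[:, regimes.index(root_regime)] += root_w
    return W


def _profile_gls(y, W, V0):
    """GLS coefficients and profiled sigma^2 / logL for V = sigma2 * V0."""
    n = len(y)
    _, logdet, (Vy, VW) = _chol_solve(V0, y, W)
    A = W.T @ VW
    b = W.T @ Vy
    beta = np.linalg.lstsq(A, b, rcond=None)[0]
    # at the GLS optimum, r' V0^-1 r = y' V0^-1 y - beta' b
    s2 = max((float(y @ Vy) - float(beta @ b)) / n, 1e-300)
    logL = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)
    return beta, s2, logL


def _fit_bm_univariate(tree, y):
    C = bm_covariance(tree)
    W = np.ones((len(y), 1))
    beta, s2, logL = _profile_gls(y, W, C)
    return float(beta[0]), s2, logL


def _fit_ou_univariate(tree, rmap, y, regimes, root_mode,
                       n_restarts=3, tmat=None):
    """Profile likelihood over alpha; theta and sigma2 by GLS given alpha."""
    if tmat is None:
        tmat = tree.mrca_depth_matrix()
    T, tables = _regime_weight_arrays(tree, rmap, regimes)
    root_regime = rmap.root_state

    def profile(log_alpha):
        a = float(np.exp(log_alpha))
        V0 = ou_covariance(tree, a, tmat)
        W = _design_matrix(T, tables, regimes, a, root_regime, root_mode)
        try:
            beta, s2, logL = _profile_gls(y, W, V0)
        except np.linalg.LinAlgError:
            return None, None, -np.inf
        return beta, s2, logL

    # pull rates from effectively-BM up to half-lives far below any branch
    height = tree.height
    lo, hi = np.log(1e-6), np.log(100.0 / max(height, 1e-9))
    # coarse grid, then bounded quasi-Newton polish from the best starts
    grid = np.linspace(lo, hi, 16)
    glogL = np.array([profile(g)[2] for g in grid])
    order = np.argsort(glogL)[::-1]
    best = (None, -np.inf, False)
    for s in order[:max(n_restarts, 1)]:
        res = minimize(lambda x: -profile(x[0])[2], x0=[grid[s]],
                       method="L-BFGS-B", bounds=[(lo, hi)],
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if -res.fun > best[1]:
            best = (float(res.x[0]), -res.fun, bool(res.success))
    log_alpha, logL, ok = best
    beta, s2, _ = profile(log_alpha)
    alpha = float(np.exp(log_alpha))
    theta = {r: float(beta[i]) for i, r in enumerate(regimes)}
    if root_mode == "free":
        root = float(beta[-1])
    else:
        root = theta[root_regime]
    at_bound = log_alpha <= lo + 1e-6 or log_alpha >= hi - 1e-6
    return alpha, s2, theta, root, logL, ok, at_bound


class UnivariateProfiler:
    """Repeated univariate OU fits on one (tree, map): cached factorizations.

    For parametric-bootstrap and power workloads thousands of datasets are
    refitted on the same covariance structure; this caches the Cholesky
    factor, design matrix, and normal equations at each point of a fixed
    log-alpha grid so a refit costs one triangular solve per grid point,
    followed by a single fresh polish evaluation at the parabolic
    refinement of the grid optimum.
    """

    def __init__(self, tree, rmap, regimes, root_mode: str = "theta",
                 grid_size: int = 32):
        from scipy.linalg import cho_factor, cho_solve
        self._cho_solve = cho_solve
        self.tree = tree
        self.rmap = rmap
        self.regimes = tuple(regimes)
        self.root_mode = root_mode
        self.tmat = tree.mrca_depth_matrix()
        self.T, self.tables = _regime_weight_arrays(tree, rmap, self.regimes)
        self.root_regime = rmap.root_state
        height = tree.height
        self.lo, self.hi = np.log(1e-6), np.log(100.0 / max(height, 1e-9))
        self.grid = np.linspace(self.lo, self.hi, grid_size)
        self._cache = []
        for g in self.grid:
            a = float(np.exp(g))
            V0 = ou_covariance(tree, a, self.tmat)
            L, logdet, _ = _chol_solve(V0)
            W = _design_matrix(self.T, self.tables, self.regimes, a,
                               self.root_regime, self.root_mode)
            Wsol = solve_triangular(L, W, lower=True)
            A = Wsol.T @ Wsol
            self._cache.append((a, L, logdet, W, Wsol, A))

    def _grid_eval(self, y):
        n = len(y)
        out = np.empty(len(self._cache))
        betas = []
        for i, (a, L, logdet, W, Wsol, A) in enumerate(self._cache):
            z = solve_triangular(L, y, lower=True)
            b = Wsol.T @ z
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
            s2 = max((float(z @ z) - float(beta @ b)) / n, 1e-300)
            out[i] = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)
            betas.append((beta, s2))
        return out, betas

    def _full_eval(self, log_alpha, y):
        a = float(np.exp(log_alpha))
        V0 = ou_covariance(self.tree, a, self.tmat)
        W = _design_matrix(self.T, self.tables, self.regimes, a,
                           self.root_regime, self.root_mode)
        beta, s2, logL = _profile_gls(y, W, V0)
        return a, beta, s2, logL

    def fit(self, y):
        """Returns (alpha, sigma2, theta dict, root value, logL)."""
        y = np.asarray(y, dtype=float)
        logLs, betas = self._grid_eval(y)
        j = int(np.argmax(logLs))
        best = (self._cache[j][0], *betas[j], logLs[j])
        if 0 < j < len(self.grid) - 1:
            # parabolic refinement in log-alpha
            x0, x1, x2 = self.grid[j - 1:j + 2]
            f0, f1, f2 = logLs[j - 1:j + 2]
            denom = (f0 - 2 * f1 + f2)
            if denom < 0:
                x_star = x1 - 0.5 * (x2 - x1) * (f2 - f0) / denom
                x_star = float(np.clip(x_star, x0, x2))
                a, beta, s2, logL = self._full_eval(x_star, y)
                if logL > best[3]:
                    best = (a, beta, s2, logL)
        alpha, beta, s2, logL = best
        theta = {r: float(beta[i]) for i, r in enumerate(self.regimes)}
        root = (float(beta[-1]) if self.root_mode == "free"
                else theta[self.root_regime])
        return alpha, s2, theta, root, logL


# ---- multivariate machinery

def _mv_cov_blocks(tmat, alphas, Sigma):
    """Stacked (n*d) covariance of a diagonal-alpha OU with diffusion Sigma.

    Ordering is dimension-major: entry (m*n + i) is tip i, dimension m.
    """
    n = tmat.shape[0]
    d = len(alphas)
    T = np.diag(tmat)
    Si = T[:, None] - tmat  # time from MRCA to tip i, per pair
    Sj = T[None, :] - tmat
    G = np.empty((n * d, n * d))
    for m in range(d):
        for l in range(m, d):
            am, al = alphas[m], alphas[l]
            s = am + al
            if s == 0:
                core = tmat * Sigma[m, l]
            else:
                core = (Sigma[m, l] *
                        np.exp(-am * Si) * np.exp(-al * Sj) *
                        (-np.expm1(-s * tmat)) / s)
            G[m * n:(m + 1) * n, l * n:(l + 1) * n] = core
            if l != m:
                G[l * n:(l + 1) * n, m * n:(m + 1) * n] = core.T
    return G


def _chol_from_params(p, d):
    """Lower-triangular Cholesky factor of Sigma from packed parameters."""
    L = np.zeros((d, d))
    L[np.diag_indices(d)] = np.exp(p[:d])
    if d > 1:
        L[np.tril_indices(d, -1)] = p[d:]
    return L


def _fit_mv_bm(tree, Y, tmat):
    """Closed-form ML for multivariate BM (GLS root per dim, Sigma profiled)."""
    n, d = Y.shape
    C = tmat
    one = np.ones((n, 1))
    _, logdetC, (CY, C1) = _chol_solve(C, Y, one)
    denom = float((one.T @ C1).item())
    root = (one.T @ CY).ravel() / denom
    R = Y - one @ root[None, :]
    _, _, (CR,) = _chol_solve(C, R)
    Sigma = (R.T @ CR) / n
    sign, logdetS = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular BM rate matrix estimate")
    logL = -0.5 * (n * d * _LOG2PI + d * logdetC + n * logdetS + n * d)
    return root, Sigma, logL


def _fit_mv_ou(tree, rmap, Y, regimes, root_mode, n_restarts=3, tmat=None,
               maxiter=400):
    """Diagonal-alpha, full-Sigma multivariate OU(M) by quasi-Newton ML."""
    n, d = Y.shape
    if tmat is None:
        tmat = tree.mrca_depth_matrix()
    T, tables = _regime_weight_arrays(tree, rmap, regimes)
    root_regime = rmap.root_state
    y = Y.T.ravel()  # dimension-major stacking
    r_idx = regimes.index(root_regime)
    ncol = len(regimes) + (1 if root_mode == "free" else 0)

    def unpack(p):
        alphas = np.exp(p[:d])
        L = _chol_from_params(p[d:], d)
        return alphas, L @ L.T

    def negll(p):
        alphas, Sigma = unpack(p)
        try:
            G = _mv_cov_blocks(tmat, alphas, Sigma)
            # block-diagonal design: per-dimension OU weights
            W = np.zeros((n * d, ncol * d))
            for m in range(d):
                Wm = _design_matrix(T, tables, regimes, alphas[m],
                                    root_regime, root_mode)
                W[m * n:(m + 1) * n, m * ncol:(m + 1) * ncol] = Wm
            _, logdet, (Gy, GW) = _chol_solve(G, y, W)
            A = W.T @ GW
            beta = np.linalg.lstsq(A, W.T @ Gy, rcond=None)[0]
            r = y - W @ beta
            _, _, (Gr,) = _chol_solve(G, r)
            logL = -0.5 * (n * d * _LOG2PI + logdet + float(r @ Gr))
            return -logL, beta
        except np.linalg.LinAlgError:
            return np.inf, None

    # starts: per-dimension univariate OU1 pulls + sample covariance scaling
    tip_var = Y.var(axis=0, ddof=0)
    height = tree.height
    base_alpha = np.log(np.full(d, 1.0 / height))
    S0 = np.cov(Y.T, ddof=0) if d > 1 else np.array([[tip_var[0]]])
    S0 = S0 / height + 1e-8 * np.eye(d)
    L0 = np.linalg.cholesky(S0)
    p0 = np.concatenate([base_alpha, np.log(np.diag(L0)),
                         L0[np.tril_indices(d, -1)]])
    rng = np.random.default_rng(12345)
    starts = [p0]
    for s in range(max(n_restarts - 1, 0)):
        jit = p0.copy()
        jit[:d] += rng.uniform(-2.5, 2.5, size=d)
        jit[d:2 * d] += rng.uniform(-1.0, 1.0, size=d)
        starts.append(jit)

    lo_a, hi_a = np.log(1e-6), np.log(100.0 / max(height, 1e-9))
    bounds = ([(lo_a, hi_a)] * d + [(-20.0, 20.0)] * d +
              [(None, None)] * (d * (d - 1) // 2))
    best = (None, np.inf, False)
    for p_start in starts:
        res = minimize(lambda p: negll(p)[0], x0=np.clip(p_start, -19, 19),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-11})
        if res.fun < best[1]:
            best = (res.x, res.fun, bool(res.success))
    p_hat, nll, ok = best
    alphas, Sigma = unpack(p_hat)
    _, beta = negll(p_hat)
    theta = {r: beta[np.arange(d) * ncol + i] for i, r in enumerate(regimes)}
    if root_mode == "free":
        root = beta[np.arange(d) * ncol + ncol - 1]
    else:
        root = theta[root_regime]
    return alphas, Sigma, theta, root, -nll, ok


def _count_params(spec: ModelSpec, d: int, n_regimes: int) -> int:
    extra_root = 1 if (spec.family != "BM" and spec.root_mode == "free") else 0
    if spec.family == "BM":
        return d * (d + 1) // 2 + d if d > 1 else 2
    if d == 1:
        base = 2  # alpha, sigma2
        th = 1 if spec.family == "OU1" else n_regimes
        return base + th + extra_root
    base = d + d * (d + 1) // 2
    th = d if spec.family == "OU1" else n_regimes * d
    return base + th + extra_root * d


def _traits_to_matrix(traits, labels):
    """Accepts dict/Series (univariate) or DataFrame / dict-of-vectors."""
    try:
        import pandas as pd
        if isinstance(traits, pd.DataFrame):
            return traits.loc[labels].to_numpy(dtype=float)
        if isinstance(traits, pd.Series):
            return traits.loc[labels].to_numpy(dtype=float)[:, None]
    except ImportError:  # pragma: no cover
        pass
    first = traits[labels[0]]
    if np.ndim(first) == 0:
        return np.array([[traits[l]] for l in labels], dtype=float)
    return np.array([np.asarray(traits[l], dtype=float) for l in labels])


def fit_model(tree: Phylogeny, maps, traits, spec: ModelSpec,
              n_restarts: int = 3) -> list:
    """Fit one model family on each supplied regime map; returns FitResults.

    ``traits`` maps species to a scalar (univariate) or to a d-vector /
    DataFrame row (multivariate PC scores).  BM and OU1 need no regime
    information but still produce one result per map for bookkeeping
    symmetry; OUM requires maps.
    """
    if isinstance(maps, RegimeMap):
        maps = [maps]
    if not maps:
        raise ValueError("at least one regime map (or the bare tree map) required")
    labels = tree.tip_labels
    try:
        import pandas as pd
        have = set(traits.index) if isinstance(traits, (pd.DataFrame, pd.Series)) \
            else set(traits)
    except ImportError:  # pragma: no cover
        have = set(traits)
    missing = [l for l in labels if l not in have]
    if missing:
        raise KeyError(f"traits missing for tips: {missing[:5]}")
    Y = _traits_to_matrix(traits, labels)
    n, d = Y.shape
    tmat = tree.mrca_depth_matrix()
    results = []
    for im, rmap in enumerate(maps):
        if spec.family == "OUM":
            regimes = tuple(sorted(set(s for segs in rmap.segments for s, _ in segs)))
            if len(regimes) < 2:
                raise ValueError("OUM requires >= 2 regimes on the map")
        else:
            regimes = ("__single__",)
        k = _count_params(spec, d, len(regimes))
        n_obs = n * d if d > 1 else n
        if spec.family == "BM":
            if d == 1:
                root, s2, logL = _fit_bm_univariate(tree, Y[:, 0])
                fr = FitResult(spec, 0.0, s2, {}, root, logL, k, n_obs)
            else:
                root, Sigma, logL = _fit_mv_bm(tree, Y, tmat)
                fr = FitResult(spec, np.zeros(d), Sigma, {}, root, logL, k, n_obs)
        else:
            use_map = rmap if spec.family == "OUM" else RegimeMap.constant(
                tree, "__single__")
            if d == 1:
                alpha, s2, theta, root, logL, ok, bound = _fit_ou_univariate(
                    tree, use_map, Y[:, 0], regimes, spec.root_mode,
                    n_restarts, tmat)
                if spec.family == "OU1":
                    theta = {"theta": theta["__single__"]}
                fr = FitResult(spec, alpha, s2, theta, root, logL, k, n_obs,
                               converged=ok, meta={"alpha_at_bound": bound})
            else:
                alphas, Sigma, theta, root, logL, ok = _fit_mv_ou(
                    tree, use_map, Y, regimes, spec.root_mode, n_restarts, tmat)
                if spec.family == "OU1":
                    theta = {"theta": theta["__single__"]}
                fr = FitResult(spec, alphas, Sigma, theta, root, logL, k, n_obs,
                               converged=ok)
        fr.meta["map_index"] = im
        results.append(fr)
    return results


# --------------------------------------------------------- model comparison

@dataclass
class ModelComparison:
    """AICc comparison of several model families over replicate maps/trees."""

    model_names: list
    aicc_matrix: np.ndarray  # replicates x models
    fits: list  # per replicate: list of FitResult per model

    @property
    def n_replicates(self) -> int:
        return self.aicc_matrix.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return np.vstack([akaike_weights(row) for row in self.aicc_matrix])

    @property
    def mean_weights(self) -> np.ndarray:
        return self.weights.mean(axis=0)

    @property
    def mean_aicc(self) -> np.ndarray:
        return self.aicc_matrix.mean(axis=0)

    @property
    def delta_aicc(self) -> np.ndarray:
        m = self.mean_aicc
        return m - m.min()

    @property
    def best_model(self) -> str:
        # ties broken toward fewer parameters
        d = self.delta_aicc
        ks = [self.fits[0][j].k for j in range(len(self.model_names))]
        order = sorted(range(len(d)), key=lambda j: (d[j], ks[j]))
        return self.model_names[order[0]]

    @property
    def supported(self) -> list:
        d = self.delta_aicc
        return [m for m, dd in zip(self.model_names, d) if dd < 2.0]

    def table(self):
        import pandas as pd
        return pd.DataFrame({
            "model": self.model_names,
            "mean_AICc": self.mean_aicc,
            "dAICc": self.delta_aicc,
            "mean_AICcW": self.mean_weights,
        })


def compare_models(trees, maps, traits, specs, n_restarts: int = 3) -> ModelComparison:
    """Fit every spec on every (tree, map) replicate and compare by AICc.

    ``trees`` may be a single tree (then ``maps`` is its map list) or a list
    of trees with ``maps[i]`` the map list of ``trees[i]``.
    """
    if isinstance(trees, Phylogeny):
        trees = [trees]
        maps = [maps if isinstance(maps, list) else [maps]]
    model_names = [s.name for s in specs]
    rows, all_fits = [], []
    for tree, tree_maps in zip(trees, maps):
        if isinstance(tree_maps, RegimeMap):
            tree_maps = [tree_maps]
        for rmap in tree_maps:
            fits = [fit_model(tree, [rmap], traits, s, n_restarts)[0] for s in specs]
            rows.append([f.aicc for f in fits])
            all_fits.append(fits)
    return ModelComparison(model_names, np.array(rows), all_fits)
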