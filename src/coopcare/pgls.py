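"""GLS regression with Pagel's lambda and data-quality variance components.

The residual covariance is

    V(lambda, gamma) = sigma^2 * ( C_lambda + sum_k gamma_k D_k )

where C_lambda is the phylogenetic correlation matrix with its off-diagonal
scaled by lambda, D_k is the diagonal indicator of ordinal data-quality
class k (1 weak .. 3 strong), and gamma_k >= 0 is the extra residual
variance of class k expressed as a ratio to the phylogenetic scale
sigma^2 ("scaled to phylogeny"). beta and sigma^2 are profiled out in
closed form; (lambda, gamma) are estimated by bounded maximum likelihood
with multiple starts, since the likelihood can be ridge-shaped when the
lambda estimate sits at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .phylo import PhyloCov, Phylogeny, lambda_transform, vcv

__all__ = [
    "PGLSVCModel",
    "PGLSVCFit",
    "GLSResult",
    "FitOptions",
    "EnsembleFit",
    "build_covariance",
    "gls_estimate",
    "fit_ml",
    "r_squared",
    "ensemble_fit",
]

logger = logging.getLogger(__name__)

QUALITY_CLASSES = (1, 2, 3)


@dataclass
class PGLSVCModel:
    """Response, design, phylogenetic correlation and quality labels."""

    y: np.ndarray
    X: np.ndarray
    C: PhyloCov
    quality: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.quality = np.asarray(self.quality, dtype=int).ravel()
        n = self.y.size
        if self.X.shape[0] != n or self.C.C.shape != (n, n) or self.quality.size != n:
            raise ValueError(
                f"inconsistent dimensions: y={n}, X={self.X.shape}, "
                f"C={self.C.C.shape}, quality={self.quality.size}")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        bad = set(self.quality) - set(QUALITY_CLASSES)
        if bad:
            raise ValueError(f"unknown quality classes {sorted(bad)}; expected 1, 2 or 3")
        if self.names is None:
            self.names = tuple(f"x{j}" for j in range(self.X.shape[1]))


@dataclass
class GLSResult:
    beta: np.ndarray
    se: np.ndarray
    sigma2_ml: float          # RSS / n, the ML profile scale
    sigma2_df: float          # RSS / (n - p), used for coefficient SEs
    loglik: float
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1
    rss: float


@dataclass
class FitOptions:
    """Knobs of the variance-component optimization and inference.

    ``criterion`` selects the estimation criterion for (lambda, gamma):
    REML (default) has much smaller small-sample bias in the variance
    components than ML and is what the coefficient inference is calibrated
    under; ML is available for likelihood comparisons. ``adjust_se="kr"``
    applies a Kenward-Roger-type correction that propagates the sampling
    uncertainty of the variance parameters into the coefficient standard
    errors (components pinned at a bound are treated as fixed).
    """

    criterion: str = "reml"        # "reml" or "ml"
    n_starts: int = 8
    gamma_max: float = 1e4
    compute_r2: bool = True
    seed: int | None = None
    extra_random_starts: int = 0   # drawn uniformly in the box, seeded
    adjust_se: str = "kr"          # "kr" or "none"


@dataclass
class PGLSVCFit:
    """A fitted lambda + quality-variance-component GLS model."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_values: np.ndarray
    lam: float
    sigma2: float
    gamma: dict[int, float]
    gamma_se: dict[int, float]
    lam_se: float
    loglik: float
    r2: float | None
    df_resid: int
    boundary_flags: dict[str, bool]
    names: tuple[str, ...]
    n: int
    criterion: str = "ml"
    converged: bool = True

    def summary_rows(self) -> list[dict]:
        rows = []
        for j, name in enumerate(self.names):
            rows.append({"term": name, "coef": float(self.beta[j]),
                         "se": float(self.se[j]), "t": float(self.t[j]),
                         "p": float(self.p_values[j])})
        return rows


def build_covariance(C: PhyloCov, lam: float, gamma, quality) -> np.ndarray:
    """V0 = C_lambda + sum_k gamma_k D_k (overall sigma^2 multiplies V0)."""
    quality = np.asarray(quality, dtype=int).ravel()
    if isinstance(gamma, dict):
        gamma = {int(k): float(g) for k, g in gamma.items()}
    elif np.ndim(gamma) == 0:
        gamma = {k: float(gamma) for k in QUALITY_CLASSES}
    else:
        gamma = dict(zip(QUALITY_CLASSES, np.asarray(gamma, dtype=float)))
    for k, g in gamma.items():
        if g < 0:
            raise ValueError(f"gamma for quality class {k} is negative ({g})")
    V = lambda_transform(C, lam).C.copy()
    d = np.array([gamma.get(int(q), 0.0) for q in quality])
    V[np.diag_indices_from(V)] += d
    return V


def _chol(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, with a single jittered retry on failure."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(V)))
        logger.warning("covariance factorization failed; retrying with jitter %g", jitter)
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            ev = float(np.linalg.eigvalsh(V).min())
            raise linalg.LinAlgError(
                f"covariance not positive definite (smallest eigenvalue {ev:.3e})"
            ) from exc


def gls_estimate(y, X, V, criterion: str = "ml") -> GLSResult:
    """Closed-form GLS via triangular whitening (no explicit inverse).

    beta = (X'V^-1X)^-1 X'V^-1 y with the scale sigma^2 profiled out:
    the ML scale is RSS/n and enters the Gaussian log-likelihood; the
    coefficient SEs use the degrees-of-freedom scale RSS/(n-p), matching
    standard phylogenetic-regression reporting with t-tests on n-p df.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    L = _chol(np.asarray(V, dtype=float))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError("whitened design is rank deficient")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    xtvix = Xw.T @ Xw
    cov_unscaled = linalg.cho_solve(linalg.cho_factor(xtvix), np.eye(p))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    sigma2_df = rss / (n - p) if n > p else np.nan
    if criterion == "reml":
        sign, logdet_xtvix = np.linalg.slogdet(xtvix)
        m = n - p
        loglik = -0.5 * (m * (np.log(2 * np.pi) + np.log(rss / m) + 1.0)
                         + logdetV + logdet_xtvix)
        scale = rss / m
    else:
        loglik = -0.5 * (n * (np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0) + logdetV)
        scale = sigma2_df
    se = np.sqrt(scale * np.diag(cov_unscaled))
    return GLSResult(beta=beta, se=se, sigma2_ml=sigma2_ml, sigma2_df=sigma2_df,
                     loglik=float(loglik), cov_unscaled=cov_unscaled, rss=rss)


# ---------------------------------------------------------------------------
# ML fitting over (lambda, gamma)
# ---------------------------------------------------------------------------

def _profile_loglik(model: PGLSVCModel, lam: float, gamma_vec: np.ndarray,
                    free_classes: Sequence[int], criterion: str) -> float:
    gamma = {k: 0.0 for k in QUALITY_CLASSES}
    for k, g in zip(free_classes, gamma_vec):
        gamma[k] = float(g)
    try:
        V0 = build_covariance(model.C, lam, gamma, model.quality)
        return gls_estimate(model.y, model.X, V0, criterion=criterion).loglik
    except (linalg.LinAlgError, ValueError):
        return -np.inf


def _make_fast_loglik(model: PGLSVCModel, free_classes: Sequence[int],
                      criterion: str):
    """Profiled log-likelihood of (lambda, gamma) with precomputed pieces.

    Same value as going through build_covariance + gls_estimate, but avoids
    per-evaluation container construction; used only inside the optimizer.
    """
    C = model.C.C
    diag = C.diagonal().copy()
    Coff = C - np.diag(diag)
    masks = [model.quality == k for k in free_classes]
    X, y = model.X, model.y
    n, p = X.shape
    const = np.log(2 * np.pi)

    def loglik(lam: float, gvec: np.ndarray) -> float:
        V = lam * Coff
        d = diag.copy()
        for mask, g in zip(masks, gvec):
            d[mask] += g
        V[np.diag_indices(n)] = d
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf
        yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
        Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
        xtx = Xw.T @ Xw
        try:
            cf = linalg.cho_factor(xtx, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        beta = linalg.cho_solve(cf, Xw.T @ yw, check_finite=False)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        if rss <= 0:
            return -np.inf
        logdetV = 2.0 * float(np.log(np.diag(L)).sum())
        if criterion == "reml":
            m = n - p
            logdet_xtx = 2.0 * float(np.log(np.diag(cf[0])).sum())
            return -0.5 * (m * (const + np.log(rss / m) + 1.0) + logdetV + logdet_xtx)
        return -0.5 * (n * (const + np.log(rss / n) + 1.0) + logdetV)

    return loglik


def _default_starts(n_free: int) -> list[np.ndarray]:
    """Deterministic starts: corners and centre of the (lambda, gamma) box."""
    base = [
        [1.0] + [0.0] * n_free,
        [0.0] + [0.0] * n_free,
        [0.5] + [1.0] * n_free,
        [1.0] + [5.0] * n_free,
        [0.5] + [0.1] * n_free,
        [1.0] + ([25.0, 0.5, 0.5][:n_free] + [0.5] * max(0, n_free - 3)),
        [0.25] + [10.0] * n_free,
        [0.9] + [2.0] * n_free,
    ]
    return [np.asarray(s, dtype=float) for s in base]


def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                       steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of f at x."""
    k = x.size
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            hi, hj = steps[i], steps[j]
            if i == j:
                fp = f(x + hi * _e(k, i))
                fm = f(x - hi * _e(k, i))
                H[i, i] = (fp - 2 * f0 + fm) / hi**2
            else:
                fpp = f(x + hi * _e(k, i) + hj * _e(k, j))
                fpm = f(x + hi * _e(k, i) - hj * _e(k, j))
                fmp = f(x - hi * _e(k, i) + hj * _e(k, j))
                fmm = f(x - hi * _e(k, i) - hj * _e(k, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    return H


def _e(k: int, i: int) -> np.ndarray:
    v = np.zeros(k)
    v[i] = 1.0
    return v


def _kr_adjusted_cov(V: np.ndarray, X: np.ndarray, Gs: list[np.ndarray]) -> np.ndarray:
    """Kenward-Roger-type adjusted coefficient covariance.

    ``V`` is the full fitted residual covariance and ``Gs`` spans the free
    directions of its linear structure (off-diagonal phylogenetic scale,
    per-quality diagonal components). The REML information of those
    components gives their sampling covariance W, which inflates the naive
    (X'V^-1X)^-1 by the usual 2*Phi*[sum W_ij (Q_ij - P_i Phi P_j)]*Phi
    term. Uncertainty in the overall scale is left to the t reference
    distribution on n - p degrees of freedom.
    """
    n, p = X.shape
    Vinv = linalg.cho_solve(linalg.cho_factor(V), np.eye(n))
    XtVi = X.T @ Vinv
    Phi = linalg.inv(XtVi @ X)
    if not Gs:
        return Phi
    Pmat = Vinv - XtVi.T @ Phi @ XtVi
    r = len(Gs)
    PG = [Pmat @ G for G in Gs]
    info = 0.5 * np.array([[np.sum(PG[i] * PG[j].T) for j in range(r)]
                           for i in range(r)])
    W = np.linalg.pinv(info, rcond=1e-10)
    Pr = [XtVi @ G @ XtVi.T for G in Gs]
    M = np.zeros((p, p))
    for i in range(r):
        GiVi = Gs[i] @ Vinv
        for j in range(r):
            Q = XtVi @ GiVi @ Gs[j] @ XtVi.T
            M += W[i, j] * (Q - Pr[i] @ Phi @ Pr[j])
    adj = Phi + 2.0 * Phi @ M @ Phi
    # guard: the adjustment must not produce a non-PSD covariance
    if np.any(np.diag(adj) <= 0):
        return Phi
    return adj


def fit_ml(model: PGLSVCModel, options: FitOptions | None = None,
           free_lambda: bool = True, free_gamma: bool = True,
           fixed_lambda: float = 1.0) -> PGLSVCFit:
    """Maximize the profiled likelihood over (lambda, gamma_k).

    gamma parameters exist only for quality classes present in the data;
    absent classes are fixed at zero. Multi-start bounded optimization
    (derivative-free Powell, then an L-BFGS-B polish) guards against the
    boundary ridge at lambda = 1. Variance-parameter SEs come from a
    central-difference Hessian at the optimum; a parameter at its bound is
    flagged and reported with SE 0 (boundary-degenerate), which is how a
    lambda estimate of exactly 1 appears as "1.00 +/- 0.00".
    """
    opts = options or FitOptions()
    n, p = model.X.shape
    present = sorted(set(model.quality.tolist()))
    free_classes = list(present) if free_gamma else []
    n_free_gamma = len(free_classes)
    n_var = (1 if free_lambda else 0) + n_free_gamma
    if n <= p + n_var:
        if n_free_gamma and min(np.bincount(model.quality)[1:][np.array(present) - 1]) <= 1:
            raise ValueError(
                "quality variance components are not estimable: a quality class "
                "contains a single species and n <= p + number of variance parameters")
        raise ValueError(f"too few observations (n={n}) for p={p} coefficients "
                         f"and {n_var} variance parameters")

    def unpack(theta: np.ndarray) -> tuple[float, np.ndarray]:
        if free_lambda:
            return float(theta[0]), theta[1:]
        return fixed_lambda, theta

    fast_ll = _make_fast_loglik(model, free_classes, opts.criterion)

    def negloglik(theta: np.ndarray) -> float:
        lam, gvec = unpack(theta)
        lam = min(max(lam, 0.0), 1.0)
        gvec = np.clip(gvec, 0.0, opts.gamma_max)
        ll = fast_ll(lam, gvec)
        return 1e10 if not np.isfinite(ll) else -ll

    # the optimizer works with gamma on a log1p scale so that steps in a
    # gamma of order 100 and in lambda within [0, 1] are commensurate
    def to_opt(theta: np.ndarray) -> np.ndarray:
        out = np.asarray(theta, dtype=float).copy()
        off = 1 if free_lambda else 0
        out[off:] = np.log1p(out[off:])
        return out

    def from_opt(theta_t: np.ndarray) -> np.ndarray:
        out = np.asarray(theta_t, dtype=float).copy()
        off = 1 if free_lambda else 0
        out[off:] = np.expm1(out[off:])
        return out

    def negloglik_t(theta_t: np.ndarray) -> float:
        return negloglik(from_opt(theta_t))

    bounds = ([(0.0, 1.0)] if free_lambda else []) + [(0.0, opts.gamma_max)] * n_free_gamma

    if n_var == 0:
        lam, gvec = (fixed_lambda, np.zeros(0))
        best_theta, best_nll = np.zeros(0), negloglik(np.zeros(0))
        converged = True
    else:
        starts = _default_starts(n_free_gamma)[:max(1, opts.n_starts)]
        if not free_lambda:
            starts = [s[1:] for s in starts]
        # de-duplicate starts after slicing
        uniq, seen = [], set()
        for s in starts:
            key = tuple(np.round(s, 6))
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        starts = uniq
        if opts.extra_random_starts:
            rng = np.random.default_rng(opts.seed)
            lo = np.array([b[0] for b in bounds])
            hi = np.array([min(b[1], 50.0) for b in bounds])
            starts += [lo + rng.random(n_var) * (hi - lo)
                       for _ in range(opts.extra_random_starts)]
        bounds_t = ([(0.0, 1.0)] if free_lambda else []) + \
            [(0.0, float(np.log1p(opts.gamma_max)))] * n_free_gamma
        best_t, best_nll, converged = None, np.inf, False
        for s in starts:
            try:
                res = optimize.minimize(negloglik_t, to_opt(s), method="L-BFGS-B",
                                        bounds=bounds_t)
            except Exception:  # pragma: no cover - defensive
                continue
            if res.fun < best_nll:
                best_nll, best_t = float(res.fun), np.asarray(res.x, dtype=float)
                converged = True
        if best_t is None:
            raise RuntimeError("variance-component optimization failed from every start")
        # derivative-free polish from the best point: guards against a
        # quasi-Newton stall on the likelihood ridge near the lambda bound
        try:
            res = optimize.minimize(negloglik_t, best_t, method="Powell",
                                    bounds=bounds_t,
                                    options={"xtol": 1e-8, "ftol": 1e-11,
                                             "maxiter": 2000})
            if res.fun < best_nll:
                best_nll, best_t = float(res.fun), np.asarray(res.x, dtype=float)
        except Exception:  # pragma: no cover - defensive
            pass
        best_theta = from_opt(best_t)

    lam, gvec = unpack(best_theta) if n_var else (fixed_lambda, np.zeros(0))
    lam = min(max(lam, 0.0), 1.0)
    gvec = np.clip(gvec, 0.0, opts.gamma_max)
    if free_lambda and free_gamma and n_free_gamma and 1e-8 < lam < 1.0:
        # With a free variance ratio for every quality class, lambda is
        # confounded with the overall scale: rescaling the covariance by
        # 1/lambda maps (lambda, gamma, sigma^2) to the identical-V
        # representative (1, (1+gamma)/lambda - 1, sigma^2 * lambda). The
        # likelihood is exactly flat along this ridge, so estimates are
        # reported in the canonical "scaled to phylogeny" form lambda = 1.
        gvec = np.clip((1.0 + gvec) / lam - 1.0, 0.0, opts.gamma_max)
        lam = 1.0
    gamma = {k: 0.0 for k in QUALITY_CLASSES}
    for k, g in zip(free_classes, gvec):
        gamma[k] = float(g)

    V0 = build_covariance(model.C, lam, gamma, model.quality)
    gls = gls_estimate(model.y, model.X, V0, criterion=opts.criterion)
    df = n - p
    se = gls.se
    if opts.adjust_se == "kr" and n_var > 0:
        Cmat = model.C.C
        Gs: list[np.ndarray] = []
        if free_lambda and lam > 1e-6:
            Gs.append(Cmat - np.diag(Cmat.diagonal()))
        if free_gamma:
            for k in free_classes:
                if gamma[k] > 1e-8:
                    Gs.append(np.diag((model.quality == k).astype(float)))
        if Gs:
            try:
                adj = _kr_adjusted_cov(gls.sigma2_df * V0, model.X, Gs)
                se = np.sqrt(np.diag(adj))
            except linalg.LinAlgError:  # pragma: no cover - defensive
                logger.warning("small-sample SE adjustment failed; using naive SEs")
    tvals = gls.beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    # variance-parameter SEs from the observed information; bounds -> SE 0 + flag
    tol_b = 1e-6
    boundary = {}
    if free_lambda:
        boundary["lambda"] = lam <= tol_b or lam >= 1.0 - tol_b
    for k, g in zip(free_classes, gvec):
        boundary[f"gamma_{k}"] = g <= 1e-8
    lam_se = 0.0
    gamma_se = {k: 0.0 for k in QUALITY_CLASSES}
    if n_var:
        names_var = (["lambda"] if free_lambda else []) + [f"gamma_{k}" for k in free_classes]
        interior = [i for i, nm in enumerate(names_var) if not boundary.get(nm, False)]
        if interior:
            theta0 = best_theta.copy()
            sub = np.array(interior)

            def f_sub(v: np.ndarray) -> float:
                th = theta0.copy()
                th[sub] = v
                return negloglik(th)

            steps = np.maximum(1e-4, 1e-4 * np.abs(theta0[sub]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = _numerical_hessian(f_sub, theta0[sub], steps)
            try:
                cov = linalg.inv(H)
                ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
            except linalg.LinAlgError:
                ses = np.full(len(interior), np.nan)
            for idx, se_v in zip(interior, ses):
                nm = names_var[idx]
                if nm == "lambda":
                    lam_se = float(se_v)
                else:
                    gamma_se[int(nm.split("_")[1])] = float(se_v)

    fit = PGLSVCFit(
        beta=gls.beta, se=se, t=tvals, p_values=pvals, lam=lam,
        sigma2=gls.sigma2_ml, gamma=gamma, gamma_se=gamma_se, lam_se=lam_se,
        loglik=gls.loglik, r2=None, df_resid=df, boundary_flags=boundary,
        names=model.names, n=n, criterion=opts.criterion, converged=converged)

    if opts.compute_r2 and p > 1:
        # the likelihood-ratio R^2 needs comparable likelihoods across
        # different fixed effects, so it is always based on ML fits
        null_model = PGLSVCModel(y=model.y, X=np.ones((n, 1)), C=model.C,
                                 quality=model.quality, names=("intercept",))
        sub_opts = FitOptions(criterion="ml", n_starts=opts.n_starts,
                              gamma_max=opts.gamma_max, compute_r2=False,
                              seed=opts.seed, adjust_se="none")
        full_ml = fit if opts.criterion == "ml" else fit_ml(
            model, sub_opts, free_lambda=free_lambda, free_gamma=free_gamma,
            fixed_lambda=fixed_lambda)
        null_ml = fit_ml(null_model, sub_opts, free_lambda=free_lambda,
                         free_gamma=free_gamma, fixed_lambda=fixed_lambda)
        fit.r2 = r_squared(full_ml, null_ml)
    return fit


def r_squared(fit: PGLSVCFit, null_fit: PGLSVCFit) -> float:
    """Likelihood-ratio R^2 = 1 - exp((2/n)(l0 - l1)), clipped to [0, 1].

    Reduces to the classical R^2 under OLS (V = I). The null fit must be
    the intercept-only model with the covariance structure re-estimated.
    """
    if fit.n != null_fit.n:
        raise ValueError("fits computed on different sample sizes")
    l1, l0 = fit.loglik, null_fit.loglik
    if l1 < l0 - 1e-6:
        raise ValueError(
            f"full-model log-likelihood {l1:.6f} below null {l0:.6f}; nesting violated")
    return float(np.clip(1.0 - np.exp(2.0 / fit.n * (l0 - l1)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Tree ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleFit:
    """Per-tree fits plus their across-tree aggregate."""

    fits: list[PGLSVCFit]
    failures: list[tuple[int, str]]
    aggregate: dict
    aggregation: str = "mean"

    @property
    def n_trees(self) -> int:
        return len(self.fits) + len(self.failures)


def _aggregate(fits: list[PGLSVCFit], how: str) -> dict:
    reduce = {"mean": np.mean, "median": np.median}[how]
    stack = lambda attr: np.array([getattr(f, attr) for f in fits])  # noqa: E731
    beta, se, t, pv = stack("beta"), stack("se"), stack("t"), stack("p_values")
    lam = np.array([f.lam for f in fits])
    gam = np.array([[f.gamma[k] for k in QUALITY_CLASSES] for f in fits])
    gam_se = np.array([[f.gamma_se[k] for k in QUALITY_CLASSES] for f in fits])
    out = {
        "names": list(fits[0].names),
        "beta": reduce(beta, axis=0).tolist(),
        "beta_sd_across_trees": beta.std(axis=0, ddof=0).tolist(),
        "se": reduce(se, axis=0).tolist(),
        "t": reduce(t, axis=0).tolist(),
        "p_values": reduce(pv, axis=0).tolist(),
        "lambda": float(reduce(lam)),
        "lambda_sd_across_trees": float(lam.std(ddof=0)),
        "lambda_se": float(reduce(np.array([f.lam_se for f in fits]))),
        "gamma": {str(k): float(v) for k, v in zip(QUALITY_CLASSES, reduce(gam, axis=0))},
        "gamma_sd_across_trees": {str(k): float(v) for k, v in
                                  zip(QUALITY_CLASSES, gam.std(axis=0, ddof=0))},
        "gamma_se": {str(k): float(v) for k, v in
                     zip(QUALITY_CLASSES, reduce(gam_se, axis=0))},
        "sigma2": float(reduce(np.array([f.sigma2 for f in fits]))),
        "loglik": float(reduce(np.array([f.loglik for f in fits]))),
        "n_species": fits[0].n,
    }
    r2s = [f.r2 for f in fits if f.r2 is not None]
    out["r2"] = float(reduce(np.array(r2s))) if r2s else None
    return out


def ensemble_fit(model_builder: Callable[[Phylogeny], PGLSVCModel],
                 trees: Sequence[Phylogeny],
                 options: FitOptions | None = None,
                 aggregation: str = "mean",
                 **fit_kwargs) -> EnsembleFit:
    """Fit the model on every tree and aggregate estimates across trees.

    ``model_builder`` maps a tree to a PGLSVCModel (typically by building
    the tree's covariance for a fixed species order). Single-tree failures
    are logged and skipped; if every tree fails, the last error is raised.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    if aggregation not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    fits: list[PGLSVCFit] = []
    failures: list[tuple[int, str]] = []
    last_exc: Exception | None = None
    for i, tree in enumerate(trees):
        try:
            fits.append(fit_ml(model_builder(tree), options, **fit_kwargs))
        except Exception as exc:
            logger.warning("tree %d failed: %s", i, exc)
            failures.append((i, str(exc)))
            last_exc = exc
    if not fits:
        raise RuntimeError(f"all {len(trees)} trees failed to fit") from last_exc
    return EnsembleFit(fits=fits, failures=failures,
                       aggregate=_aggregate(fits, aggregation),
                       aggregation=aggregation)
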