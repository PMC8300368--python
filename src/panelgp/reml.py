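"""REML variance components for the animal model, statsmodels-style.

:class:`AdditiveVarianceModel` fits y = Xb + a + e with a ~ N(0, sigma2_a G)
and e ~ N(0, sigma2_e I) by restricted maximum likelihood.  The restricted
likelihood is evaluated on the eigen-rotated error contrasts (one
eigendecomposition of S G S with S the fixed-effect projector, then every
iteration is O(n)); fitting warm-starts with EM — whose restricted
log-likelihood is provably non-decreasing — and switches to average-
information (AI) Newton updates, falling back to EM whenever an AI step
leaves the feasible region or lowers the likelihood.

:class:`BivariateAdditiveModel` fits the two-trait animal model with
unstructured 2x2 genetic and residual covariance matrices by direct
maximization of the restricted likelihood (log-Cholesky parameterization,
so both matrices stay positive definite) on G's eigenbasis, and reports the
genetic correlation r_G = cov_G12 / sqrt(sigma2_G1 sigma2_G2) and the
phenotypic correlation r_P = cov_P12 / sqrt(sigma2_P1 sigma2_P2) with
cov_P = cov_G + cov_E.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .grm import GRM

__all__ = ["AdditiveVarianceModel", "VarianceComponentsResults",
           "BivariateAdditiveModel", "BivariateResults"]

_LOG2PI = np.log(2.0 * np.pi)


def _as_matrix(grm) -> np.ndarray:
    return grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)


def clean_design(X: np.ndarray) -> np.ndarray:
    """Drop fixed-effect columns that became degenerate after row subsetting.

    Subsetting to a training window can zero out dummy columns (the dummies
    of validation-only levels) or make a dummy block collinear with the
    intercept (when the reference level is absent).  Columns are kept
    greedily in order as long as each adds rank; a design that was full
    rank stays untouched.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    Q = np.zeros((n, 0))
    keep = []
    for j in range(X.shape[1]):
        x = X[:, j]
        r = x - Q @ (Q.T @ x)
        norm = np.linalg.norm(r)
        if norm > 1e-8 * max(np.linalg.norm(x), 1.0):
            keep.append(j)
            Q = np.column_stack([Q, r / norm])
    return X[:, keep]


@dataclass
class VarianceComponentsResults:
    """Univariate REML estimates and diagnostics."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    se_sigma2_a: float
    se_sigma2_e: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    em_loglik_path: np.ndarray = field(repr=False, default=None)
    model: "AdditiveVarianceModel" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Additive variance model (REML)",
            "=" * 46,
            f"{'sigma2_a':<14}{self.sigma2_a:>12.6g}  (SE {self.se_sigma2_a:.3g})",
            f"{'sigma2_e':<14}{self.sigma2_e:>12.6g}  (SE {self.se_sigma2_e:.3g})",
            f"{'h2':<14}{self.h2:>12.4f}  (SE {self.se_h2:.3g})",
            f"{'log-lik':<14}{self.loglik:>12.4f}",
            f"{'converged':<14}{str(self.converged):>12}  ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


class AdditiveVarianceModel:
    """Single-trait animal model y = Xb + a + e, a ~ N(0, sigma2_a G)."""

    def __init__(self, y, X, grm):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            X = X.T
        G = _as_matrix(grm)
        ok = np.isfinite(y)
        y, X, G = y[ok], clean_design(X[ok]), G[np.ix_(ok, ok)]
        n, p = X.shape
        if n < 30:
            raise ValueError(f"need >= 30 observations with phenotype, got {n}")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design is rank deficient")
        self.y, self.X, self.G = y, X, G
        self.n, self.p = n, p
        # error contrasts: K spans the orthogonal complement of col(X), so
        # K'y ~ N(0, sigma2_a K'GK + sigma2_e I) regardless of b
        Q_full, _ = np.linalg.qr(X, mode="complete")
        K = Q_full[:, p:]
        KGK = K.T @ G @ K
        vals, vecs = np.linalg.eigh((KGK + KGK.T) / 2.0)
        self.xi = np.maximum(vals, 0.0)
        self.eta = vecs.T @ (K.T @ y)

    # -- restricted log-likelihood and derivatives on the diagonal spectrum --
    def _loglik(self, sa, se):
        v = sa * self.xi + se
        if (v <= 0).any():
            return -np.inf
        return -0.5 * (np.log(v).sum() + (self.eta ** 2 / v).sum()
                       + (self.n - self.p) * _LOG2PI)

    def _em_step(self, sa, se):
        xi, eta = self.xi, self.eta
        v = sa * xi + se
        ahat = sa * xi * eta / v
        cond_var = sa * xi * se / v
        pos = xi > 1e-12
        if not pos.any():           # degenerate G: no additive signal possible
            return sa, ((eta - ahat) ** 2 + cond_var).sum() / len(xi)
        sa_new = ((ahat[pos] ** 2 + cond_var[pos]) / xi[pos]).sum() / pos.sum()
        se_new = ((eta - ahat) ** 2 + cond_var).sum() / len(xi)
        return sa_new, se_new

    def _score_ai(self, sa, se):
        xi, eta = self.xi, self.eta
        v = sa * xi + se
        w = eta ** 2 / v ** 2
        score = np.array([-0.5 * ((xi / v).sum() - (xi * w).sum()),
                          -0.5 * ((1.0 / v).sum() - w.sum())])
        q = eta ** 2 / v ** 3
        ai = 0.5 * np.array([[(xi ** 2 * q).sum(), (xi * q).sum()],
                             [(xi * q).sum(), q.sum()]])
        return score, ai

    def fit(self, max_iter: int = 200, tol: float = 1e-8,
            n_em_warmup: int = 10) -> VarianceComponentsResults:
        var_y = float(np.var(self.eta)) or 1.0
        floor = 1e-8 * var_y
        sa = se = var_y / 2.0
        prev = (sa, se)
        ll = self._loglik(sa, se)
        em_path = [ll]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            if it <= n_em_warmup:
                sa, se = self._em_step(sa, se)
                sa, se = max(sa, floor), max(se, floor)
                ll_new = self._loglik(sa, se)
                em_path.append(ll_new)
            else:
                score, ai = self._score_ai(sa, se)
                try:
                    step = np.linalg.solve(ai, score)
                except np.linalg.LinAlgError:
                    step = None
                took_ai = False
                if step is not None:
                    # project infeasible updates onto the non-negativity
                    # floor; halve the step while it lowers the likelihood
                    for halving in range(6):
                        cand = np.maximum(
                            np.array([sa, se]) + step / 2 ** halving, floor)
                        ll_cand = self._loglik(*cand)
                        if ll_cand >= ll - 1e-12:
                            sa, se = cand
                            ll_new = ll_cand
                            took_ai = True
                            break
                if not took_ai:
                    sa, se = self._em_step(sa, se)
                    sa, se = max(sa, floor), max(se, floor)
                    ll_new = self._loglik(sa, se)
            param_change = abs(sa - prev[0]) + abs(se - prev[1])
            prev = (sa, se)
            if abs(ll_new - ll) < tol or param_change < 1e-10 * var_y:
                ll = ll_new
                converged = True
                break
            ll = ll_new

        _, ai = self._score_ai(sa, se)
        try:
            cov = np.linalg.inv(ai)
            se_a, se_e = np.sqrt(np.maximum(np.diag(cov), 0.0))
            tot = sa + se
            grad = np.array([se, -sa]) / tot ** 2
            se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            se_a = se_e = se_h2 = np.nan
        return VarianceComponentsResults(
            sigma2_a=float(sa), sigma2_e=float(se), h2=float(sa / (sa + se)),
            se_sigma2_a=float(se_a), se_sigma2_e=float(se_e), se_h2=se_h2,
            loglik=float(ll), converged=converged, n_iter=it,
            em_loglik_path=np.asarray(em_path), model=self)


@dataclass
class BivariateResults:
    """Two-trait REML estimates: 2x2 genetic/residual covariances, r_G, r_P."""

    sigma_g: np.ndarray       # 2x2 genetic covariance matrix
    sigma_e: np.ndarray       # 2x2 residual covariance matrix
    r_g: float
    r_p: float
    loglik: float
    converged: bool
    n_obs: int

    @property
    def sigma2_a(self) -> np.ndarray:
        return np.diag(self.sigma_g)

    @property
    def sigma2_e_diag(self) -> np.ndarray:
        return np.diag(self.sigma_e)

    @property
    def cov_g12(self) -> float:
        return float(self.sigma_g[0, 1])

    @property
    def sigma2_p(self) -> np.ndarray:
        return np.diag(self.sigma_g + self.sigma_e)

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.sigma_g) / self.sigma2_p

    def summary(self) -> str:
        lines = [
            "Bivariate animal model (REML)",
            "=" * 46,
            f"trait 1: sigma2_a {self.sigma_g[0, 0]:.4g}  sigma2_e {self.sigma_e[0, 0]:.4g}  h2 {self.h2[0]:.3f}",
            f"trait 2: sigma2_a {self.sigma_g[1, 1]:.4g}  sigma2_e {self.sigma_e[1, 1]:.4g}  h2 {self.h2[1]:.3f}",
            f"genetic covariance {self.cov_g12:.4g}   r_G {self.r_g:.3f}",
            f"r_P {self.r_p:.3f}   log-lik {self.loglik:.4f}   converged {self.converged}",
        ]
        return "\n".join(lines)


def _chol_from_params(params3):
    l11, l21, l22 = params3
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    return L @ L.T


class BivariateAdditiveModel:
    """Two-trait animal model sharing one G; complete-case on both traits."""

    def __init__(self, y1, y2, X1, X2, grm):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        G = _as_matrix(grm)
        ok = np.isfinite(y1) & np.isfinite(y2)
        if ok.sum() < 30:
            raise ValueError(f"need >= 30 overlapping observations, got {ok.sum()}")
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        if X1.shape[0] != len(y1):
            X1 = X1.T
        if X2.shape[0] != len(y2):
            X2 = X2.T
        y1, y2 = y1[ok], y2[ok]
        X1, X2 = clean_design(X1[ok]), clean_design(X2[ok])
        for X in (X1, X2):
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("fixed-effect design is rank deficient")
        G = G[np.ix_(ok, ok)]
        self.n = len(y1)
        self.sd = np.array([y1.std(ddof=1), y2.std(ddof=1)])
        vals, U = np.linalg.eigh((G + G.T) / 2.0)
        self.lam = np.maximum(vals, 0.0)
        self.u = np.column_stack([U.T @ (y1 / self.sd[0]), U.T @ (y2 / self.sd[1])])
        self.X1r, self.X2r = U.T @ X1, U.T @ X2
        self.p1, self.p2 = X1.shape[1], X2.shape[1]

    def _neg_restricted_ll(self, theta):
        Sg = _chol_from_params(theta[:3])
        Se = _chol_from_params(theta[3:])
        lam, u = self.lam, self.u
        a = lam * Sg[0, 0] + Se[0, 0]
        b = lam * Sg[0, 1] + Se[0, 1]
        c = lam * Sg[1, 1] + Se[1, 1]
        det = a * c - b * b
        if (det <= 0).any() or (a <= 0).any():
            return np.inf
        i11, i12, i22 = c / det, -b / det, a / det

        X1r, X2r = self.X1r, self.X2r
        A11 = X1r.T @ (i11[:, None] * X1r)
        A12 = X1r.T @ (i12[:, None] * X2r)
        A22 = X2r.T @ (i22[:, None] * X2r)
        A = np.block([[A11, A12], [A12.T, A22]])
        rhs = np.concatenate([X1r.T @ (i11 * u[:, 0] + i12 * u[:, 1]),
                              X2r.T @ (i12 * u[:, 0] + i22 * u[:, 1])])
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, rhs)
        e1 = u[:, 0] - X1r @ beta[: self.p1]
        e2 = u[:, 1] - X2r @ beta[self.p1:]
        quad = (i11 * e1 ** 2 + 2.0 * i12 * e1 * e2 + i22 * e2 ** 2).sum()
        ll = -0.5 * (np.log(det).sum() + logdet_A + quad)
        return -ll

    @staticmethod
    def _chol_params(S):
        L = np.linalg.cholesky(S)
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])

    def fit(self, max_iter: int = 500) -> BivariateResults:
        # split the sample covariance of the (standardized) traits evenly
        # between the genetic and residual parts as a starting point
        C = np.corrcoef(self.u[:, 0], self.u[:, 1])
        theta0 = np.concatenate([
            self._chol_params(0.45 * C + 0.05 * np.eye(2)),
            self._chol_params(0.45 * C + 0.10 * np.eye(2)),
        ])
        res = minimize(self._neg_restricted_ll, theta0, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
        Sg = _chol_from_params(res.x[:3])
        Se = _chol_from_params(res.x[3:])
        scale = np.outer(self.sd, self.sd)
        Sg, Se = Sg * scale, Se * scale
        Sp = Sg + Se
        r_g = Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1])
        r_p = Sp[0, 1] / np.sqrt(Sp[0, 0] * Sp[1, 1])
        return BivariateResults(sigma_g=Sg, sigma_e=Se,
                                r_g=float(np.clip(r_g, -1, 1)),
                                r_p=float(np.clip(r_p, -1, 1)),
                                loglik=float(-res.fun), converged=bool(res.success),
                                n_obs=self.n)
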