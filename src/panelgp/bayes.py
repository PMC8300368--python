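"""Bayesian whole-genome regression: BayesA, BayesB and BayesCpi.

One Gibbs kernel serves all three methods.  The model is
y = Xb + sum_i x_i g_i + e with flat priors on the fixed effects, a scaled
inverse chi-squared prior on the residual variance, and per-marker effects
whose variance prior defines the method:

* BayesA  — every marker has an effect (pi = 0); per-marker variance
  sigma2_gi ~ scaled-inv-chi2(v_g, s2_g).
* BayesB  — a marker has zero effect with probability pi; otherwise its own
  sigma2_gi ~ scaled-inv-chi2(v_g, s2_g).  The indicator is sampled from
  the likelihood with the effect integrated out given the current variance.
* BayesCpi — as BayesB but with one common effect variance and pi sampled
  from its Beta full conditional under a uniform (0, 1) prior.

The scale s2_g is derived from a REML additive-variance estimate via
E(sigma2_gi) = sigma2_a / ((1 - pi) * sum_i 2 p_i (1 - p_i)) and
s2_g = E(sigma2_gi) (v_g - 2) / v_g, so the prior mass matches the genetic
variance the markers must absorb.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["PriorSpec", "PosteriorEffects", "BayesAlphabetModel",
           "derive_scale", "effective_sample_size",
           "VG_PRESELECT", "VG_PREDICT"]

#: Prior degrees of freedom for the marker-effect variance: the preselection
#: profile and the prediction profile differ in the final digit by
#: convention of the respective software defaults.
VG_PRESELECT = 4.234
VG_PREDICT = 4.2

#: Chain profiles: "full" is a production-length run, "test" is scaled for CI.
CHAIN_PROFILES = {"full": (50_000, 10_000), "test": (5_000, 1_000)}


@dataclass
class PriorSpec:
    """Mixture prior and chain settings for one sampler run."""

    pi: float = 0.999
    v_g: float = VG_PRESELECT
    s2_g: float | None = None       # derived from REML sigma2_a when None
    chain_length: int = 5_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi < 1.0:
            raise ValueError(f"pi={self.pi} outside [0, 1)")
        if self.v_g <= 2.0:
            raise ValueError("v_g must exceed 2 for a finite prior mean")
        if self.chain_length <= self.burn_in:
            raise ValueError("chain_length must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def profile(cls, name: str, **kwargs) -> "PriorSpec":
        chain, burn = CHAIN_PROFILES[name]
        return cls(chain_length=chain, burn_in=burn, **kwargs)


def derive_scale(sigma2_a: float, mafs, pi: float, v_g: float) -> float:
    """Prior scale s2_g from the additive variance and marker heterozygosity."""
    het = 2.0 * np.asarray(mafs, dtype=float) * (1.0 - np.asarray(mafs, dtype=float))
    denom = max((1.0 - pi) * het.sum(), 1e-12)
    e_var = sigma2_a / denom
    return float(e_var * (v_g - 2.0) / v_g)


@dataclass
class PosteriorEffects:
    """Posterior summaries of one Gibbs run."""

    marker_id: np.ndarray
    effect_mean: np.ndarray          # posterior mean marker effect (0 when excluded)
    inclusion_prob: np.ndarray       # posterior P(delta_i = 1)
    variance_explained: np.ndarray | None
    pi_mean: float
    sigma2_e_mean: float
    genetic_var_trace: np.ndarray = field(repr=False, default=None)
    pi_trace: np.ndarray = field(repr=False, default=None)
    ess_genetic_var: float = np.nan

    def top_markers(self, k: int) -> np.ndarray:
        """Ids of the k largest markers by variance explained (effect² fallback)."""
        score = (self.variance_explained if self.variance_explained is not None
                 else self.effect_mean ** 2)
        order = np.argsort(score)[::-1][:k]
        return self.marker_id[order]


@njit(cache=True)
def _gibbs(Zt, Xt, y, method, pi0, v_g, s2_g, nu_e, s2_e,
           n_iter, burn_in, thin, seed):
    """Shared kernel. method: 0 = BayesA, 1 = BayesB, 2 = BayesCpi.

    Zt is (m, n) marker-major centered codes; Xt is (p, n) fixed effects.
    Returns posterior sums/traces.
    """
    np.random.seed(seed)
    m, n = Zt.shape
    p = Xt.shape[0]
    xtx = np.empty(m)
    for i in range(m):
        xtx[i] = np.dot(Zt[i], Zt[i])
    ftf = np.empty(p)
    for j in range(p):
        ftf[j] = np.dot(Xt[j], Xt[j])

    beta = np.zeros(p)
    g = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    sigma_gi = np.full(m, v_g * s2_g / max(v_g - 2.0, 0.1))
    sigma_g_common = sigma_gi[0]
    sigma_e = s2_e
    pi = pi0
    e = y.copy()

    n_saved = (n_iter - burn_in + thin - 1) // thin
    g_sum = np.zeros(m)
    delta_sum = np.zeros(m)
    pi_trace = np.empty(n_saved)
    gv_trace = np.empty(n_saved)
    se_sum = 0.0
    saved = 0

    for it in range(n_iter):
        # fixed effects (flat prior)
        for j in range(p):
            rhs = np.dot(Xt[j], e) + ftf[j] * beta[j]
            mean = rhs / ftf[j]
            new_b = mean + np.random.normal(0.0, 1.0) * np.sqrt(sigma_e / ftf[j])
            e += Xt[j] * (beta[j] - new_b)
            beta[j] = new_b

        n_incl = 0
        ss_g = 0.0
        for i in range(m):
            if xtx[i] <= 0.0:
                continue
            svar = sigma_g_common if method == 2 else sigma_gi[i]
            r = np.dot(Zt[i], e) + xtx[i] * g[i]
            if method == 0:
                incl = True
            else:
                v0 = xtx[i] * sigma_e
                v1 = xtx[i] * xtx[i] * svar + v0
                log_odds = (np.log(1.0 - pi) - np.log(pi)
                            + 0.5 * (np.log(v0) - np.log(v1))
                            + 0.5 * r * r * (1.0 / v0 - 1.0 / v1))
                if log_odds > 25.0:
                    incl = True
                elif log_odds < -25.0:
                    incl = False
                else:
                    incl = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            if incl:
                denom = xtx[i] + sigma_e / svar
                mean = r / denom
                g_new = mean + np.random.normal(0.0, 1.0) * np.sqrt(sigma_e / denom)
                delta[i] = 1
                n_incl += 1
            else:
                g_new = 0.0
                delta[i] = 0
            if g_new != g[i]:
                e += Zt[i] * (g[i] - g_new)
                g[i] = g_new
            if method != 2:
                # per-locus variance: posterior when in the model, prior draw otherwise
                if delta[i] == 1:
                    sigma_gi[i] = ((v_g * s2_g + g[i] * g[i])
                                   / np.random.chisquare(v_g + 1.0))
                else:
                    sigma_gi[i] = v_g * s2_g / np.random.chisquare(v_g)
            else:
                ss_g += g[i] * g[i]

        if method == 2:
            sigma_g_common = (v_g * s2_g + ss_g) / np.random.chisquare(v_g + n_incl)
            pi = np.random.beta(m - n_incl + 1.0, n_incl + 1.0)

        sse = np.dot(e, e)
        sigma_e = (nu_e * s2_e + sse) / np.random.chisquare(nu_e + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            g_sum += g
            delta_sum += delta
            pi_trace[saved] = pi
            # genetic values are y - Xb - e; trace their variance
            fixed_part = np.zeros(n)
            for j in range(p):
                fixed_part += Xt[j] * beta[j]
            u = y - fixed_part - e
            gv_trace[saved] = np.var(u)
            se_sum += sigma_e
            saved += 1

    return g_sum / saved, delta_sum / saved, pi_trace, gv_trace, se_sum / saved


def effective_sample_size(trace: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0.0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


class BayesAlphabetModel:
    """Gibbs-sampled whole-genome regression (methods "A", "B", "Cpi").

    ``Z`` holds 0/1/2 codes (centered internally); ``X`` the fixed-effect
    design (defaults to an intercept).  ``fit`` returns
    :class:`PosteriorEffects`; posterior means are over post-burn-in samples.
    """

    _METHOD_CODES = {"A": 0, "B": 1, "Cpi": 2}

    def __init__(self, y, Z, X=None, method: str = "B",
                 prior: PriorSpec | None = None, marker_ids=None,
                 sigma2_a: float | None = None):
        if method not in self._METHOD_CODES:
            raise ValueError(f"unknown method {method!r}; use A, B or Cpi")
        self.method = method
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        Z = np.asarray(Z, dtype=float)[ok]
        self.y = y[ok]
        self.n, self.m = Z.shape
        self.freqs = Z.mean(axis=0) / 2.0
        self.Zt = np.ascontiguousarray((Z - Z.mean(axis=0)).T)
        if X is None:
            X = np.ones((len(y), 1))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        from .reml import clean_design
        self.Xt = np.ascontiguousarray(clean_design(X[ok]).T)
        self.marker_ids = (np.asarray(marker_ids, dtype=object) if marker_ids is not None
                           else np.array([f"m{j}" for j in range(self.m)], dtype=object))

        if prior is None:
            prior = PriorSpec()
        if method == "A" and prior.pi != 0.0:
            prior = PriorSpec(pi=0.0, v_g=prior.v_g, s2_g=prior.s2_g,
                              chain_length=prior.chain_length,
                              burn_in=prior.burn_in, thin=prior.thin,
                              seed=prior.seed)
        self.prior = prior
        self.sigma2_a = sigma2_a

    def fit(self) -> PosteriorEffects:
        pr = self.prior
        var_y = float(np.var(self.y, ddof=1))
        if pr.s2_g is not None:
            s2_g = pr.s2_g
        else:
            # default the additive variance to half the phenotypic variance
            # when no REML estimate is supplied
            sigma2_a = self.sigma2_a if self.sigma2_a is not None else 0.5 * var_y
            # BayesCpi leaves pi free; anchor its common-variance scale on the
            # a-priori assumption that ~1% of markers carry the signal
            pi_for_scale = pr.pi if self.method != "Cpi" else 0.99
            s2_g = derive_scale(sigma2_a, self.freqs, pi_for_scale, pr.v_g)
        nu_e = 4.0
        s2_e = var_y / 4.0   # prior mean nu/(nu-2)*s2 = half the phenotypic variance
        pi0 = pr.pi if self.method != "Cpi" else 0.5

        g_mean, pip, pi_trace, gv_trace, se_mean = _gibbs(
            self.Zt, self.Xt, self.y, self._METHOD_CODES[self.method],
            max(pi0, 1e-12), pr.v_g, s2_g, nu_e, s2_e,
            pr.chain_length, pr.burn_in, pr.thin, pr.seed)

        var_exp = None
        if self.sigma2_a is not None and self.sigma2_a > 0:
            from .preselect import variance_explained
            var_exp = variance_explained(g_mean, self.freqs, self.sigma2_a)
        return PosteriorEffects(
            marker_id=self.marker_ids, effect_mean=g_mean, inclusion_prob=pip,
            variance_explained=var_exp,
            pi_mean=float(pi_trace.mean()) if self.method == "Cpi" else float(pi0),
            sigma2_e_mean=float(se_mean), genetic_var_trace=gv_trace,
            pi_trace=pi_trace, ess_genetic_var=effective_sample_size(gv_trace))
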