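"""Genomic prediction: GBLUP and the Bayesian alphabet.

GBLUP fits variance components by REML on the training individuals and
solves for breeding values two ways every run — the covariance path
(u = sigma2_g G_at V_t^-1 (y - Xb)) and the joint mixed-model equations
over all genotyped individuals — and checks that they agree, since their
equivalence is an algebraic identity of the model.  Direct genomic values
for validation individuals come from the joint solution.

Bayesian prediction reuses the Gibbs kernel; DGV_j = sum_i Z_ij g_i with
raw 0/1/2 codes and posterior-mean effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import BayesAlphabetModel, PosteriorEffects, PriorSpec, VG_PREDICT
from .datatypes import GenotypeMatrix
from .grm import GRM
from .reml import AdditiveVarianceModel, VarianceComponentsResults, clean_design

__all__ = ["DGVResult", "GBLUPModel", "bayes_train_predict", "dgv_from_effects"]


@dataclass
class DGVResult:
    """Direct genomic values for the validation individuals."""

    individual_ids: np.ndarray
    dgv: np.ndarray
    method: str
    effects: np.ndarray | None = None       # per-SNP posterior means (Bayesian)
    pi: float | None = None                 # fitted pi (BayesCpi)
    varcomp: VarianceComponentsResults | None = field(repr=False, default=None)
    posterior: PosteriorEffects | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dgv).all():
            raise ValueError("non-finite DGVs")

    def summary(self) -> str:
        lines = [f"DGVs ({self.method}), n_validation = {len(self.dgv)}",
                 f"mean {self.dgv.mean():.4g}  sd {self.dgv.std(ddof=1):.4g}"]
        if self.varcomp is not None:
            lines.append(f"training h2 = {self.varcomp.h2:.3f}")
        if self.pi is not None:
            lines.append(f"posterior mean pi = {self.pi:.4f}")
        return "\n".join(lines)


def dgv_from_effects(Z_valid, effects) -> np.ndarray:
    """DGV_j = sum_i Z_ij g_i with raw 0/1/2 codes."""
    return np.asarray(Z_valid, dtype=float) @ np.asarray(effects, dtype=float)


class GBLUPModel:
    """GBLUP over a shared G with phenotypes observed only in training.

    ``grm`` covers all genotyped individuals; ``train_idx`` / ``valid_idx``
    are disjoint row index arrays into it.
    """

    def __init__(self, y_train, X_train, grm: GRM, train_idx, valid_idx):
        self.train_idx = np.asarray(train_idx, dtype=np.int64)
        self.valid_idx = np.asarray(valid_idx, dtype=np.int64)
        if np.intersect1d(self.train_idx, self.valid_idx).size:
            raise ValueError("training and validation sets overlap")
        self.y = np.asarray(y_train, dtype=float)
        X = np.atleast_2d(np.asarray(X_train, dtype=float))
        if X.shape[0] != len(self.y):
            X = X.T
        self.X = X
        self.grm = grm

    def fit(self, ridge: float = 1e-8) -> DGVResult:
        ok = np.isfinite(self.y)
        tr = self.train_idx[ok]
        y, X = self.y[ok], clean_design(self.X[ok])
        G = self.grm.matrix
        G_tt = G[np.ix_(tr, tr)]

        vc = AdditiveVarianceModel(y, X, G_tt).fit()
        if not vc.converged:
            raise RuntimeError("training REML did not converge")
        sa, se = vc.sigma2_a, vc.sigma2_e

        # covariance path
        V = sa * G_tt + se * np.eye(len(tr))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ (Vi @ y))
        r = Vi @ (y - X @ beta)
        u_cov = sa * (G[:, tr] @ r)

        # joint mixed-model equations over all individuals
        n_all = G.shape[0]
        lam = se / sa
        Z = np.zeros((len(tr), n_all))
        Z[np.arange(len(tr)), tr] = 1.0
        rhs = np.concatenate([X.T @ y, Z.T @ y])

        def solve_mme(G_work):
            G_inv = np.linalg.inv(G_work)
            lhs = np.vstack([
                np.hstack([X.T @ X, X.T @ Z]),
                np.hstack([Z.T @ X, Z.T @ Z + lam * G_inv]),
            ])
            return np.linalg.solve(lhs, rhs)[X.shape[1]:]

        scale = max(np.abs(u_cov).max(), 1.0)
        try:
            np.linalg.cholesky(G)
            u_mme = solve_mme(G)
        except np.linalg.LinAlgError:
            u_mme = solve_mme(G + ridge * np.eye(n_all))
        if np.abs(u_cov - u_mme).max() > 1e-6 * scale:
            # near-singular G: regularize and retry once
            u_mme = solve_mme(G + ridge * np.eye(n_all))
            if np.abs(u_cov - u_mme).max() > 1e-6 * scale:
                raise AssertionError(
                    "GBLUP solution paths disagree beyond tolerance: "
                    f"{np.abs(u_cov - u_mme).max():.3g}")

        ids = self.grm.individual_ids[self.valid_idx]
        return DGVResult(individual_ids=ids, dgv=u_mme[self.valid_idx],
                         method="GBLUP", varcomp=vc)


def bayes_train_predict(method: str, genotypes: GenotypeMatrix, y_train,
                        fixed_design_train, train_idx, valid_idx,
                        prior: PriorSpec | None = None,
                        sigma2_a: float | None = None) -> DGVResult:
    """Train BayesA/B/Cpi on the training rows and predict validation DGVs.

    Method profiles: BayesA forces pi = 0; BayesB uses the fixed pi in
    ``prior`` (default 0.995 for a preselected panel); BayesCpi samples pi.
    """
    train_idx = np.asarray(train_idx, dtype=np.int64)
    valid_idx = np.asarray(valid_idx, dtype=np.int64)
    if np.intersect1d(train_idx, valid_idx).size:
        raise ValueError("training and validation sets overlap")
    if prior is None:
        defaults = {"A": 0.0, "B": 0.995, "Cpi": 0.5}
        prior = PriorSpec(pi=defaults[method], v_g=VG_PREDICT)
    Z_train = genotypes.values[train_idx].astype(float)
    Z_valid = genotypes.values[valid_idx].astype(float)
    model = BayesAlphabetModel(y_train, Z_train, X=fixed_design_train,
                               method=method, prior=prior, sigma2_a=sigma2_a)
    post = model.fit()
    dgv = dgv_from_effects(Z_valid, post.effect_mean)
    return DGVResult(individual_ids=genotypes.individual_ids[valid_idx],
                     dgv=dgv, method=f"Bayes{method}", effects=post.effect_mean,
                     pi=post.pi_mean if method == "Cpi" else None,
                     posterior=post)
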