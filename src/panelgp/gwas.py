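"""Single-marker mixed-model association (MMRA).

Two-stage: (1) fit the polygenic null model y = Xb + a + e once by REML,
with the top principal components of G included among the fixed effects to
absorb stratification; (2) test every SNP with a generalized-least-squares
Wald test holding the null covariance V = sigma2_a G + sigma2_e I fixed.
With P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, the per-SNP estimate is
alpha_hat = s'Py / s'Ps with Var(alpha_hat) = 1/s'Ps and a 1-df chi-squared
Wald statistic.  Exact per-SNP REML would shift p-values slightly; the
fixed-covariance approximation is the standard fast route.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import GenotypeMatrix, MarkerMap
from .grm import GRM, pca_top
from .reml import AdditiveVarianceModel

__all__ = ["GWASResult", "mmra_gwas"]


@dataclass
class GWASResult:
    """Per-SNP effect estimates, SEs, Wald statistics and p-values."""

    marker_id: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    null_sigma2_a: float
    null_sigma2_e: float

    def __len__(self) -> int:
        return len(self.marker_id)

    def to_frame(self, marker_map: MarkerMap | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"marker_id": self.marker_id.astype(str),
                           "beta": self.beta, "se": self.se,
                           "statistic": self.statistic, "p": self.p_value})
        if marker_map is not None:
            df.insert(1, "chromosome", marker_map.chromosome)
            df.insert(2, "position_bp", marker_map.position_bp)
        return df

    def plot_manhattan(self, marker_map: MarkerMap, ax=None, **kwargs):
        """-log10 p against cumulative genome position, colored by chromosome."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for c in np.unique(marker_map.chromosome):
            on = marker_map.chromosome == c
            pos = marker_map.position_bp[on]
            ax.scatter(offset + pos, -np.log10(np.maximum(self.p_value[on], 1e-300)),
                       s=4, **kwargs)
            offset += pos.max()
        ax.set_xlabel("genome position")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax


def mmra_gwas(genotypes: GenotypeMatrix, y, fixed_design, grm: GRM,
              n_pcs: int = 3, marker_map: MarkerMap | None = None) -> GWASResult:
    """Mixed-model single-locus regression over all markers.

    ``fixed_design`` is the covariate matrix (with intercept); the top
    ``n_pcs`` principal components of ``grm`` are appended automatically.
    Monomorphic SNPs get beta 0 and p 1.
    """
    if genotypes.missing.any():
        raise ValueError("GWAS requires complete genotypes")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    ok = np.isfinite(y)
    if ok.sum() < 30:
        raise ValueError("fewer than 30 phenotyped individuals")
    if n_pcs > 0:
        X = np.column_stack([X, pca_top(grm, n_pcs)])
    S_all = genotypes.values.astype(float)
    G = grm.matrix
    from .reml import clean_design
    y, X, S, Gs = y[ok], clean_design(X[ok]), S_all[ok], G[np.ix_(ok, ok)]

    null = AdditiveVarianceModel(y, X, Gs).fit()
    if not null.converged:
        raise RuntimeError("polygenic null model did not converge")
    sa, se = null.sigma2_a, null.sigma2_e

    # V^-1 via the eigendecomposition of G on the analysis individuals
    vals, U = np.linalg.eigh(Gs)
    d_inv = 1.0 / (sa * np.maximum(vals, 0.0) + se)
    Vi_y = U @ (d_inv * (U.T @ y))
    Vi_X = U @ (d_inv[:, None] * (U.T @ X))
    XtViX_inv = np.linalg.inv(X.T @ Vi_X)
    Py = Vi_y - Vi_X @ (XtViX_inv @ (X.T @ Vi_y))

    Vi_S = U @ (d_inv[:, None] * (U.T @ S))
    XtViS = X.T @ Vi_S
    num = S.T @ Py                                        # s'Py
    sPs = np.einsum("ij,ij->j", S, Vi_S) - np.einsum(
        "ij,ij->j", XtViS, XtViX_inv @ XtViS)             # s'Ps

    poly = sPs > 1e-12
    beta = np.zeros(S.shape[1])
    se_b = np.full(S.shape[1], np.inf)
    stat = np.zeros(S.shape[1])
    beta[poly] = num[poly] / sPs[poly]
    se_b[poly] = 1.0 / np.sqrt(sPs[poly])
    stat[poly] = num[poly] ** 2 / sPs[poly]
    p = np.where(poly, chi2.sf(stat, df=1), 1.0)
    if marker_map is not None:
        marker_ids = marker_map.marker_id
    else:
        marker_ids = np.array([f"m{j}" for j in range(S.shape[1])], dtype=object)
    return GWASResult(marker_ids, beta, se_b, stat, p, sa, se)
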