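"""VanRaden genomic relationship matrix and principal components.

G = (M - P)(M - P)' / (2 Σ pᵢ(1-pᵢ)), where M holds 0/1/2 minor-allele
dosages, the columns of P equal 2pᵢ with pᵢ the observed counted-allele
frequency, and the denominator scales the diagonal to average ~1 in an
unrelated population.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeMatrix

__all__ = ["GRM", "build_grm", "pca_top"]


@dataclass
class GRM:
    matrix: np.ndarray
    individual_ids: np.ndarray
    allele_freqs: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, rows, cols=None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.matrix[np.ix_(rows, cols)]


def build_grm(genotypes: GenotypeMatrix) -> GRM:
    """Build the genomic relationship matrix from complete dosage codes."""
    if genotypes.missing.any():
        raise ValueError("GRM requires complete genotypes; fill or filter missing calls")
    M = genotypes.values.astype(float)
    p = M.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        raise ValueError(
            f"{mono.sum()} monomorphic markers: centering and the 2p(1-p) "
            "denominator are undefined; filter them first")
    W = M - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return GRM(G, genotypes.individual_ids, p)


def pca_top(grm: GRM, k: int = 3) -> np.ndarray:
    """Top-k principal component scores: eigenvectors of G scaled by sqrt(eigenvalue).

    Deterministic sign: in each component, the loading of largest magnitude
    is made positive.
    """
    if k > grm.n:
        raise ValueError(f"k={k} exceeds number of individuals {grm.n}")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    scores = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))[None, :]
    for j in range(scores.shape[1]):
        i_max = np.argmax(np.abs(scores[:, j]))
        if scores[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores
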