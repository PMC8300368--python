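"""Quality control, allele statistics, LD decay and the masking harness.

Standard chip-QC filters (individual call rate, SNP call rate, MAF,
Hardy-Weinberg chi-squared), modal-genotype fill for residual missingness,
composite-LD r² on genotype codes, binned LD-decay curves, and the
masking-based genotype-imputation accuracy metric.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import GenotypeMatrix, MarkerMap

__all__ = [
    "QCThresholds", "QCReport", "LDDecayCurve",
    "compute_maf", "call_rate", "hwe_chisq_p", "apply_qc", "fill_missing",
    "ld_r2", "ld_decay_curve", "imputation_accuracy",
]


class UndefinedValueError(ValueError):
    """A statistic is undefined on the given input (all missing / zero variance)."""


class EmptyResultError(ValueError):
    """QC removed everything."""


@dataclass
class QCThresholds:
    """Retention thresholds: a record is kept when it exceeds each one."""

    snp_call_rate_min: float = 0.90
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    individual_call_rate_min: float = 0.90

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "hwe_p_min",
                     "individual_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_individuals_in: int
    n_markers_in: int
    n_individuals_removed_call_rate: int
    n_markers_removed_call_rate: int
    n_markers_removed_maf: int
    n_markers_removed_hwe: int
    n_individuals_out: int
    n_markers_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class LDDecayCurve:
    """Mean r² within distance bins covering (0, max_dist]."""

    bin_edges_bp: np.ndarray      # length n_bins + 1, starting at 0
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_bp": self.bin_edges_bp[:-1],
            "bin_end_bp": self.bin_edges_bp[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })

    def plot(self, ax=None, **kwargs):
        """Mean r² against bin midpoint (kb)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        mid = (self.bin_edges_bp[:-1] + self.bin_edges_bp[1:]) / 2.0
        ok = self.n_pairs > 0
        ax.plot(mid[ok] / 1e3, self.mean_r2[ok], marker="o", **kwargs)
        ax.set_xlabel("distance (kb)")
        ax.set_ylabel("mean $r^2$")
        return ax


def _valid(column, missing=None):
    col = np.asarray(column, dtype=float)
    if missing is not None:
        col = np.where(np.asarray(missing, dtype=bool), np.nan, col)
    return col[~np.isnan(col)]


def compute_maf(column, missing=None) -> float:
    """Minor allele frequency min(f, 1-f) with f the counted-allele frequency."""
    obs = _valid(column, missing)
    if obs.size == 0:
        raise UndefinedValueError("MAF undefined: all calls missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def call_rate(column, missing=None) -> float:
    col = np.asarray(column, dtype=float)
    if missing is not None:
        col = np.where(np.asarray(missing, dtype=bool), np.nan, col)
    return float(1.0 - np.isnan(col).mean())


def hwe_chisq_p(column, missing=None) -> float:
    """1-df chi-squared Hardy-Weinberg test on genotype counts.

    Monomorphic sites return p = 1 by convention (the test is vacuous).
    No continuity correction.
    """
    obs = _valid(column, missing)
    if obs.size == 0:
        raise UndefinedValueError("HWE undefined: all calls missing")
    n = obs.size
    n2 = float((obs == 2).sum())
    n1 = float((obs == 1).sum())
    f = (2 * n2 + n1) / (2 * n)
    if f <= 0.0 or f >= 1.0:
        return 1.0
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]) * n
    observed = np.array([n - n1 - n2, n1, n2])
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


def apply_qc(genotypes: GenotypeMatrix, marker_map: MarkerMap,
             thresholds: QCThresholds = QCThresholds()
             ) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Filter individuals then markers; each filter keeps values strictly above threshold.

    Order: individual call rate first; then, on the retained individuals,
    SNP call rate, MAF and HWE (the marker statistics depend on who is kept,
    so the individual filter must come first).
    """
    n, m = genotypes.values.shape
    dos = genotypes.dosages()

    ind_cr = 1.0 - np.isnan(dos).mean(axis=1)
    keep_ind = ind_cr > thresholds.individual_call_rate_min
    dos = dos[keep_ind]
    if dos.shape[0] == 0:
        raise EmptyResultError("all individuals removed by call-rate filter")

    obs = ~np.isnan(dos)
    n_obs = obs.sum(axis=0)
    snp_cr = n_obs / dos.shape[0]
    with np.errstate(invalid="ignore"):
        f = np.nansum(dos, axis=0) / np.maximum(2.0 * n_obs, 1)
    maf = np.minimum(f, 1.0 - f)
    keep_cr = snp_cr > thresholds.snp_call_rate_min
    keep_maf = maf > thresholds.maf_min
    hwe_p = np.ones(dos.shape[1])
    candidates = np.flatnonzero(keep_cr & keep_maf & (n_obs > 0))
    for j in candidates:
        hwe_p[j] = hwe_chisq_p(dos[:, j])
    keep_hwe = hwe_p > thresholds.hwe_p_min

    keep_snp = keep_cr & keep_maf & keep_hwe & (n_obs > 0)
    report = QCReport(
        n_individuals_in=n, n_markers_in=m,
        n_individuals_removed_call_rate=int((~keep_ind).sum()),
        n_markers_removed_call_rate=int((~keep_cr).sum()),
        n_markers_removed_maf=int((keep_cr & ~keep_maf).sum()),
        n_markers_removed_hwe=int((keep_cr & keep_maf & ~keep_hwe).sum()),
        n_individuals_out=int(keep_ind.sum()),
        n_markers_out=int(keep_snp.sum()),
    )
    if report.n_markers_out == 0:
        raise EmptyResultError("all markers removed by QC")
    out = genotypes.subset(keep_ind, keep_snp)
    return out, marker_map.subset(keep_snp), report


def fill_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP modal genotype (ties -> lower code).

    A simple deterministic stand-in for reference-panel imputation; the
    original matrix is left untouched for audit.
    """
    values = genotypes.values.copy()
    missing = genotypes.missing
    for j in np.flatnonzero(missing.any(axis=0)):
        obs = values[~missing[:, j], j]
        if obs.size == 0:
            raise UndefinedValueError(f"column {j} is entirely missing")
        counts = np.bincount(obs, minlength=3)
        values[missing[:, j], j] = int(np.argmax(counts))  # argmax -> lowest code on ties
    return GenotypeMatrix(values, np.zeros_like(missing), genotypes.individual_ids)


def ld_r2(col_i, col_j, missing_i=None, missing_j=None) -> float:
    """Squared Pearson correlation of genotype codes over pairwise-complete calls."""
    x = np.asarray(col_i, dtype=float)
    y = np.asarray(col_j, dtype=float)
    if missing_i is not None:
        x = np.where(np.asarray(missing_i, dtype=bool), np.nan, x)
    if missing_j is not None:
        y = np.where(np.asarray(missing_j, dtype=bool), np.nan, y)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedValueError("r2 undefined: zero variance or <2 complete pairs")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay_curve(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                   max_dist_bp: int = 2_000_000, n_bins: int = 40,
                   max_pairs: int | None = None,
                   rng: np.random.Generator | None = None) -> LDDecayCurve:
    """Bin all intra-chromosomal marker pairs within ``max_dist_bp`` by distance.

    ``max_pairs`` subsamples pairs (seeded ``rng`` required) for large maps.
    Zero-variance columns are skipped.
    """
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    dos = genotypes.dosages()

    pair_i, pair_j = [], []
    for c in np.unique(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == c)
        if idx.size < 2:
            continue
        order = idx[np.argsort(marker_map.position_bp[idx])]
        pos = marker_map.position_bp[order]
        a = np.arange(len(order))
        hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
        n_per_a = np.maximum(hi - a - 1, 0)
        if n_per_a.sum() == 0:
            continue
        rep_a = np.repeat(a, n_per_a)
        offsets = np.arange(n_per_a.sum()) - np.repeat(
            np.concatenate(([0], np.cumsum(n_per_a)[:-1])), n_per_a)
        rep_b = rep_a + 1 + offsets
        pair_i.append(order[rep_a])
        pair_j.append(order[rep_b])
    if not pair_i:
        raise UndefinedValueError("no intra-chromosomal pairs within max_dist_bp")
    pair_i = np.concatenate(pair_i)
    pair_j = np.concatenate(pair_j)
    if max_pairs is not None and len(pair_i) > max_pairs:
        if rng is None:
            raise ValueError("subsampling pairs requires an rng")
        sel = rng.choice(len(pair_i), size=max_pairs, replace=False)
        pair_i, pair_j = pair_i[sel], pair_j[sel]

    dists = (marker_map.position_bp[pair_j] - marker_map.position_bp[pair_i]).astype(float)
    bins = np.minimum(np.searchsorted(edges, dists, side="left"), n_bins) - 1
    bins = np.maximum(bins, 0)
    if not genotypes.missing.any():
        # complete data: r is a dot product of standardized columns
        sd = dos.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (dos - dos.mean(axis=0)) / (sd * np.sqrt(dos.shape[0]))
        for start in range(0, len(pair_i), 200_000):
            sl = slice(start, start + 200_000)
            r = np.einsum("ij,ij->j", z[:, pair_i[sl]], z[:, pair_j[sl]])
            ok = np.isfinite(r)
            np.add.at(sums, bins[sl][ok], r[ok] ** 2)
            np.add.at(counts, bins[sl][ok], 1)
    else:
        for (a, b, k) in zip(pair_i, pair_j, bins):
            try:
                r2 = ld_r2(dos[:, a], dos[:, b])
            except UndefinedValueError:
                continue
            sums[k] += r2
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean_r2, counts)


def imputation_accuracy(true_genotypes: GenotypeMatrix,
                        imputed_genotypes: GenotypeMatrix,
                        mask: np.ndarray) -> float:
    """Fraction of masked entries whose imputed code equals the true code."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != true_genotypes.values.shape:
        raise ValueError("mask shape does not match genotypes")
    if not mask.any():
        raise ValueError("empty mask: no entries were hidden")
    return float((imputed_genotypes.values[mask] == true_genotypes.values[mask]).mean())
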