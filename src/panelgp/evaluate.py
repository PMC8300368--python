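"""Validation schemes, accuracy/bias metrics and the end-to-end experiment.

Prediction accuracy is cor(DGV, adjusted phenotype) / sqrt(h2) on the
validation set, with the adjusted phenotype the OLS residual after removing
the environmental fixed effects; dispersion bias is the regression slope of
adjusted phenotype on DGV (1 = unbiased, <1 inflation, >1 deflation).

Two validation schemes: a birth-year split (train before the cut year,
validate after — the forward-prediction design a breeding program faces)
for the low-density panel, and replicated k-fold cross-validation for the
full-density comparison, with metrics averaged per fold, then per replicate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerMap, TraitTable
from .grm import build_grm
from .gwas import mmra_gwas
from .predict import GBLUPModel, bayes_train_predict
from .preselect import (bayesb_train, gene_select, merge_panel,
                        select_top_fraction, sliding_window_select)
from .qc import UndefinedValueError, apply_qc, compute_maf
from .reml import AdditiveVarianceModel
from .bayes import PriorSpec, VG_PRESELECT, VG_PREDICT
from .simdata import SimConfig, simulate_dataset

__all__ = ["CVScheme", "EvalMetrics", "adjust_phenotypes", "make_scheme",
           "accuracy", "bias_slope", "ExperimentConfig", "run_experiment"]


@dataclass
class CVScheme:
    """Fold assignments for one validation design.

    ``folds`` has shape (n_replicates, n_individuals) with fold labels
    0..k-1 for scheme "kfold"; for "year_split" it has one row with 0 =
    training, 1 = validation.
    """

    scheme: str
    folds: np.ndarray
    k: int
    n_replicates: int
    seed: int | None = None

    def splits(self):
        """Yield (replicate, fold, train_idx, valid_idx)."""
        for rep in range(self.folds.shape[0]):
            labels = self.folds[rep]
            n_folds = self.k if self.scheme == "kfold" else 1
            for f in range(n_folds):
                valid = np.flatnonzero(labels == (f if self.scheme == "kfold" else 1))
                train = np.flatnonzero(labels != (f if self.scheme == "kfold" else 1))
                yield rep, f, train, valid


@dataclass
class EvalMetrics:
    trait: str
    method: str
    panel: str
    scheme: str
    accuracy: float
    bias_slope: float
    n_validation: int


def adjust_phenotypes(y, fixed_design, column_names=None) -> np.ndarray:
    """OLS residuals of the trait on the environmental fixed effects.

    Missing phenotypes stay NaN.  Raises on a rank-deficient design, naming
    the collinear columns when names are given.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if column_names is not None:
            # flag columns whose removal restores full column rank
            bad = [column_names[j] for j in range(X.shape[1])
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
            raise ValueError(f"fixed-effect design is rank deficient; "
                             f"collinear columns: {bad}")
        raise ValueError("fixed-effect design is rank deficient")
    out = np.full_like(y, np.nan)
    ok = np.isfinite(y)
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def make_scheme(n_individuals: int, scheme: str = "kfold", k: int = 5,
                n_replicates: int = 20, seed: int = 0,
                birth_year=None, cut_year: int = 2014) -> CVScheme:
    """Build fold assignments.

    kfold: seeded random permutation folds of near-equal size (sizes differ
    by at most 1), a fresh randomization per replicate.  year_split: train
    on birth_year < cut_year, validate on the rest.
    """
    if scheme == "kfold":
        if n_individuals < k:
            raise ValueError(f"need at least k={k} individuals")
        rng = np.random.default_rng(seed)
        folds = np.empty((n_replicates, n_individuals), dtype=np.int64)
        base = np.arange(n_individuals) % k
        for rep in range(n_replicates):
            folds[rep] = base[rng.permutation(n_individuals)]
        return CVScheme("kfold", folds, k, n_replicates, seed)
    if scheme == "year_split":
        by = np.asarray(birth_year)
        valid = (by >= cut_year).astype(np.int64)
        if valid.all() or not valid.any():
            raise ValueError("year split puts all individuals on one side")
        return CVScheme("year_split", valid[None, :], 1, 1, None)
    raise ValueError(f"unknown scheme {scheme!r}")


def accuracy(dgv, y_adj, h2: float) -> float:
    """Pearson cor(DGV, adjusted phenotype) / sqrt(h2)."""
    dgv = np.asarray(dgv, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    ok = np.isfinite(dgv) & np.isfinite(y_adj)
    dgv, y_adj = dgv[ok], y_adj[ok]
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2={h2} outside (0, 1]")
    if len(dgv) < 3:
        raise ValueError("need at least 3 validation individuals")
    if dgv.std() == 0.0 or y_adj.std() == 0.0:
        raise UndefinedValueError("accuracy undefined: zero variance")
    return float(np.corrcoef(dgv, y_adj)[0, 1] / np.sqrt(h2))


def bias_slope(dgv, y_adj) -> float:
    """OLS slope of adjusted phenotype on DGV."""
    dgv = np.asarray(dgv, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    ok = np.isfinite(dgv) & np.isfinite(y_adj)
    dgv, y_adj = dgv[ok], y_adj[ok]
    if dgv.std() == 0.0:
        raise UndefinedValueError("bias slope undefined: zero DGV variance")
    return float(np.cov(y_adj, dgv, ddof=1)[0, 1] / np.var(dgv, ddof=1))


@dataclass
class ExperimentConfig:
    """End-to-end panel-design-and-validation experiment settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    traits: tuple | None = None            # None = all simulated traits
    methods: tuple = ("GBLUP",)            # of {"GBLUP","BayesA","BayesB","BayesCpi"}
    gwas_fraction: float = 0.001
    bayesb_fraction: float = 0.001
    use_gwas: bool = True
    use_bayesb: bool = True
    use_window: bool = True
    use_gene: bool = True
    n_genes: int = 500
    window_bp: int = 500_000
    cv_k: int = 5
    cv_replicates: int = 20
    cut_year: int = 2014
    chain_length: int = 5_000
    burn_in: int = 1_000
    seed: int = 0


def _panel_flags(cfg):
    return [(flag, on) for flag, on in (
        ("gwas", cfg.use_gwas), ("bayesb", cfg.use_bayesb),
        ("window", cfg.use_window), ("gene", cfg.use_gene)) if on]


def run_experiment(config: ExperimentConfig, data=None):
    """Design the low-density panel and benchmark it against full density.

    Returns (results DataFrame averaged per scheme, per-fold DataFrame,
    Panel, context dict).  ``data`` may supply a pre-built
    (genotypes, marker_map, traits) triple; otherwise the dataset is
    simulated from ``config.sim``.
    """
    if data is None:
        genotypes, marker_map, trait_table, truth = simulate_dataset(config.sim)
    else:
        genotypes, marker_map, trait_table = data[:3]
        truth = data[3] if len(data) > 3 else None
    genotypes, marker_map, qc_report = apply_qc(genotypes, marker_map)
    keep_ids = set(map(str, genotypes.individual_ids))
    tt = TraitTable(trait_table.data.loc[[i for i in trait_table.data.index
                                          if i in keep_ids]].copy(),
                    traits=trait_table.traits)
    traits = tuple(config.traits or tt.traits)
    n = genotypes.n_individuals
    grm = build_grm(genotypes)
    X, x_names = tt.fixed_design()
    mafs = np.array([compute_maf(genotypes.values[:, j])
                     for j in range(len(marker_map))])

    birth_year = tt.data["birth_year"].to_numpy()
    year_scheme = make_scheme(n, "year_split", birth_year=birth_year,
                              cut_year=config.cut_year)
    _, _, train_idx, valid_idx = next(year_scheme.splits())

    # --- per-trait h2 on the full data (accuracy denominator) and panel design
    h2_hat, gwas_lists, bayes_lists = {}, [], []
    for t in traits:
        y = tt.phenotype(t)
        vc = AdditiveVarianceModel(y, X, grm).fit()
        h2_hat[t] = min(max(vc.h2, 1e-3), 1.0)
        y_train_only = np.where(np.isin(np.arange(n), train_idx), y, np.nan)
        if config.use_gwas:
            gw = mmra_gwas(genotypes, y_train_only, X, grm, marker_map=marker_map)
            gwas_lists.append(select_top_fraction(gw.p_value, marker_map,
                                                  config.gwas_fraction, "smallest"))
        if config.use_bayesb:
            prior = PriorSpec(pi=0.999, v_g=VG_PRESELECT,
                              chain_length=config.chain_length,
                              burn_in=config.burn_in,
                              seed=config.seed + traits.index(t))
            post = bayesb_train(genotypes.subset(train_idx), y[train_idx],
                                X[train_idx], prior=prior, sigma2_a=vc.sigma2_a,
                                marker_map=marker_map)
            bayes_lists.append(select_top_fraction(
                post.variance_explained, marker_map,
                config.bayesb_fraction, "largest"))

    per_strategy, attribution = {}, {}
    if gwas_lists:
        per_strategy["gwas"] = gwas_lists
        attribution["gwas"] = {t: set(map(str, ids))
                               for t, ids in zip(traits, gwas_lists)}
    if bayes_lists:
        per_strategy["bayesb"] = bayes_lists
        attribution["bayesb"] = {t: set(map(str, ids))
                                 for t, ids in zip(traits, bayes_lists)}
    if config.use_window:
        per_strategy["window"] = sliding_window_select(marker_map, mafs,
                                                       window_bp=config.window_bp)
    if config.use_gene:
        from .simdata import simulate_gene_annotation
        genes = simulate_gene_annotation(marker_map, config.n_genes,
                                         rng=np.random.default_rng(config.seed + 7))
        per_strategy["gene"], _ = gene_select(marker_map, mafs, genes)
    panel = merge_panel(per_strategy, marker_map, mafs=mafs,
                        trait_attribution=attribution)
    panel_cols = marker_map.index_of(panel.marker_id)

    # --- evaluation
    def predict_dgv(method, geno, geno_grm, y, train, valid, sigma2_a):
        if method == "GBLUP":
            return GBLUPModel(y[train], X[train], geno_grm, train, valid).fit()
        short = method.removeprefix("Bayes")
        defaults = {"A": 0.0, "B": 0.995, "Cpi": 0.5}
        prior = PriorSpec(pi=defaults[short], v_g=VG_PREDICT,
                          chain_length=config.chain_length,
                          burn_in=config.burn_in, seed=config.seed + 13)
        return bayes_train_predict(short, geno, y[train], X[train], train,
                                   valid, prior=prior, sigma2_a=sigma2_a)

    geno_panel = genotypes.subset(cols=panel_cols)
    grm_panel = build_grm(geno_panel) if "GBLUP" in config.methods else None
    kfold = make_scheme(n, "kfold", k=config.cv_k,
                        n_replicates=config.cv_replicates, seed=config.seed + 1)
    rows = []
    for t in traits:
        y = tt.phenotype(t)
        y_adj = adjust_phenotypes(y, X, x_names)
        sigma2_a_t = AdditiveVarianceModel(y, X, grm).fit().sigma2_a
        for method in config.methods:
            # full-density chip: replicated k-fold CV
            for rep, f, tr, va in kfold.splits():
                dgv = predict_dgv(method, genotypes, grm, y, tr, va, sigma2_a_t)
                rows.append(dict(trait=t, method=method, panel="full",
                                 scheme="kfold", replicate=rep, fold=f,
                                 accuracy=accuracy(dgv.dgv, y_adj[va], h2_hat[t]),
                                 bias=bias_slope(dgv.dgv, y_adj[va]),
                                 n_validation=len(va)))
            # low-density panel: forward year split, panel genotypes directly
            dgv = predict_dgv(method, geno_panel, grm_panel, y, train_idx,
                              valid_idx, sigma2_a_t)
            rows.append(dict(trait=t, method=method, panel="lowdensity",
                             scheme="year_split", replicate=0, fold=0,
                             accuracy=accuracy(dgv.dgv, y_adj[valid_idx], h2_hat[t]),
                             bias=bias_slope(dgv.dgv, y_adj[valid_idx]),
                             n_validation=len(valid_idx)))
    per_fold = pd.DataFrame(rows)
    # average over folds within replicate, then over replicates
    summary = (per_fold
               .groupby(["trait", "method", "panel", "scheme", "replicate"],
                        as_index=False)[["accuracy", "bias"]].mean()
               .groupby(["trait", "method", "panel", "scheme"],
                        as_index=False)[["accuracy", "bias"]].mean())
    context = dict(qc_report=qc_report, h2_hat=h2_hat, truth=truth,
                   marker_map=marker_map, n_panel=len(panel),
                   train_idx=train_idx, valid_idx=valid_idx)
    return summary, per_fold, panel, context
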