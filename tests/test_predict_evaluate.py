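"""GBLUP/Bayesian prediction and the evaluation harness."""
import numpy as np
import pandas as pd
import pytest

from panelgp.datatypes import GenotypeMatrix
from panelgp.evaluate import (ExperimentConfig, accuracy, adjust_phenotypes,
                              bias_slope, make_scheme, run_experiment)
from panelgp.grm import GRM, build_grm
from panelgp.predict import GBLUPModel, bayes_train_predict, dgv_from_effects
from panelgp.qc import UndefinedValueError
from panelgp.simdata import SimConfig


def _independent_geno(rng, n, m):
    freqs = rng.uniform(0.1, 0.5, m)
    vals = rng.binomial(2, freqs[None, :], (n, m)).astype(np.int8)
    ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    return GenotypeMatrix(vals, np.zeros((n, m), dtype=bool), ids)


class TestGBLUP:
    def test_equivalent_to_snp_blup_ridge(self):
        """GBLUP DGVs equal ridge regression on centered markers with the
        matched per-marker effect variance (a model identity)."""
        rng = np.random.default_rng(20)
        n, m = 200, 500
        g = _independent_geno(rng, n, m)
        grm = build_grm(g)
        W = g.values.astype(float) - g.values.mean(axis=0)
        c = 2 * np.sum(grm.allele_freqs * (1 - grm.allele_freqs))
        y = W[:, :40] @ rng.standard_normal(40) * 0.1 + rng.standard_normal(n)
        tr, va = np.arange(150), np.arange(150, 200)
        res = GBLUPModel(y[tr], np.ones((150, 1)), grm, tr, va).fit()
        sa, se = res.varcomp.sigma2_a, res.varcomp.sigma2_e
        # SNP-BLUP: alpha = W_t'(W_t W_t'/c·sa + se I)^-1 (y - mu); u = W alpha/c·sa
        Wt = W[tr]
        V = sa * (Wt @ Wt.T) / c + se * np.eye(150)
        Vi = np.linalg.inv(V)
        X = np.ones((150, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ (Vi @ y[tr]))
        r = Vi @ (y[tr] - X @ beta)
        alpha = (sa / c) * (Wt.T @ r)
        u_snp = W[va] @ alpha
        np.testing.assert_allclose(res.dgv, u_snp, atol=1e-6 * max(1, np.abs(u_snp).max()))

    def test_genotype_twins_get_equal_dgvs(self):
        rng = np.random.default_rng(21)
        g = _independent_geno(rng, 100, 300)
        vals = g.values.copy()
        vals[98] = vals[0]                      # two validation twins of trainee 0
        vals[99] = vals[0]
        g = GenotypeMatrix(vals, g.missing, g.individual_ids)
        grm = build_grm(g)
        y = rng.standard_normal(98)
        res = GBLUPModel(y, np.ones((98, 1)), grm, np.arange(98),
                         np.array([98, 99])).fit()
        assert res.dgv[0] == pytest.approx(res.dgv[1], abs=1e-8)
        assert res.varcomp.converged

    def test_overlapping_sets_rejected(self):
        rng = np.random.default_rng(22)
        g = _independent_geno(rng, 50, 60)
        grm = build_grm(g)
        with pytest.raises(ValueError, match="overlap"):
            GBLUPModel(rng.standard_normal(40), np.ones((40, 1)), grm,
                       np.arange(40), np.array([39]))

    def test_predictive_on_simulated_trait(self, small_dataset, small_grm):
        _, genotypes, _, traits, truth = small_dataset
        y = traits.phenotype("ADG")
        X, _ = traits.fixed_design()
        idx = np.random.default_rng(23).permutation(len(y))
        tr, va = idx[:400], idx[400:]
        res = GBLUPModel(y[tr], X[tr], small_grm, tr, va).fit()
        r = np.corrcoef(res.dgv, truth.breeding_values[va, 0])[0, 1]
        assert r > 0.5


class TestBayesPredict:
    def test_dgv_formula_hand_case(self):
        assert dgv_from_effects([[1, 2]], [0.5, -0.25])[0] == pytest.approx(0.0)

    def test_null_trait_gives_flat_dgvs(self):
        rng = np.random.default_rng(24)
        g = _independent_geno(rng, 300, 400)
        y = rng.standard_normal(300)
        from panelgp.bayes import PriorSpec
        prior = PriorSpec(pi=0.995, chain_length=1200, burn_in=300, seed=6)
        res = bayes_train_predict("B", g, y[:250], np.ones((250, 1)),
                                  np.arange(250), np.arange(250, 300), prior=prior)
        assert res.dgv.std() < 0.2 * y.std()

    def test_bayescpi_recovers_sparsity_level(self):
        rng = np.random.default_rng(25)
        n, m = 500, 2000
        g = _independent_geno(rng, n, m)
        qtl = rng.choice(m, 20, replace=False)
        x = g.values[:, qtl].astype(float)
        tbv = x @ (np.sqrt(0.02) / x.std(axis=0))
        y = tbv + rng.standard_normal(n) * np.sqrt(max(1e-9, 1 - tbv.var()))
        from panelgp.bayes import PriorSpec
        prior = PriorSpec(pi=0.5, chain_length=3000, burn_in=1000, seed=7)
        res = bayes_train_predict("Cpi", g, y[:450], np.ones((450, 1)),
                                  np.arange(450), np.arange(450, 500), prior=prior)
        assert 0.95 <= res.pi < 1.0


    def test_doubling_chain_length_is_stable(self, small_dataset):
        """DGV-vs-TBV correlation moves < 0.02 when the chain doubles."""
        _, genotypes, _, traits, truth = small_dataset
        y = traits.phenotype("ADG")
        X, _ = traits.fixed_design()
        tr, va = np.arange(400), np.arange(400, 500)
        from panelgp.bayes import PriorSpec
        cors = []
        for chain in (2000, 4000):
            prior = PriorSpec(pi=0.995, chain_length=chain, burn_in=500, seed=9)
            res = bayes_train_predict("B", genotypes, y[tr], X[tr], tr, va,
                                      prior=prior)
            cors.append(np.corrcoef(res.dgv, truth.breeding_values[va, 0])[0, 1])
        assert abs(cors[1] - cors[0]) < 0.02


class TestAdjustPhenotypes:
    def test_no_fixed_effects_center_only(self):
        y = np.array([1., 2., 3., 4.])
        adj = adjust_phenotypes(y, np.ones((4, 1)))
        np.testing.assert_allclose(adj, y - y.mean())

    def test_planted_sex_effect_fully_removed(self):
        rng = np.random.default_rng(26)
        sex = rng.integers(0, 2, 500)
        y = 10.0 * sex + rng.standard_normal(500)
        X = np.column_stack([np.ones(500), sex])
        adj = adjust_phenotypes(y, X)
        assert abs(adj[sex == 0].mean() - adj[sex == 1].mean()) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(27)
        X = np.column_stack([np.ones(100), rng.standard_normal((100, 3))])
        y = rng.standard_normal(100)
        adj = adjust_phenotypes(y, X)
        np.testing.assert_allclose(X.T @ adj, 0.0, atol=1e-8)

    def test_collinear_columns_named(self):
        X = np.column_stack([np.ones(50), np.arange(50), 2 * np.arange(50)])
        with pytest.raises(ValueError, match="covar_b"):
            adjust_phenotypes(np.zeros(50), X,
                              column_names=["intercept", "covar_a", "covar_b"])


class TestSchemes:
    def test_kfold_partitions_exactly(self):
        sch = make_scheme(103, "kfold", k=5, n_replicates=4, seed=1)
        for rep in range(4):
            labels = sch.folds[rep]
            sizes = np.bincount(labels, minlength=5)
            assert sizes.sum() == 103
            assert sizes.max() - sizes.min() <= 1
        seen = [tuple(tr) for _, _, tr, va in sch.splits()]
        assert len(seen) == 20

    def test_same_seed_reproduces_scheme(self):
        a = make_scheme(50, "kfold", k=5, n_replicates=2, seed=9)
        b = make_scheme(50, "kfold", k=5, n_replicates=2, seed=9)
        np.testing.assert_array_equal(a.folds, b.folds)

    def test_year_split(self):
        by = np.array([2010, 2012, 2014, 2015])
        sch = make_scheme(4, "year_split", birth_year=by)
        _, _, tr, va = next(sch.splits())
        assert list(tr) == [0, 1] and list(va) == [2, 3]

    def test_one_sided_year_split_rejected(self):
        with pytest.raises(ValueError):
            make_scheme(3, "year_split", birth_year=np.array([2010, 2011, 2012]))


class TestMetrics:
    def test_perfect_prediction(self):
        x = np.array([1., 2., 3., 4.])
        assert accuracy(x, x, 1.0) == pytest.approx(1.0)
        assert bias_slope(x, x) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        rng = np.random.default_rng(28)
        x = rng.standard_normal(2000)
        y = 0.3 * x + rng.standard_normal(2000) * np.sqrt(1 - 0.09)
        r = np.corrcoef(x, y)[0, 1]
        assert accuracy(x, y, 0.36) == pytest.approx(r / 0.6)

    def test_doubled_target_doubles_slope(self):
        x = np.array([0., 1., 2., 3.])
        assert bias_slope(x, 2 * x) == pytest.approx(2.0)

    def test_sign_preserved(self):
        x = np.array([1., 2., 3.])
        assert accuracy(x, -x, 1.0) == pytest.approx(-1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(29)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert accuracy(3.7 * x, y, 0.5) == pytest.approx(accuracy(x, y, 0.5))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedValueError):
            bias_slope(np.ones(5), np.arange(5.))
        with pytest.raises(ValueError):
            accuracy(np.arange(5.), np.arange(5.), 0.0)


@pytest.fixture(scope="module")
def tiny_run():
    cfg = ExperimentConfig(
        sim=SimConfig(n_individuals=300, chromosome_lengths_bp=(3_000_000,) * 3,
                      marker_density_per_mb=60, seed=5, maf_floor=0.02,
                      traits=("ADG", "LW"), h2={"ADG": 0.4, "LW": 0.38},
                      genetic_corr=0.8),
        traits=("ADG",), methods=("GBLUP",), gwas_fraction=0.01,
        use_bayesb=False, cv_k=3, cv_replicates=2, n_genes=60, seed=5)
    return run_experiment(cfg)


class TestExperiment:
    def test_results_schema(self, tiny_run):
        summary, per_fold, panel, ctx = tiny_run
        assert set(summary.columns) >= {"trait", "method", "panel", "scheme",
                                        "accuracy", "bias"}
        assert set(summary.panel) == {"full", "lowdensity"}
        assert len(panel) > 0
        for flag in panel.provenance.values():
            assert flag.dtype == bool

    def test_averaging_order_folds_then_replicates(self, tiny_run):
        summary, per_fold, *_ = tiny_run
        sub = per_fold[(per_fold.panel == "full")]
        manual = (sub.groupby("replicate")["accuracy"]
                  .mean()                        # over folds within replicate
                  .mean())                       # over replicates
        got = summary[(summary.panel == "full")]["accuracy"].iloc[0]
        assert got == pytest.approx(manual)

    def test_identity_panel_reproduces_full_density(self, small_dataset, small_grm):
        """A panel containing every marker must predict exactly like the chip."""
        _, genotypes, _, traits, _ = small_dataset
        y = traits.phenotype("ADG")
        X, _ = traits.fixed_design()
        idx = np.arange(len(y))
        tr, va = idx[:400], idx[400:]
        full = GBLUPModel(y[tr], X[tr], small_grm, tr, va).fit()
        panel_grm = build_grm(genotypes)        # identity panel
        low = GBLUPModel(y[tr], X[tr], panel_grm, tr, va).fit()
        np.testing.assert_allclose(full.dgv, low.dgv, rtol=1e-10)
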