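"""QC filters, allele statistics, LD and the masking harness."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, spearmanr

from panelgp.datatypes import GenotypeMatrix, MarkerMap
from panelgp.qc import (EmptyResultError, QCThresholds, UndefinedValueError,
                        apply_qc, compute_maf, fill_missing, hwe_chisq_p,
                        imputation_accuracy, ld_decay_curve, ld_r2)
from panelgp.simdata import SimConfig, simulate_genotypes


def _geno(values, missing=None):
    values = np.asarray(values, dtype=np.int8)
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    ids = np.array([f"i{k}" for k in range(values.shape[0])], dtype=object)
    return GenotypeMatrix(values, np.asarray(missing, dtype=bool), ids)


def _map(n, chrom=1, spacing=1000):
    return MarkerMap(np.array([f"s{j}" for j in range(n)], dtype=object),
                     np.full(n, chrom), np.arange(1, n + 1) * spacing,
                     np.full(n, "A", dtype=object), np.full(n, "B", dtype=object))


class TestMAF:
    @pytest.mark.parametrize("column, missing, expected", [
        ([0, 0, 0, 0], None, 0.0),
        ([1, 1, 1, 1], None, 0.5),
        ([0, 1, 2, 2, 0], [False] * 4 + [True], 0.375),  # 5/8 counted -> MAF 3/8
    ])
    def test_hand_counts(self, column, missing, expected):
        assert compute_maf(column, missing) == pytest.approx(expected)

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            compute_maf([0, 1], [True, True])


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        col = np.repeat([0, 1, 2], [25, 50, 25])
        assert hwe_chisq_p(col) == pytest.approx(1.0)

    def test_hand_computed_chisq(self):
        # 10/10/10 at f = 0.5: expected 7.5/15/7.5 -> chi2 = 2·(2.5²/7.5) + 5²/15
        col = np.repeat([0, 1, 2], [10, 10, 10])
        stat = 2 * (2.5 ** 2 / 7.5) + 5 ** 2 / 15
        assert hwe_chisq_p(col) == pytest.approx(chi2.sf(stat, 1))

    def test_all_heterozygotes_fail_filter(self):
        # n heterozygotes give chi-squared = n exactly
        assert hwe_chisq_p(np.ones(100, dtype=int)) == pytest.approx(chi2.sf(100, 1))
        assert hwe_chisq_p(np.ones(100, dtype=int)) < 1e-6

    def test_monomorphic_convention(self):
        assert hwe_chisq_p([0, 0, 0, 0]) == 1.0


class TestApplyQC:
    def test_zero_thresholds_remove_nothing(self):
        rng = np.random.default_rng(0)
        g = _geno(rng.integers(0, 3, (30, 15)))
        t = QCThresholds(0.0, 0.0, 0.0, 0.0)
        out, mm, report = apply_qc(g, _map(15), t)
        assert report.n_markers_out == 15 and report.n_individuals_out == 30

    def test_planted_low_maf_snp_removed(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 3, (200, 10))
        vals[:, 3] = 0
        vals[0, 3] = 1              # MAF = 1/400 = 0.0025 < 0.01
        out, mm, report = apply_qc(_geno(vals), _map(10))
        assert report.n_markers_removed_maf == 1
        assert "s3" not in set(mm.marker_id)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        n, m = 120, 40
        vals = rng.integers(0, 3, (n, m)).astype(np.int8)
        miss = rng.random((n, m)) < rng.uniform(0, 0.25, m)[None, :]
        g = _geno(vals, miss)
        t = QCThresholds(0.9, 0.05, 1e-3, 0.92)
        out, mm, _ = apply_qc(g, _map(m), t)

        # independent reimplementation, criterion by criterion
        dos = vals.astype(float)
        dos[miss] = np.nan
        keep_i = [i for i in range(n) if 1 - np.isnan(dos[i]).mean() > 0.92]
        sub = dos[keep_i]
        keep_j = []
        for j in range(m):
            col = sub[:, j]
            obs = col[~np.isnan(col)]
            if len(obs) / len(sub) <= 0.9 or len(obs) == 0:
                continue
            f = obs.sum() / (2 * len(obs))
            if min(f, 1 - f) <= 0.05:
                continue
            if hwe_chisq_p(obs) <= 1e-3:
                continue
            keep_j.append(f"s{j}")
        assert set(mm.marker_id) == set(keep_j)
        assert out.n_individuals == len(keep_i)

    def test_everything_filtered_raises(self):
        g = _geno(np.zeros((40, 4), dtype=int))     # all monomorphic
        with pytest.raises(EmptyResultError):
            apply_qc(g, _map(4))


class TestFillMissing:
    def test_no_missing_unchanged(self):
        g = _geno([[0, 1], [2, 1]])
        np.testing.assert_array_equal(fill_missing(g).values, g.values)

    def test_modal_fill_and_tie_break(self):
        vals = np.array([[0], [0], [0], [0]], dtype=np.int8)
        miss = np.array([[False], [False], [False], [True]])
        assert fill_missing(_geno(vals, miss)).values[3, 0] == 0
        # tie 2x code 1 vs 2x code 2 -> lower code wins
        vals = np.array([[1], [1], [2], [2], [0]], dtype=np.int8)
        miss = np.array([[False]] * 4 + [[True]])
        vals[4] = 0
        assert fill_missing(_geno(vals, miss)).values[4, 0] == 1


class TestLD:
    def test_identical_columns(self):
        x = np.array([0, 1, 2, 1, 0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_hand_computed_four_individuals(self):
        x = np.array([0., 1., 2., 1.])
        y = np.array([0., 0., 2., 2.])
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(x, y) == pytest.approx(r * r)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedValueError):
            ld_r2([1, 1, 1], [0, 1, 2])

    def test_independent_columns_bias_is_one_over_n(self):
        rng = np.random.default_rng(3)
        n = 10_000
        vals = [ld_r2(rng.integers(0, 3, n), rng.integers(0, 3, n))
                for _ in range(50)]
        assert np.mean(vals) == pytest.approx(1 / n, abs=5e-5)

    def test_decay_curve_matches_all_pairs_brute_force(self):
        cfg = SimConfig(n_individuals=150, chromosome_lengths_bp=(2_000_000,),
                        marker_density_per_mb=100, seed=4, maf_floor=0.02,
                        traits=("ADG",), h2={"ADG": 0.4}, genetic_corr=1.0)
        g, mm = simulate_genotypes(cfg)
        curve = ld_decay_curve(g, mm, max_dist_bp=500_000, n_bins=10)
        sums = np.zeros(10)
        counts = np.zeros(10)
        edges = np.linspace(0, 500_000, 11)
        m = len(mm)
        for a in range(m):
            for b in range(a + 1, m):
                d = mm.position_bp[b] - mm.position_bp[a]
                if d > 500_000 or mm.chromosome[a] != mm.chromosome[b]:
                    continue
                k = min(np.searchsorted(edges, d, side="left"), 10) - 1
                try:
                    sums[max(k, 0)] += ld_r2(g.values[:, a], g.values[:, b])
                    counts[max(k, 0)] += 1
                except UndefinedValueError:
                    pass
        np.testing.assert_array_equal(curve.n_pairs, counts)
        np.testing.assert_allclose(curve.mean_r2, sums / counts, rtol=1e-10)

    def test_decay_is_monotone_on_mosaic_data(self):
        cfg = SimConfig(n_individuals=400, chromosome_lengths_bp=(5_000_000,) * 2,
                        marker_density_per_mb=60, seed=6, maf_floor=0.05,
                        traits=("ADG",), h2={"ADG": 0.4}, genetic_corr=1.0)
        g, mm = simulate_genotypes(cfg)
        curve = ld_decay_curve(g, mm, max_dist_bp=2_000_000, n_bins=15)
        ok = curve.n_pairs > 0
        rho, _ = spearmanr(np.arange(15)[ok], curve.mean_r2[ok])
        assert rho <= 0

    def test_single_marker_map_raises(self):
        g = _geno([[0], [1], [2]])
        with pytest.raises(UndefinedValueError):
            ld_decay_curve(g, _map(1))


class TestImputationAccuracy:
    def test_perfect_and_zero(self):
        g = _geno([[0, 1], [2, 1]])
        mask = np.array([[True, False], [False, True]])
        assert imputation_accuracy(g, g, mask) == 1.0
        wrong = _geno([[2, 0], [0, 0]])
        assert imputation_accuracy(g, wrong, mask) == 0.0

    def test_empty_mask_rejected(self):
        g = _geno([[0, 1]])
        with pytest.raises(ValueError):
            imputation_accuracy(g, g, np.zeros((1, 2), dtype=bool))

    def test_modal_fill_matches_analytic_expectation(self):
        rng = np.random.default_rng(8)
        n, m = 800, 60
        freqs = rng.uniform(0.1, 0.5, m)
        vals = rng.binomial(2, freqs[None, :], (n, m)).astype(np.int8)
        truth = _geno(vals.copy())
        mask = rng.random((n, m)) < 0.05
        hidden = vals.copy()
        observed_missing = mask.copy()
        g_masked = GenotypeMatrix(hidden, observed_missing, truth.individual_ids)
        filled = fill_missing(g_masked)
        acc = imputation_accuracy(truth, filled, mask)
        # expectation: the modal-genotype frequency averaged over markers
        expected = np.mean([max(np.bincount(vals[~mask[:, j], j], minlength=3))
                            / (~mask[:, j]).sum() for j in range(m)])
        assert acc == pytest.approx(expected, abs=0.02)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 2), min_size=2, max_size=40))
def test_maf_always_in_range(codes):
    assert 0.0 <= compute_maf(codes) <= 0.5
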