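import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from resistnet.dataio import ExpressionMatrix
from resistnet.diffexp import (
    bh_fdr,
    filter_features,
    lm_contrast,
    nb_contrast,
    pca,
    quantile_normalize,
    size_factors,
)


def _em(values, conditions, kind="count", prefix="f"):
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    cond = pd.Series(conditions, index=data.columns)
    return ExpressionMatrix(data, cond, kind)


class TestFilterFeatures:
    def test_needs_enough_samples_above_threshold(self):
        rows = [
            [11] + [0] * 9,  # 1 sample > 10: dropped (needs 2 of 10)
            [11, 11] + [0] * 8,  # kept
            [10] * 10,  # never strictly > 10: dropped
        ]
        em = _em(rows, ["A"] * 5 + ["B"] * 5)
        kept = filter_features(em)
        assert list(kept.data.index) == ["f1"]

    def test_all_zero_matrix_warns_and_empties(self, caplog):
        em = _em(np.zeros((3, 4)), ["A", "A", "B", "B"])
        with caplog.at_level("WARNING"):
            out = filter_features(em)
        assert out.data.empty
        assert "filter" in caplog.text


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        em = _em(np.tile([[5], [9], [20]], (1, 4)), ["A", "A", "B", "B"])
        assert np.allclose(size_factors(em), 1.0)

    def test_doubled_column_factor_doubles(self):
        base = np.array([[5.0, 5, 10], [9, 9, 18], [20, 20, 40]])
        em = _em(base, ["A", "B", "B"])
        s = size_factors(em)
        assert s.iloc[2] / s.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 500, size=(50, 6)).astype(float)
        em = _em(mat, ["A"] * 3 + ["B"] * 3)
        s = size_factors(em).to_numpy()
        # independent oracle
        ref = np.array([np.prod(row) ** (1 / 6) for row in mat])
        raw = np.array([np.median(mat[:, j] / ref) for j in range(6)])
        expected = raw / np.prod(raw) ** (1 / 6)
        assert np.allclose(s, expected)

    def test_error_without_all_positive_feature(self):
        em = _em([[0, 1, 2], [3, 0, 5]], ["A", "B", "B"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(em)
        assert size_factors(em, pseudo_reference=True).notna().all()


class TestNbContrast:
    def test_all_zero_feature_has_missing_stats(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(50, size=(20, 6)).astype(float)
        mat[5] = 0.0
        em = _em(mat, ["A"] * 3 + ["B"] * 3)
        res = nb_contrast(em, pair=("A", "B"))
        assert np.isnan(res.table.loc["f5", "pval"])
        assert np.isnan(res.table.loc["f5", "qval"])
        assert res.table["pval"].drop("f5").notna().all()

    def test_swapping_conditions_flips_sign(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson([[30], [300], [90]] * 10, size=(30, 6)).astype(float)
        em = _em(mat, ["A"] * 3 + ["B"] * 3)
        ab = nb_contrast(em, pair=("A", "B"))
        ba = nb_contrast(em, pair=("B", "A"))
        assert np.allclose(ab.log2fc, -ba.log2fc, equal_nan=True)
        assert np.allclose(ab.pval, ba.pval, equal_nan=True)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(100, size=(25, 6)).astype(float)
        em = _em(mat, ["A", "A", "A", "B", "B", "B"])
        perm = ["s4", "s1", "s5", "s0", "s2", "s3"]
        em2 = em.subset_samples(perm)
        r1 = nb_contrast(em, pair=("A", "B"))
        r2 = nb_contrast(em2, pair=("A", "B"))
        assert np.allclose(r1.log2fc, r2.log2fc, atol=1e-8)

    def test_common_scaling_leaves_log2fc_unchanged(self):
        rng = np.random.default_rng(4)
        mat = rng.poisson(80, size=(25, 6)).astype(float)
        em = _em(mat, ["A"] * 3 + ["B"] * 3)
        r1 = nb_contrast(em, pair=("A", "B"))
        s = size_factors(em) * 3.0
        r2 = nb_contrast(em, pair=("A", "B"), factors=s)
        assert np.allclose(r1.log2fc, r2.log2fc, atol=1e-6)


class TestQuantileNormalize:
    def test_columns_share_multiset_after(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 2, size=20)
        mat = np.column_stack([rng.permutation(base) for _ in range(4)])
        em = _em(mat, ["A", "A", "B", "B"], kind="intensity")
        out = quantile_normalize(em)
        ref = np.sort(out.data.iloc[:, 0].to_numpy())
        for j in range(1, 4):
            assert np.allclose(np.sort(out.data.iloc[:, j].to_numpy()), ref)

    def test_sorted_columns_equal_reference(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(10, 2, size=(20, 4))
        em = _em(mat, ["A", "A", "B", "B"], kind="intensity")
        out = quantile_normalize(em)
        ref = np.sort(mat, axis=0).mean(axis=1)
        for j in range(4):
            assert np.allclose(np.sort(out.data.iloc[:, j].to_numpy()), ref)

    def test_matches_independent_reference_implementation(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(8, 1, size=(20, 4))
        em = _em(mat, ["A", "A", "B", "B"], kind="intensity")
        out = quantile_normalize(em).data.to_numpy()
        # oracle: classic mean-quantile normalisation, no ties, no missing
        ref = np.sort(mat, axis=0).mean(axis=1)
        expect = np.empty_like(mat)
        for j in range(4):
            expect[np.argsort(mat[:, j]), j] = ref
        assert np.allclose(out, expect)

    def test_missing_left_missing(self):
        mat = np.array([[1.0, 2, 3], [4, np.nan, 6], [7, 8, 9], [2, 3, 4.0]])
        em = _em(mat, ["A", "B", "B"], kind="intensity")
        out = quantile_normalize(em)
        assert np.isnan(out.data.iloc[1, 1])
        assert out.data.notna().sum().sum() == 11

    def test_single_sample_rejected(self):
        em = _em([[1.0], [2.0]], ["A"], kind="intensity")
        with pytest.raises(ValueError):
            quantile_normalize(em)


class TestLmContrast:
    def test_identical_groups_give_zero_fc(self):
        mat = np.tile([[5.0], [7.0], [9.0]], (1, 6))
        em = _em(mat, ["A"] * 3 + ["B"] * 3, kind="intensity")
        res = lm_contrast(em, pair=("A", "B"))
        assert np.allclose(res.log2fc, 0.0)

    def test_unmoderated_equals_classical_t(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(8, 1, size=(40, 8))
        em = _em(mat, ["A"] * 4 + ["B"] * 4, kind="intensity")
        res = lm_contrast(em, pair=("A", "B"), moderate=False)
        for i in range(40):
            t, p = stats.ttest_ind(mat[i, 4:], mat[i, :4], equal_var=True)
            assert res.table["stat"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert res.table["pval"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_sparse_protein_missing_stats(self):
        mat = np.random.default_rng(0).normal(8, 1, size=(5, 6))
        mat[0, [1, 2, 4, 5]] = np.nan  # one observation per group
        em = _em(mat, ["A"] * 3 + ["B"] * 3, kind="intensity")
        res = lm_contrast(em, pair=("A", "B"))
        assert np.isnan(res.table["pval"].iloc[0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(0, 1, size=(1000, 6))
        em = _em(mat, ["A"] * 3 + ["B"] * 3, kind="intensity")
        res = lm_contrast(em, pair=("A", "B"))
        assert stats.kstest(res.pval.dropna(), "uniform").pvalue > 0.01


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        base_a, base_b = np.full(30, 1.0), np.full(30, 5.0)
        mat = np.column_stack([base_a, base_a, base_b, base_b])
        em = _em(mat + np.random.default_rng(0).normal(0, 1e-6, mat.shape),
                 ["A", "A", "B", "B"], kind="intensity")
        scores, frac = pca(em, 2)
        pc1 = scores["PC1"]
        assert np.sign(pc1.iloc[0]) == np.sign(pc1.iloc[1]) != np.sign(pc1.iloc[2])
        assert frac[0] > 0.999

    def test_variance_fractions_non_increasing(self):
        rng = np.random.default_rng(1)
        em = _em(rng.normal(size=(30, 6)), ["A"] * 3 + ["B"] * 3, kind="intensity")
        _, frac = pca(em, 5)
        assert np.all(np.diff(frac) <= 1e-12)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(20, 5))
        em = _em(mat, ["A"] * 3 + ["B"] * 2, kind="intensity")
        x = mat.T - mat.T.mean(axis=0)
        u, sv, vt = np.linalg.svd(x, full_matrices=False)
        assert np.allclose((u * sv) @ vt, x, atol=1e-8)
        scores, _ = pca(em, 5)
        # projecting back through the right singular vectors reproduces X
        assert np.allclose(scores.to_numpy() @ vt, x, atol=1e-8) or np.allclose(
            np.abs(scores.to_numpy() @ vt), np.abs(x), atol=1e-8
        )

    def test_too_many_components_rejected(self):
        em = _em(np.ones((4, 3)), ["A", "A", "B"], kind="intensity")
        with pytest.raises(ValueError):
            pca(em, 4)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_missing_stays_missing(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        q = bh_fdr(pvals)
        m = len(pvals)
        # oracle: literal BH step-up definition
        order = np.argsort(pvals, kind="mergesort")
        expected = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(pvals[i] * m / rank_from_top, prev)
            expected[i] = val
            prev = val
        assert np.allclose(q, expected)
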