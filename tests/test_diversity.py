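import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from barrelbiome import (
    OtuTable,
    alpha_group_test,
    bray_curtis,
    pcoa,
    permanova,
    shannon,
)

counts_strategy = st.lists(st.integers(0, 1000), min_size=2, max_size=12).filter(
    lambda v: sum(v) > 0
)


class TestShannon:
    def test_uniform_over_four(self):
        assert shannon([8, 8, 8, 8]) == pytest.approx(2.0)

    def test_single_taxon_zero(self):
        assert shannon([17, 0, 0]) == pytest.approx(0.0)

    def test_fixture_column_against_direct_summation(self, icvv_16s):
        table, _ = icvv_16s
        col = table.to_frame()["Rioja_FML0"]
        total = col.sum()
        expected = -sum(
            (c / total) * math.log2(c / total) for c in col if c > 0
        )
        assert shannon(col.to_numpy()) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])

    def test_base_switch(self):
        h_bits = shannon([3, 1], base=2)
        h_nats = shannon([3, 1], base=math.e)
        assert h_nats == pytest.approx(h_bits * math.log(2))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_permutation_and_scale_invariance(self, counts):
        h = shannon(counts)
        assert shannon(list(reversed(counts))) == pytest.approx(h, abs=1e-9)
        assert shannon([7 * c for c in counts]) == pytest.approx(h, abs=1e-9)
        k = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= math.log2(k) + 1e-12


class TestGroupTests:
    def test_textbook_pooled_t(self):
        res = alpha_group_test([3, 4, 5, 5, 6, 7], list("aaabbb"), "two_group_t")
        assert res.statistic == pytest.approx(-2.449, abs=1e-3)
        assert res.p_value == pytest.approx(0.0705, abs=1e-3)
        assert res.df == (4.0,)

    def test_sign_convention_group1_minus_group2(self):
        res = alpha_group_test([5, 5, 1, 3], ["x", "x", "y", "y"], "two_group_t")
        assert res.statistic > 0  # group1 mean larger
        assert math.isfinite(res.statistic)

    def test_zero_variance_one_group_finite_statistic(self):
        res = alpha_group_test([4, 4, 3, 5], ["a", "a", "b", "b"], "two_group_t")
        assert math.isfinite(res.statistic)
        assert res.statistic == pytest.approx(0.0)

    def test_identical_values_everywhere(self):
        res = alpha_group_test([2, 2, 2, 2], ["a", "a", "b", "b"], "two_group_t")
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        res = alpha_group_test([2, 2, 2, 2, 2, 2], list("aabbcc"), "one_way_anova")
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_anova_matches_scipy_on_regular_data(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(0)
        vals = rng.normal(size=9)
        labels = list("aaabbbccc")
        res = alpha_group_test(vals, labels, "one_way_anova")
        ref = f_oneway(vals[:3], vals[3:6], vals[6:])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_two_group_t_requires_two_levels(self):
        with pytest.raises(ValueError, match="exactly 2"):
            alpha_group_test([1, 2, 3], list("abc"), "two_group_t")

    def test_zero_residual_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            alpha_group_test([1, 2], ["a", "b"], "two_group_t")
        with pytest.raises(ValueError, match="degrees of freedom"):
            alpha_group_test([1, 2, 3], list("abc"), "one_way_anova")

    def test_welch_flag_changes_df(self):
        vals = [1.0, 2.0, 3.0, 10.0, 20.0, 30.0, 40.0]
        labels = ["a"] * 3 + ["b"] * 4
        student = alpha_group_test(vals, labels, "two_group_t", equal_var=True)
        welch = alpha_group_test(vals, labels, "two_group_t", equal_var=False)
        assert student.df != welch.df


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        t = OtuTable(("a", "b"), ("s1", "s2"), np.array([[3, 3], [5, 5]]))
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        t = OtuTable(("a", "b"), ("s1", "s2"), np.array([[4, 0], [0, 9]]))
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        t = OtuTable(("a", "b"), ("s1", "s2"), np.array([[6, 2], [2, 2]]))
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(1 / 3)

    def test_matches_formula_on_random_counts(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(6, 4))
        counts[0] += 1
        t = OtuTable(
            tuple(f"t{i}" for i in range(6)), tuple(f"s{j}" for j in range(4)), counts
        )
        dm = bray_curtis(t)
        for i in range(4):
            for j in range(4):
                x, y = counts[:, i], counts[:, j]
                expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected)
                assert 0 <= dm[f"s{i}", f"s{j}"] <= 1

    def test_all_zero_sample_rejected(self):
        t = OtuTable(("a",), ("s1", "s2"), np.array([[1, 0]]))
        with pytest.raises(ValueError, match="'s2'"):
            bray_curtis(t)


class TestPcoa:
    def test_two_samples_axis_is_half_distance(self):
        ordination = pcoa(np.array([[0.0, 0.8], [0.8, 0.0]]))
        coords = ordination.coordinates
        assert coords.shape == (2, 1)
        np.testing.assert_allclose(sorted(coords[:, 0]), [-0.4, 0.4], atol=1e-12)

    def test_three_collinear_points(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        ordination = pcoa(d)
        positive = ordination.eigenvalues[ordination.eigenvalues > 1e-9]
        assert len(positive) == 1
        axis = ordination.coordinates[:, 0]
        np.testing.assert_allclose(np.abs(axis), [1, 0, 1], atol=1e-9)
        assert axis[0] == pytest.approx(-axis[2])

    def test_euclidean_input_reconstructed_exactly(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(7, 2))
        d = squareform(pdist(points))
        coords = pcoa(d).coordinates
        recon = squareform(pdist(coords))
        assert np.abs(recon - d).max() < 1e-8

    def test_axes_ordered_and_proportions_bounded(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(6, 3))
        ordination = pcoa(squareform(pdist(points)))
        assert (np.diff(ordination.eigenvalues) <= 1e-9).all()
        assert ordination.proportion_explained.sum() <= 1 + 1e-9

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(6)
        ordination = pcoa(squareform(pdist(rng.normal(size=(5, 2)))))
        for k in range(ordination.coordinates.shape[1]):
            col = ordination.coordinates[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_agrees_with_skbio_reference(self, icvv_16s):
        table, _ = icvv_16s
        dm = bray_curtis(table)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=0)
        n_pos = ours.coordinates.shape[1]
        ref_eigs = np.asarray(ref.eigvals)[:n_pos]
        np.testing.assert_allclose(
            ours.eigenvalues[:n_pos], ref_eigs, rtol=1e-8, atol=1e-10
        )
        ref_coords = ref.samples.to_numpy()[:, :n_pos]
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(ref_coords), atol=1e-6
        )


class TestPermanova:
    @staticmethod
    def _random_dm(rng, n):
        points = rng.normal(size=(n, 3))
        return DistanceMatrix(squareform(pdist(points)), ids=[f"s{i}" for i in range(n)])

    def test_single_level_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="2 factor levels"):
            permanova(self._random_dm(rng, 4), ["a"] * 4)

    def test_empty_group_impossible_more_levels_than_samples(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="more samples than"):
            permanova(self._random_dm(rng, 3), ["a", "b", "c"])

    def test_perfect_separation_minimum_attainable_p(self):
        d = np.zeros((4, 4))
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            d[i, j] = d[j, i] = 1.0
        res = permanova(d, ["a", "a", "b", "b"])
        assert res.method == "exhaustive"
        assert math.isinf(res.pseudo_F)
        assert res.p_value == pytest.approx(2 / 6)  # label swap ties with identity

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(11)
        dm = self._random_dm(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)
        assert ours.group_sizes == {"a": 3, "b": 3, "c": 3}

    def test_exhaustive_mode_triggers_on_small_designs(self):
        rng = np.random.default_rng(12)
        res = permanova(self._random_dm(rng, 6), ["a", "a", "b", "b", "c", "c"])
        assert res.method == "exhaustive"
        assert res.n_permutations == 90  # 6!/(2!2!2!)
        assert res.p_value >= 1 / res.n_permutations

    def test_seed_determinism_monte_carlo(self):
        rng = np.random.default_rng(13)
        dm = self._random_dm(rng, 16)
        labels = (["a"] * 8) + (["b"] * 8)
        r1 = permanova(dm, labels, n_permutations=199, seed=42, max_exhaustive=10)
        r2 = permanova(dm, labels, n_permutations=199, seed=42, max_exhaustive=10)
        r3 = permanova(dm, labels, n_permutations=199, seed=43, max_exhaustive=10)
        assert r1.p_value == r2.p_value
        assert r1.method == "monte_carlo"
        assert r3.pseudo_F == r1.pseudo_F  # statistic is seed-free

    def test_null_p_values_uniform(self):
        # exhaustive p-values under label-independent data are uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(14)
        labels = ["a"] * 5 + ["b"] * 5
        pvals = [
            permanova(self._random_dm(rng, 10), labels).p_value for _ in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_fixture_time_factor_reaches_resolution_floor_scale(self, icvv_16s):
        # 2 samples per level at 4 levels: exhaustive space 8!/2^4 = 2520
        from barrelbiome import factor_subset

        table, meta = icvv_16s
        ids, labels = factor_subset(meta, "time")
        dm = bray_curtis(table).filter(ids)
        res = permanova(dm, labels, seed=0)
        assert res.method == "exhaustive"
        assert res.n_permutations == 2520
        assert res.p_value <= 3 / 35  # documented attainable range at this n
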