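import numpy as np
import pandas as pd
import pytest

from succnet import clr_transform, relative_abundance
from succnet.diversity import (
    alpha_metrics,
    anosim,
    bray_curtis_matrix,
    compare_groups,
    convergence_to_reference,
    pcoa,
    permanova,
)

from conftest import make_table, two_blob_distances


class TestAlpha:
    def test_equal_abundances_symmetric(self):
        t = make_table([[25, 25, 25, 25]])
        a = alpha_metrics(t).iloc[0]
        assert a["shannon_ln"] == pytest.approx(np.log(4))
        assert a["gini_simpson"] == pytest.approx(0.75)
        assert a["observed_otus"] == 4

    def test_chao1_equals_observed_without_rare_otus(self):
        t = make_table([[5, 9, 14]])  # no singletons or doubletons
        a = alpha_metrics(t).iloc[0]
        assert a["chao1"] == a["observed_otus"] == 3

    def test_chao1_bias_corrected_hand_value(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = [[1, 1, 1, 1, 2, 2, 5, 7, 9, 30]]
        a = alpha_metrics(make_table(counts)).iloc[0]
        assert a["chao1"] == pytest.approx(12.0)

    def test_column_permutation_invariant(self, synth_default):
        table, _ = synth_default
        a = alpha_metrics(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_otus)
        shuffled = make_table(table.counts[:, perm])
        b = alpha_metrics(shuffled)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError):
            alpha_metrics(make_table([[0, 0]]))


class TestGroupComparison:
    def test_perfect_separation(self):
        vals = [1, 2, 3, 101, 102, 103]
        res = compare_groups(vals, ["a"] * 3 + ["b"] * 3)
        assert res.kw_p < 0.05
        assert res.letters["a"] != res.letters["b"]

    def test_constant_values_degenerate(self):
        res = compare_groups([5.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.kw_statistic == 0.0
        assert res.kw_p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "a", "a"])

    def test_bh_is_monotone(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=40)
        labels = np.repeat(list("abcdefgh"), 5)
        res = compare_groups(vals, labels)
        df = res.pairwise.sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-12).all()
        assert (df["q"] >= df["p"] - 1e-12).all()

    def test_dunn_z_hand_check(self):
        # two groups, no ties: z = (mr_a - mr_b) / sqrt(n(n+1)/12 * (1/na+1/nb))
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        res = compare_groups(vals, ["a"] * 3 + ["b"] * 3)
        row = res.pairwise.iloc[0]
        se = np.sqrt(6 * 7 / 12 * (1 / 3 + 1 / 3))
        assert abs(row["z"]) == pytest.approx(3.0 / se)


class TestBrayCurtis:
    def test_identity_and_maximum(self):
        t = make_table([[1, 0], [0, 1]])
        bc = bray_curtis_matrix(relative_abundance(t))
        assert bc.iloc[0, 0] == 0.0
        assert bc.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = make_table([[4, 2, 4], [2, 2, 6]])
        bc = bray_curtis_matrix(relative_abundance(t))
        assert bc.iloc[0, 1] == pytest.approx(0.2)

    def test_bounded_symmetric(self, synth_default):
        table, _ = synth_default
        bc = bray_curtis_matrix(relative_abundance(table)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert bc.min() >= 0 and bc.max() <= 1
        assert np.allclose(np.diag(bc), 0)


class TestPcoa:
    def test_collinear_points_recover_line(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        coords = res.coordinates.to_numpy()[:, 0]
        np.testing.assert_allclose(sorted(np.diff(sorted(coords))), [1.0, 1.0], atol=1e-9)

    def test_all_zero_distances(self):
        res = pcoa(pd.DataFrame(np.zeros((4, 4))))
        assert res.coordinates.to_numpy().size == 0 or \
            np.allclose(res.coordinates.to_numpy(), 0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0.0, 1.0], [2.0, 0.0]]))

    def test_euclidean_embedding_reproduces_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(pd.DataFrame(d))
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_matches_reference_implementation(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = pcoa(pd.DataFrame(d))
        ref = skbio_ord.pcoa(DistanceMatrix(d))
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        np.testing.assert_allclose(ours.eigenvalues[:4], ref_eig[:4], atol=1e-8)


class TestPermutationTests:
    def test_permanova_separated_clusters_minimal_p(self):
        d = two_blob_distances(n_per=8, sep=50.0, seed=1)
        labels = ["a"] * 8 + ["b"] * 8
        f, p = permanova(d, labels, n_perm=999, seed=0)
        assert p == pytest.approx(0.001)
        assert f > 10

    def test_permanova_matches_reference(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix
        d = two_blob_distances(n_per=6, sep=3.0, seed=2)
        labels = ["a"] * 6 + ["b"] * 6
        f, _ = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_dist.permanova(DistanceMatrix(d.to_numpy()), grouping=labels,
                                   permutations=99)
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_permanova_identical_samples_nan(self):
        d = pd.DataFrame(np.zeros((6, 6)))
        with pytest.warns(UserWarning):
            f, p = permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert np.isnan(f)

    def test_permanova_reproducible_and_bounded(self):
        d = two_blob_distances(n_per=5, sep=2.0, seed=4)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova(d, labels, n_perm=199, seed=42)
        r2 = permanova(d, labels, n_perm=199, seed=42)
        assert r1 == r2
        assert r1[1] >= 1.0 / 200

    def test_anosim_perfect_separation(self):
        d = two_blob_distances(n_per=6, sep=100.0, seed=5)
        r, p = anosim(d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.01)

    def test_anosim_all_equal_distances(self):
        d = pd.DataFrame(np.ones((6, 6)) - np.eye(6))
        r, _ = anosim(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert r == pytest.approx(0.0)

    def test_anosim_matches_reference(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix
        d = two_blob_distances(n_per=6, sep=2.0, seed=6)
        labels = ["a"] * 6 + ["b"] * 6
        r, _ = anosim(d, labels, n_perm=99, seed=0)
        ref = skbio_dist.anosim(DistanceMatrix(d.to_numpy()), grouping=labels,
                                permutations=99)
        assert r == pytest.approx(ref["test statistic"], rel=1e-10)


class TestConvergence:
    def test_reference_sample_at_centroid(self):
        t = make_table([[1, 2, 3], [3, 2, 1]], groups=["ND", "1y"])
        clr = clr_transform(t, 1.0)
        conv = convergence_to_reference(clr, t.metadata, "ND")
        assert conv["s0"] == pytest.approx(0.0)
        assert conv["s1"] > 0

    def test_unit_offset_distance_one(self):
        t = make_table([[1, 1], [1, 1]], groups=["ND", "1y"])
        clr = clr_transform(t, 1.0)
        clr.values.loc["s1"] = [2 ** -0.5, -(2 ** -0.5)]  # unit vector, sums to 0
        conv = convergence_to_reference(clr, t.metadata, "ND")
        assert conv["s1"] == pytest.approx(1.0)

    def test_recovery_groups_closer_to_reference(self, synth_default):
        table, truth = synth_default
        clr = clr_transform(table, 1.0)
        conv = convergence_to_reference(clr, table.metadata, "ND")
        stages = pd.Series(truth.stage_labels)
        chaos_mean = conv[stages == "chaos"].mean()
        recovery_mean = conv[stages == "recovery"].mean()
        assert recovery_mean < chaos_mean

    def test_missing_reference_errors(self, tiny_table):
        clr = clr_transform(tiny_table, 1.0)
        with pytest.raises(ValueError):
            convergence_to_reference(clr, tiny_table.metadata, "ND")
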