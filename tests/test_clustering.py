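import numpy as np
import pandas as pd
import pytest

from emtsig import clustering
from emtsig.clustering import (
    annotate_gene_clusters,
    composition_table,
    connectivity_index,
    correlation_distance,
    dunn_index,
    hcluster,
    select_k,
    silhouette_width,
    stability_scan,
)
from emtsig.diffexp import SignatureSet
from emtsig.matrix_io import ExpressionMatrix

import oracles


def _matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )
    return ExpressionMatrix(df, "zscore")


# the worked 1-D example: two tight pairs far apart
POINTS_1D = np.array([[0.0], [1.0], [10.0], [11.0]])
LABELS_1D = np.array([1, 1, 2, 2])
D_1D = np.abs(POINTS_1D - POINTS_1D.T)


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        m = _matrix([[1, 2, 3], [1, 2, 3], [3, 1, 2]])
        d = correlation_distance(m, axis="gene")
        assert d.loc["g0", "g1"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        m = _matrix([[1, 2, 3], [3, 2, 1], [1, 3, 2]])
        d = correlation_distance(m, axis="gene")
        assert d.loc["g0", "g1"] == pytest.approx(2.0, abs=1e-12)

    def test_constant_item_named(self):
        m = _matrix([[1, 1, 1], [1, 2, 3], [2, 1, 3]])
        with pytest.raises(ValueError, match="g0"):
            correlation_distance(m, axis="gene")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_pairwise_formula(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(10, 8)))
        d = correlation_distance(m, axis="gene").to_numpy()
        for i in range(10):
            for j in range(10):
                expected = 1.0 - oracles.pearson(m.data.iloc[i], m.data.iloc[j])
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestHcluster:
    def test_two_blobs_recovered_at_k2(self):
        d = pd.DataFrame(D_1D, index=list("abcd"), columns=list("abcd"))
        out = hcluster(d, k_values=[2])
        labels = out.labels(2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_k_equals_n_all_singletons(self):
        d = pd.DataFrame(D_1D, index=list("abcd"), columns=list("abcd"))
        out = hcluster(d, k_values=[4])
        assert len(set(out.labels(4))) == 4

    def test_complete_linkage_heights_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        from scipy.spatial.distance import cdist

        ids = [str(i) for i in range(20)]
        d = pd.DataFrame(cdist(x, x), index=ids, columns=ids)
        out = hcluster(d)
        heights = out.merge_tree[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_cuts_nest_as_k_grows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4))
        from scipy.spatial.distance import cdist

        d = pd.DataFrame(cdist(x, x), index=[str(i) for i in range(30)], columns=[str(i) for i in range(30)])
        out = hcluster(d, k_values=range(2, 8))
        for k in range(2, 7):
            coarse, fine = out.labels_at_k[k], out.labels_at_k[k + 1]
            mapping = {}
            for c_fine, c_coarse in zip(fine, coarse):
                assert mapping.setdefault(c_fine, c_coarse) == c_coarse

    def test_nan_distance_rejected(self):
        d = pd.DataFrame(D_1D.copy(), index=list("abcd"), columns=list("abcd"))
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            hcluster(d)


class TestStabilityIndices:
    def test_worked_example_connectivity_zero(self):
        assert connectivity_index(D_1D, LABELS_1D, L=1) == 0.0

    def test_worked_example_dunn_nine(self):
        assert dunn_index(D_1D, LABELS_1D) == pytest.approx(9.0)

    def test_worked_example_silhouette(self):
        assert silhouette_width(D_1D, LABELS_1D) == pytest.approx(0.8997, abs=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_indices_match_naive_references(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 2))
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        labels = rng.integers(1, 4, size=15)
        if len(set(labels)) < 2:
            labels[0] = 1 + (labels[0] % 3)
        L = int(rng.integers(1, 6))
        assert connectivity_index(d, labels, L) == pytest.approx(
            oracles.connectivity(d, labels, L), abs=1e-10
        )
        assert dunn_index(d, labels) == pytest.approx(oracles.dunn(d, labels), abs=1e-10)
        assert silhouette_width(d, labels) == pytest.approx(
            oracles.silhouette(d, labels), abs=1e-10
        )

    def test_separation_limit(self):
        """As between-block separation grows, silhouette -> 1 and connectivity -> 0."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 5))
        prev_sil = -1.0
        for gap in (2.0, 20.0, 200.0):
            x = base.copy()
            x[10:] += gap
            from scipy.spatial.distance import cdist

            d = cdist(x, x)
            labels = np.array([1] * 10 + [2] * 10)
            sil = silhouette_width(d, labels)
            assert sil >= prev_sil
            prev_sil = sil
        assert prev_sil > 0.99
        assert connectivity_index(d, labels, L=5) == 0.0


class TestSelectK:
    def test_unanimous_winner_recommended(self):
        profile = pd.DataFrame(
            {"connectivity": [5.0, 1.0, 7.0], "dunn": [0.5, 2.0, 0.1], "silhouette": [0.3, 0.8, 0.1]},
            index=pd.Index([2, 3, 4], name="k"),
        )
        k, ranks, tie = select_k(profile)
        assert k == 3
        assert not tie

    def test_tie_goes_to_smaller_k_and_flags(self):
        profile = pd.DataFrame(
            {"connectivity": [1.0, 2.0], "dunn": [1.0, 2.0], "silhouette": [0.5, 0.5]},
            index=pd.Index([2, 3], name="k"),
        )
        k, ranks, tie = select_k(profile)
        assert k == 2
        assert tie

    def test_planted_three_blocks_recovered(self):
        rng = np.random.default_rng(3)
        # three mutually distinct block profiles with pairwise correlation -0.5
        profiles = np.repeat(np.array([[3.0, 0.0, -3.0], [-3.0, 3.0, 0.0], [0.0, -3.0, 3.0]]), 20, axis=0)
        x = np.repeat(profiles, 10, axis=1) + rng.normal(0, 1.0, size=(60, 30))
        m = _matrix(x, prefix="s").data
        em = ExpressionMatrix(m, "zscore")
        profile, _ = stability_scan(em, axis="gene", k_range=range(2, 7), L=5)
        k, _, _ = select_k(profile)
        assert k == 3


class TestAnnotation:
    sig = SignatureSet(up=[f"u{i}" for i in range(100)], down=[f"d{i}" for i in range(100)])

    def _labels(self, layout):
        """layout: dict cluster -> (n_up, n_down)."""
        genes, labels = [], []
        for cluster, (n_up, n_down) in layout.items():
            genes += [f"u{i}" for i in range(n_up)] if cluster == 1 else [f"u{50 + i}" for i in range(n_up)]
            genes += [f"d{i}" for i in range(n_down)] if cluster == 1 else [f"d{50 + i}" for i in range(n_down)]
            labels += [cluster] * (n_up + n_down)
        return pd.Series(labels, index=genes)

    @pytest.mark.parametrize(
        "n_up,n_down,expected",
        [(91, 9, "EMT-up"), (50, 50, "partial-EMT"), (0, 100, "EMT-down")],
    )
    def test_threshold_labels(self, n_up, n_down, expected):
        labels = self._labels({1: (n_up, n_down)})
        ann = annotate_gene_clusters(labels, self.sig)
        assert ann.loc[1, "label"] == expected
        assert ann.loc[1, "frac_up"] == pytest.approx(n_up / (n_up + n_down))

    def test_invariant_to_relabeling(self):
        labels = self._labels({1: (40, 5), 2: (3, 30)})
        ann1 = annotate_gene_clusters(labels, self.sig)
        swapped = labels.map({1: 2, 2: 1})
        ann2 = annotate_gene_clusters(swapped, self.sig)
        assert ann1.loc[1, "label"] == ann2.loc[2, "label"]
        assert ann1.loc[2, "label"] == ann2.loc[1, "label"]

    def test_non_signature_gene_rejected(self):
        labels = pd.Series([1], index=["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            annotate_gene_clusters(labels, self.sig)


class TestComposition:
    def test_all_in_one_cluster(self):
        labels = pd.Series([1] * 6 + [2] * 4, index=[f"s{i}" for i in range(10)])
        subtype = pd.Series(["X"] * 6 + ["Y"] * 4, index=labels.index)
        comp = composition_table(labels, subtype)
        assert comp["col_pct"].loc[1, "X"] == pytest.approx(100.0)

    def test_even_split(self):
        labels = pd.Series([1, 2, 1, 2], index=list("abcd"))
        subtype = pd.Series(["X"] * 4, index=labels.index)
        comp = composition_table(labels, subtype)
        assert comp["col_pct"].loc[1, "X"] == pytest.approx(50.0)

    def test_percentages_recompute_from_counts(self):
        rng = np.random.default_rng(5)
        labels = pd.Series(rng.integers(1, 4, 50), index=[f"s{i}" for i in range(50)])
        subtype = pd.Series(rng.choice(list("XYZ"), 50), index=labels.index)
        comp = composition_table(labels, subtype)
        np.testing.assert_allclose(comp["row_pct"].sum(axis=1), 100.0)
        np.testing.assert_allclose(comp["col_pct"].sum(axis=0), 100.0)
        recomputed = comp["counts"].div(comp["counts"].sum(axis=1), axis=0) * 100
        pd.testing.assert_frame_equal(comp["row_pct"], recomputed)

    def test_unlabeled_sample_rejected(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        subtype = pd.Series(["X"], index=["a"])
        with pytest.raises(ValueError, match="b"):
            composition_table(labels, subtype)
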