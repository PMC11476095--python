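"""Rank-product test, PCA, UPGMA dendrogram, and Newick export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from biofilmassay import multivariate as mv


# ---------------------------------------------------------------------------
# 24 h / 48 h ratios
# ---------------------------------------------------------------------------

def _biorep_summary(values):
    rows = []
    for iso, bio, tp, od in values:
        rows.append({"isolate_id": iso, "factor": "baseline", "level": np.nan,
                     "timepoint_h": tp, "bio_rep": bio, "mean_od": od,
                     "n_wells": 3, "sd_od": 0.0})
    return pd.DataFrame(rows)


class TestRatio2448:
    def test_basic_ratios(self):
        df = _biorep_summary([("A", 1, 24.0, 0.2), ("A", 1, 48.0, 0.4),
                              ("B", 1, 24.0, 0.3), ("B", 1, 48.0, 0.3)])
        out = mv.ratio_24_48(df)
        assert dict(zip(out["isolate_id"], out["ratio"])) == pytest.approx(
            {"A": 2.0, "B": 1.0})

    def test_zero_denominator_dropped(self):
        df = _biorep_summary([("A", 1, 24.0, 0.0), ("A", 1, 48.0, 0.4),
                              ("B", 1, 24.0, 0.2), ("B", 1, 48.0, 0.4)])
        out = mv.ratio_24_48(df)
        assert list(out["isolate_id"]) == ["B"]

    def test_mixed_conditions_rejected(self):
        df = _biorep_summary([("A", 1, 24.0, 0.2)])
        df2 = df.assign(factor="ph", level=9.0)
        with pytest.raises(ValueError, match="single condition"):
            mv.ratio_24_48(pd.concat([df, df2]))


# ---------------------------------------------------------------------------
# Rank product
# ---------------------------------------------------------------------------

def exhaustive_rank_product(X):
    """Independent enumeration oracle for the one-sided rank-product p-values.

    The null rank of an item in each replicate is uniform over that
    replicate's observed rank values; the null rank product is enumerated over
    the full Cartesian grid.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    out = {}
    for name, ranks in (("up", rankdata(-X, axis=0, method="average")),
                        ("down", rankdata(X, axis=0, method="average"))):
        observed = ranks.prod(axis=1)
        columns = [list(ranks[:, j]) for j in range(k)]
        null = [math.prod(combo) for combo in itertools.product(*columns)]
        out[name] = np.array([
            (sum(nv <= obs * (1 + 1e-12) for nv in null) + 1) / (len(null) + 1)
            for obs in observed])
    return out


class TestRankProduct:
    def test_top_ranked_isolate_worked_example(self):
        # isolate 0 has the largest ratio in both of 2 replicates among 5
        X = np.array([[5.0, 5.0], [1, 1], [2, 2], [3, 3], [4, 4]])
        out = mv.rank_product_test(X, B=10_000, seed=1).set_index("isolate_id")
        row = out.loc["0"]
        assert row["rp_up"] == pytest.approx(1.0)
        # only (1,1) of the 25 enumerable rank pairs gives RP <= 1
        assert row["p_up"] == pytest.approx(2 / 26)
        assert row["direction"] == "up"

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(1, 4))
            X = np.round(rng.normal(1.0, 0.5, size=(n, k)), 2)  # rounding makes ties
            out = mv.rank_product_test(X, B=10_000, seed=7).set_index("isolate_id")
            oracle = exhaustive_rank_product(X)
            for i in range(n):
                assert out.loc[str(i), "p_up"] == pytest.approx(oracle["up"][i])
                assert out.loc[str(i), "p_down"] == pytest.approx(oracle["down"][i])

    def test_all_tied_ratios_never_significant(self):
        out = mv.rank_product_test(np.ones((6, 3)), B=5_000, seed=3)
        assert not out["significant"].any()
        assert (out["p_value"] == 1.0).all()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        out1 = mv.rank_product_test(X, B=500, seed=11).set_index("isolate_id")
        out2 = mv.rank_product_test(
            pd.DataFrame(X[perm], index=[str(i) for i in perm]),
            B=500, seed=11).set_index("isolate_id")
        for i in range(8):
            assert out2.loc[str(i), "p_value"] == pytest.approx(out1.loc[str(i), "p_value"])

    def test_p_value_floor(self):
        out = mv.rank_product_test(np.random.default_rng(1).normal(size=(4, 2)),
                                   B=100, seed=5)
        assert (out["p_value"] >= 1 / (16 + 1)).all()  # exact null here has 16 points

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mv.rank_product_test(np.ones((3, 2)), B=0, seed=1)
        with pytest.raises(ValueError):
            mv.rank_product_test(np.ones((3, 2)), B=10, seed=None)
        with pytest.raises(ValueError):
            mv.rank_product_test(np.ones((1, 2)), B=10, seed=1)

    def test_bh_correction_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        raw = mv.rank_product_test(X, B=2_000, seed=9)
        bh = mv.rank_product_test(X, B=2_000, seed=9, correction="bh")
        assert (bh["p_value"] >= raw["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_variance_in_one_column_only(self):
        X = np.column_stack([np.arange(5.0), np.ones(5), np.ones(5) * 2])
        res = mv.pca(X, n_components=1, standardize=False)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 4))
        res = mv.pca(X, n_components=4, standardize=False)
        cov = np.cov(X, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.variance_fraction, eigvals / eigvals.sum(),
                                   rtol=1e-10)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_duplicate_rows_identical_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3))
        X2 = np.vstack([X, X[0]])
        res = mv.pca(X2, n_components=2, standardize=False)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[-1], atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        res = mv.pca(X, n_components=4, standardize=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        res = mv.pca(X, n_components=3)
        for col in res.loadings.columns:
            loads = res.loadings[col]
            assert loads.iloc[int(np.argmax(np.abs(loads)))] > 0

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(6.0), [1.0, 2.0, 3.0])  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            mv.pca(X, n_components=2, standardize=False)


# ---------------------------------------------------------------------------
# UPGMA + Newick
# ---------------------------------------------------------------------------

def random_ultrametric(rng, n):
    """Random ultrametric distance matrix built from an explicit merge tree."""
    clusters = [{i} for i in range(n)]
    D = np.zeros((n, n))
    height = 0.0
    merges = []
    while len(clusters) > 1:
        height += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[a, b] = D[b, a] = height
        merged = clusters[i] | clusters[j]
        merges.append((frozenset(merged), height))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return D, merges


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dend = mv.upgma_from_distances(D, ["A", "B", "C"])
        assert [(m.a, m.b, m.height) for m in dend.merges] == [(0, 1, 1.0), (2, 3, 4.0)]

    def test_two_points(self):
        dend = mv.upgma(np.array([[0.0], [3.0]]), labels=["x", "y"])
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(3.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        dend = mv.upgma(X)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_recovers_generating_ultrametric_tree(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            D, merges = random_ultrametric(rng, n)
            labels = [f"L{i}" for i in range(n)]
            dend = mv.upgma_from_distances(D, labels)
            expected = {(frozenset(labels[i] for i in members), round(h, 9))
                        for members, h in merges}
            assert dend.leaf_sets() == expected

    def test_matches_scipy_average_linkage(self):
        # cross-check merge heights against scipy on tie-free random data
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        dend = mv.upgma(X)
        Z = scipy_average(pdist(X))
        np.testing.assert_allclose(sorted(dend.heights), sorted(Z[:, 2]), rtol=1e-10)

    def test_lexicographic_tie_break(self):
        # three mutually equidistant points: first merge must involve 'a'
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        dend = mv.upgma_from_distances(D, ["c", "a", "b"])
        first = dend.members()[3]
        assert first == frozenset({"a", "b"})

    def test_nan_distance_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            mv.upgma_from_distances(D, ["a", "b"])


@pytest.fixture(scope="module")
def dend():
    D = np.array([
        [0.0, 1.0, 5.0, 5.0],
        [1.0, 0.0, 5.0, 5.0],
        [5.0, 5.0, 0.0, 2.0],
        [5.0, 5.0, 2.0, 0.0],
    ])
    return mv.upgma_from_distances(D, ["w", "x", "y", "z"])


class TestCutClusters:

    def test_k_equals_n(self, dend):
        labels = mv.cut_clusters(dend, 4)
        assert len(set(labels.assignments.values())) == 4

    def test_k_equals_one(self, dend):
        labels = mv.cut_clusters(dend, 1)
        assert set(labels.assignments.values()) == {1}

    def test_production_ranked_clusters(self, dend):
        production = {"w": 5.0, "x": 4.0, "y": 0.5, "z": 0.4}
        labels = mv.cut_clusters(dend, 2, production)
        assert labels.quality == {1: "best", 2: "worst"}
        assert labels.cluster_members()[1] == {"w", "x"}

    def test_ambiguous_cut_rejected(self):
        D = np.full((3, 3), 1.0)
        np.fill_diagonal(D, 0.0)
        dend = mv.upgma_from_distances(D, ["a", "b", "c"])
        with pytest.raises(ValueError, match="impossible"):
            mv.cut_clusters(dend, 2)

    def test_k_out_of_range(self, dend):
        with pytest.raises(ValueError):
            mv.cut_clusters(dend, 0)
        with pytest.raises(ValueError):
            mv.cut_clusters(dend, 5)


class TestNewick:
    def test_round_trip_lossless(self):
        rng = np.random.default_rng(9)
        for n in (2, 5, 8):
            X = rng.normal(size=(n, 3))
            dend = mv.upgma(X, labels=[f"iso{i}" for i in range(n)])
            text = mv.to_newick(dend)
            assert text.endswith(";")
            assert mv.newick_leaf_sets(text) == dend.leaf_sets()

    def test_patristic_distance_equals_merge_height(self):
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dend = mv.upgma_from_distances(D, ["A", "B", "C"])
        sets = mv.newick_leaf_sets(mv.to_newick(dend))
        assert (frozenset({"A", "B"}), 1.0) in sets
        assert (frozenset({"A", "B", "C"}), 4.0) in sets
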