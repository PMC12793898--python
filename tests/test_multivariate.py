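from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from epimsap import multivariate as mv
from epimsap.errors import AnalysisError, ConfigError
from epimsap.types import DistanceMatrix


def dm_of(x, metric="EUCLIDEAN"):
    return mv.pairwise_distances(np.asarray(x, float), metric)


# ---------------------------------------------------------------------------
# independent oracles

def permanova_f_oracle(d2, labels):
    """One-way pseudo-F from raw squared distances (direct group sums)."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_p_exhaustive_oracle(d2, labels):
    """Exact p by enumerating every assignment of samples to group sizes."""
    labels = np.asarray(labels)
    n = len(labels)
    levels, counts = np.unique(labels, return_counts=True)
    assert len(levels) == 2, "oracle written for two groups"
    f_obs = permanova_f_oracle(d2, labels)
    total = exceed = 0
    for members in combinations(range(n), counts[0]):
        lab = np.full(n, levels[1], dtype=object)
        lab[list(members)] = levels[0]
        total += 1
        if permanova_f_oracle(d2, lab) >= f_obs - 1e-12:
            exceed += 1
    return exceed / total


class TestPairwiseDistances:
    def test_identical_rows_distance_zero(self):
        d = dm_of([[1, 2, 3], [1, 2, 3]])
        assert d.d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        d = dm_of([[0, 0], [3, 4]])
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_jaccard_frozen_example(self):
        # rows (1,1,0) vs (1,0,1): union 3, intersection 1 -> 2/3
        d = dm_of([[1, 1, 0], [1, 0, 1]], "JACCARD")
        assert d.d[0, 1] == pytest.approx(2.0 / 3.0)

    def test_jaccard_rejects_non_binary(self):
        with pytest.raises(AnalysisError):
            dm_of([[0.5, 1], [1, 0]], "JACCARD")

    def test_simple_matching_counts_mismatch_fraction(self):
        d = dm_of([[1, 1, 0, 0], [1, 0, 1, 0]], "SIMPLE_MATCHING")
        assert d.d[0, 1] == pytest.approx(0.5)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigError):
            dm_of([[0, 1]], "MANHATTAN")


class TestPermanova:
    def test_p_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            n = int(rng.integers(6, 9))
            n_a = int(rng.integers(2, n - 1))
            labels = np.array(["a"] * n_a + ["b"] * (n - n_a))
            x = rng.normal(size=(n, 3)) + np.where(labels == "a", 0.8, 0.0)[:, None]
            d = dm_of(x)
            res = mv.permanova(d, {"g": labels}, exhaustive=True)
            p_oracle = permanova_p_exhaustive_oracle(d.d ** 2, labels)
            assert res.terms[0].p == pytest.approx(p_oracle, abs=1e-12)

    def test_f_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a"] * 10 + ["b"] * 8)
        d = dm_of(rng.normal(size=(18, 5)))
        res = mv.permanova(d, {"g": labels}, n_perm=9, seed=0)
        assert res.terms[0].F == pytest.approx(permanova_f_oracle(d.d ** 2, labels), rel=1e-10)

    def test_f_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        labels = ["a"] * 7 + ["b"] * 7 + ["c"] * 6
        d = dm_of(rng.normal(size=(20, 4)))
        ours = mv.permanova(d, {"g": np.array(labels)}, n_perm=9, seed=0)
        theirs = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(d.d, d.samples), grouping=labels, permutations=9)
        assert ours.terms[0].F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_scale_invariance_of_f_r2_p(self):
        rng = np.random.default_rng(1)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        d = dm_of(rng.normal(size=(12, 3)))
        d10 = DistanceMatrix(d.samples, 10.0 * d.d)
        r1 = mv.permanova(d, {"g": labels}, n_perm=99, seed=3)
        r2 = mv.permanova(d10, {"g": labels}, n_perm=99, seed=3)
        assert r1.terms[0].F == pytest.approx(r2.terms[0].F)
        assert r1.terms[0].R2 == pytest.approx(r2.terms[0].R2)
        assert r1.terms[0].p == r2.terms[0].p

    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(2)
        site = np.repeat(["x", "y", "z"], 8)
        season = np.tile(["d", "w"], 12)
        d = dm_of(rng.normal(size=(24, 6)))
        res = mv.permanova(d, {"site": site, "season": season}, n_perm=9, seed=0)
        total_r2 = sum(t.R2 for t in res.terms) + res.r2_residual
        assert total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_identically_distributed_groups_give_small_r2(self):
        rng = np.random.default_rng(3)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        d = dm_of(rng.normal(size=(60, 10)))
        res = mv.permanova(d, {"g": labels}, n_perm=99, seed=0)
        assert res.terms[0].R2 < 0.06

    def test_single_level_term_rejected(self):
        d = dm_of(np.eye(4))
        with pytest.raises(AnalysisError):
            mv.permanova(d, {"g": np.array(["a"] * 4)}, n_perm=9)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        labels = np.array(["a"] * 8 + ["b"] * 8)
        d = dm_of(rng.normal(size=(16, 4)))
        p1 = mv.permanova(d, {"g": labels}, n_perm=199, seed=11).terms[0].p
        p2 = mv.permanova(d, {"g": labels}, n_perm=199, seed=11).terms[0].p
        assert p1 == p2


class TestPcoa:
    def test_embedding_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        ordn = mv.pcoa(dm_of(pts))
        re_d = mv.pairwise_distances(ordn.coordinates).d
        np.testing.assert_allclose(re_d, dm_of(pts).d, atol=1e-9)

    def test_matches_principal_components_up_to_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 4))
        ordn = mv.pcoa(dm_of(x))
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        pcs = xc @ vt.T
        k = min(ordn.n_axes, pcs.shape[1])
        for j in range(k):
            dot = np.abs(ordn.coordinates[:, j] @ pcs[:, j])
            assert dot == pytest.approx(np.linalg.norm(ordn.coordinates[:, j]) * np.linalg.norm(pcs[:, j]), rel=1e-8)

    def test_matches_scikit_bio_eigenvalues(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        d = dm_of(rng.normal(size=(10, 3)))
        ours = mv.pcoa(d)
        theirs = skbio_ord.pcoa(skbio_dist.DistanceMatrix(d.d, d.samples))
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[: ordn_len(ours)], atol=1e-8)

    def test_two_samples_distance_two(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        ordn = mv.pcoa(d)
        np.testing.assert_allclose(np.abs(ordn.coordinates[:, 0]), [1.0, 1.0], atol=1e-12)

    def test_zero_matrix_gives_zero_eigenvalues(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ordn = mv.pcoa(d)
        assert np.allclose(ordn.eigenvalues, 0.0)

    def test_centroid_at_origin(self, monitoring_dataset):
        from epimsap import msap_scoring
        x = msap_scoring.encode_matrix(monitoring_dataset["sm"])
        ordn = mv.pcoa(mv.pairwise_distances(x))
        np.testing.assert_allclose(ordn.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(3)
        ordn = mv.pcoa(dm_of(rng.normal(size=(9, 5))))
        assert (np.diff(ordn.eigenvalues) <= 1e-9).all()

    def test_lingoes_removes_negative_eigenvalues(self):
        # a non-Euclidean dissimilarity (sqrt of Jaccard is Euclidean, raw is not always)
        rng = np.random.default_rng(4)
        x = (rng.random((8, 12)) < 0.4).astype(float)
        d = mv.pairwise_distances(x, "JACCARD")
        ordn = mv.pcoa(d, correction="LINGOES")
        assert (ordn.eigenvalues >= -1e-8).all()


def ordn_len(o):
    return len(o.eigenvalues)


class TestPermdisp:
    def test_equal_scatter_gives_small_f(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 2))
        x = np.vstack([a, -a])  # mirrored identical scatter
        labels = np.array(["a"] * 20 + ["b"] * 20)
        f, p = mv.permdisp(dm_of(x), labels, n_perm=199, seed=1)
        assert p > 0.5

    def test_inflated_group_detected(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(20, 3))
            b = 3.0 * rng.normal(size=(20, 3))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            _, p = mv.permdisp(dm_of(np.vstack([a, b])), labels, n_perm=199, seed=seed)
            hits += p <= 0.05
        assert hits >= 27  # >= 90% power at this effect size

    def test_singleton_group_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(9, 2))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        f, p = mv.permdisp(dm_of(x), labels, n_perm=99, seed=0)
        assert np.isfinite(f)


class TestRdaPartition:
    def test_term_identical_to_response_explains_everything(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = mv.rda_partition(y, {"t": y.copy()})
        assert out["combined"] == pytest.approx(1.0)

    def test_orthogonal_balanced_factors_order_invariant(self):
        rng = np.random.default_rng(0)
        a = np.repeat(["x", "y"], 8)
        b = np.tile(["u", "v"], 8)
        y = rng.normal(size=(16, 3))
        o1 = mv.rda_partition(y, {"a": a, "b": b})
        o2 = mv.rda_partition(y, {"b": b, "a": a})
        assert o1["a"] == pytest.approx(o2["a"], abs=1e-9)
        assert o1["b"] == pytest.approx(o2["b"], abs=1e-9)

    def test_duplicated_term_adds_nothing(self):
        rng = np.random.default_rng(1)
        a = np.repeat(["x", "y"], 6)
        y = rng.normal(size=(12, 2))
        out = mv.rda_partition(y, {"a": a, "a2": a})
        assert out["a2"] == pytest.approx(0.0, abs=1e-9)


class TestDbrda:
    def test_predictor_equal_to_axis_one_recovers_its_fraction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 4))
        d = dm_of(x)
        emb = mv.pcoa(d)
        pred = pd.DataFrame({"axis1": emb.coordinates[:, 0]})
        res = mv.dbrda(d, pred, n_perm=9, seed=0)
        assert res.constrained_fraction == pytest.approx(emb.explained[0], abs=1e-9)

    def test_constant_predictor_named_in_error(self):
        d = dm_of(np.random.default_rng(1).normal(size=(8, 2)))
        with pytest.raises(AnalysisError, match="flat"):
            mv.dbrda(d, pd.DataFrame({"flat": np.ones(8)}), n_perm=9)

    def test_null_predictor_p_roughly_uniform(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = dm_of(rng.normal(size=(20, 5)))
            pred = pd.DataFrame({"z": rng.normal(size=20)})
            res = mv.dbrda(d, pred, n_perm=99, seed=seed)
            rejections += res.p_overall <= 0.05
        assert 0 <= rejections <= 12  # 5% nominal, binomial slack


class TestGroupCentroids:
    def test_singleton_group_is_its_own_centroid(self):
        from epimsap.types import OrdinationResult
        ordn = OrdinationResult("PCOA", ["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]),
                                np.ones(2), np.ones(2) / 2)
        cents = mv.group_centroids(ordn, np.array(["g1", "g2"]))
        np.testing.assert_allclose(cents["g1"], [1.0, 2.0])

    def test_symmetric_points_midpoint(self):
        from epimsap.types import OrdinationResult
        ordn = OrdinationResult("PCOA", ["a", "b"], np.array([[1.0, 0.0], [-1.0, 2.0]]),
                                np.ones(2), np.ones(2) / 2)
        cents = mv.group_centroids(ordn, np.array(["g", "g"]))
        np.testing.assert_allclose(cents["g"], [0.0, 1.0])

    def test_matches_direct_mean_oracle(self):
        from epimsap.types import OrdinationResult
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(30, 4))
        groups = rng.choice(["a", "b", "c"], size=30)
        ordn = OrdinationResult("PCOA", [f"s{i}" for i in range(30)], coords,
                                np.ones(4), np.ones(4) / 4)
        cents = mv.group_centroids(ordn, groups)
        for g in "abc":
            np.testing.assert_allclose(cents[g], coords[groups == g].mean(axis=0), atol=1e-12)
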