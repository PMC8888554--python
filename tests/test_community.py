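"""Community statistics: diversity, Bray-Curtis, PERMANOVA, ordination,
environmental fitting, VIF screening, transformation choice, UPGMA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from holodepth import community as comm
from holodepth.tables import AsvTable


def asv(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = [f"a{j}" for j in range(rows.shape[1])]
    kind = "relabund" if np.allclose(rows.sum(axis=1), 1) else "counts"
    return AsvTable(pd.DataFrame(rows, index=ids, columns=cols), kind=kind)


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        t = asv([np.full(10, 7)])
        res = comm.alpha_diversity(t)
        assert res["richness"].iloc[0] == 10
        assert res["shannon"].iloc[0] == pytest.approx(np.log(10))
        assert res["inv_simpson"].iloc[0] == pytest.approx(10.0)

    def test_single_taxon(self):
        res = comm.alpha_diversity(asv([[9, 0, 0]]))
        assert res["richness"].iloc[0] == 1
        assert res["shannon"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        res = comm.alpha_diversity(asv([[2, 1, 1]]))
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert res["shannon"].iloc[0] == pytest.approx(expected)

    def test_empty_sample_flagged(self):
        res = comm.alpha_diversity(asv([[0, 0, 0], [1, 1, 1]]))
        assert np.isnan(res["shannon"].iloc[0])
        assert res["richness"].iloc[0] == 0


class TestBrayCurtis:
    def test_reference_values(self):
        t = asv([[2, 1, 0], [1, 1, 1], [0, 0, 4], [2, 1, 0]])
        d = comm.bray_curtis(t).values()
        assert d[0, 1] == pytest.approx(1 / 3)
        assert d[0, 2] == pytest.approx(1.0)  # disjoint supports
        assert d[0, 3] == pytest.approx(0.0)  # identical samples

    def test_properties_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            t = asv(rng.integers(0, 50, size=(6, 12)) * 1.0)
            d = comm.bray_curtis(t).values()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            comm.bray_curtis(asv([[0, 0], [0, 0], [1, 2]]))


class TestPermanova:
    @pytest.fixture()
    def clustered(self):
        # unbalanced groups so no label permutation reproduces the
        # observed partition (a balanced complement would tie the F)
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (10, 10)) + 10
        b = rng.normal(6, 1, (9, 10)) + 10
        t = asv(np.vstack([a, b]))
        labels = np.array(["g1"] * 10 + ["g2"] * 9)
        return comm.bray_curtis(t), labels

    def test_separated_clusters_minimum_p(self, clustered):
        dist, labels = clustered
        res = comm.permanova(dist, labels, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)
        assert 0 < res.r2 < 1

    def test_matches_scikit_bio_oracle(self, clustered):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dist, labels = clustered
        res = comm.permanova(dist, labels, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(dist.values(), ids=dist.sample_ids)
        ref = skbio_stats.permanova(dm, labels, permutations=999, seed=0)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_exhaustive_enumeration_tiny(self):
        rng = np.random.default_rng(8)
        t = asv(rng.integers(1, 30, (4, 6)) * 1.0)
        dist = comm.bray_curtis(t)
        labels = np.array(["x", "x", "y", "y"])
        res = comm.permanova(dist, labels, n_perm="exhaustive")
        d2 = dist.values() ** 2
        f_obs, _ = comm._pseudo_f(d2, labels)
        from itertools import permutations

        hits = sum(
            comm._pseudo_f(d2, labels[list(p)])[0] >= f_obs - 1e-12
            for p in permutations(range(4))
        )
        assert res.p == pytest.approx(hits / 24)

    def test_partition_conservation(self, clustered):
        dist, labels = clustered
        d2 = dist.values() ** 2
        n = d2.shape[0]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        f, r2 = comm._pseudo_f(d2, labels)
        # reconstruct among+within from F and R2 and compare to total
        ss_among = r2 * ss_total
        ss_within = ss_total - ss_among
        a = 2
        assert f == pytest.approx((ss_among / (a - 1)) / (ss_within / (n - a)))

    def test_relabeling_invariance(self, clustered):
        dist, labels = clustered
        perm = np.random.default_rng(1).permutation(len(labels))
        d2 = dist.values()
        reordered = comm.DistanceMatrix(
            pd.DataFrame(d2[np.ix_(perm, perm)],
                         index=np.array(dist.sample_ids)[perm],
                         columns=np.array(dist.sample_ids)[perm]),
        )
        r1 = comm.permanova(dist, labels, n_perm=99, seed=3)
        r2 = comm.permanova(reordered, labels[perm], n_perm=99, seed=3)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)

    def test_singleton_groups_rejected(self):
        t = asv(np.random.default_rng(0).integers(1, 9, (3, 4)) * 1.0)
        with pytest.raises(ValueError, match="singleton"):
            comm.permanova(comm.bray_curtis(t), np.array(["a", "b", "c"]))


class TestOrdination:
    def test_line_geometry_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        dist = comm.DistanceMatrix(pd.DataFrame(d, index=list("abcd"),
                                                columns=list("abcd")), "euclidean")
        scores = comm.ordinate(dist, k=1)
        rec = np.abs(scores.to_numpy()[:, 0][:, None] - scores.to_numpy()[:, 0][None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_sign_canonicalisation_reproducible(self):
        rng = np.random.default_rng(2)
        t = asv(rng.integers(1, 40, (6, 10)) * 1.0)
        dist = comm.bray_curtis(t)
        s1 = comm.ordinate(dist, 2)
        s2 = comm.ordinate(dist, 2)
        pd.testing.assert_frame_equal(s1, s2)
        assert s1.iloc[np.flatnonzero(np.abs(s1.iloc[:, 0]) > 1e-12)[0], 0] > 0

    def test_square_recovered_up_to_rotation(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dist = comm.DistanceMatrix(pd.DataFrame(d, index=list("abcd"),
                                                columns=list("abcd")), "euclidean")
        scores = comm.ordinate(dist, 2).to_numpy()
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, scores)
        assert disparity < 1e-12

    def test_excessive_dimensions_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        d = np.abs(x[:, None] - x[None, :])
        dist = comm.DistanceMatrix(pd.DataFrame(d, index=list("abc"),
                                                columns=list("abc")), "euclidean")
        with pytest.raises(ValueError, match="positive eigenvalues"):
            comm.ordinate(dist, k=2)


class TestEnvfit:
    @pytest.fixture()
    def scores(self):
        rng = np.random.default_rng(3)
        return pd.DataFrame(rng.normal(size=(20, 2)), columns=["PCo1", "PCo2"],
                            index=[f"s{i}" for i in range(20)])

    def test_variable_equal_to_axis(self, scores):
        env = pd.DataFrame({"v": scores["PCo1"]}, index=scores.index)
        res = comm.envfit(scores, env, n_perm=99, seed=0)[0]
        assert res.r2 == pytest.approx(1.0)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.direction[1]) == pytest.approx(0.0, abs=1e-6)

    def test_r2_matches_least_squares_oracle(self, scores):
        rng = np.random.default_rng(4)
        v = rng.normal(size=20)
        env = pd.DataFrame({"v": v}, index=scores.index)
        res = comm.envfit(scores, env, n_perm=49, seed=0)[0]
        sc = scores.to_numpy() - scores.to_numpy().mean(axis=0)
        vc = v - v.mean()
        beta, *_ = np.linalg.lstsq(sc, vc, rcond=None)
        r2_oracle = 1 - ((vc - sc @ beta) ** 2).sum() / (vc**2).sum()
        assert res.r2 == pytest.approx(r2_oracle, abs=1e-10)
        assert 0 <= res.r2 <= 1

    def test_constant_variable_flagged(self, scores):
        env = pd.DataFrame({"v": np.ones(20)}, index=scores.index)
        res = comm.envfit(scores, env, n_perm=9, seed=0)[0]
        assert np.isnan(res.r2)
        assert res.p == 1.0

    def test_gradient_driver_attains_top_r2(self, metadata15, hma_dataset):
        table, _, _ = hma_dataset
        dist = comm.bray_curtis(table.relative_abundance())
        scores = comm.ordinate(dist, 2)
        env = metadata15.set_index("sample_id")[
            ["latitude", "longitude", "depth", "year"]]
        fits = comm.envfit(scores, env, n_perm=49, seed=0)
        best = max(fits, key=lambda f: f.r2)
        assert best.variable == "depth"


class TestVif:
    def test_orthogonal_variables_all_one(self):
        n = 64
        x = np.arange(n)
        env = pd.DataFrame({
            "a": np.where(x % 2 == 0, 1.0, -1.0),
            "b": np.where((x // 2) % 2 == 0, 1.0, -1.0),
            "c": np.where((x // 4) % 2 == 0, 1.0, -1.0),
        })
        kept, vifs = comm.vif_screen(env)
        assert set(kept) == {"a", "b", "c"}
        assert all(v == pytest.approx(1.0) for k, v in vifs.items())

    def test_duplicate_variable_removed(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        env = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=30)})
        kept, _ = comm.vif_screen(env)
        assert "b" in kept
        assert len({"a", "dup"} & set(kept)) == 1

    def test_constructed_r2_gives_closed_form_vif(self):
        # x2 = x1 + noise with R^2 = 0.95 => VIF = 20, removed at threshold 10
        rng = np.random.default_rng(6)
        n = 4000
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        noise -= noise @ x1 / (x1 @ x1) * x1  # exactly orthogonal
        x2 = x1 + noise * np.sqrt((x1 @ x1) / (noise @ noise) * (0.05 / 0.95))
        env = pd.DataFrame({"x1": x1, "x2": x2, "z": rng.normal(size=n)})
        kept, vifs = comm.vif_screen(env, threshold=10)
        removed = {"x1", "x2"} - set(kept)
        assert len(removed) == 1
        assert vifs[removed.pop()] == pytest.approx(20.0, rel=0.05)


class TestTransformSelection:
    def test_single_candidate_returned(self, tiny_asv_table):
        best, scores = comm.select_transformation(
            tiny_asv_table, [1.0, 2.0, 3.0], candidates=["sqrt"])
        assert best == "sqrt"
        assert list(scores) == ["sqrt"]

    def test_constant_gradient_rejected(self, tiny_asv_table):
        with pytest.raises(ValueError, match="constant"):
            comm.select_transformation(tiny_asv_table, [1.0, 1.0, 1.0])

    def test_depth_structured_data_scores_high(self, metadata15, hma_dataset):
        table, _, _ = hma_dataset
        best, scores = comm.select_transformation(
            table, metadata15["depth"].to_numpy())
        assert scores[best] > 0.5
        rng = np.random.default_rng(0)
        _, null_scores = comm.select_transformation(
            table, rng.permutation(metadata15["depth"].to_numpy()))
        assert max(null_scores.values()) < scores[best]


class TestUpgma:
    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.5, (5, 8)) + 10
        b = rng.normal(8, 0.5, (5, 8)) + 10
        dist = comm.bray_curtis(asv(np.vstack([a, b])))
        _, labels = comm.upgma_cluster(dist, n_clusters=2)
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic distances of UPGMA on an ultrametric matrix equal it
        d = squareform(np.array([1.0, 4.0, 4.0, 4.0, 4.0, 2.0]))
        ids = list("abcd")
        dist = comm.DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))
        z = hierarchy.linkage(dist.condensed(), method="average")
        coph = hierarchy.cophenet(z)
        assert np.allclose(coph, dist.condensed())

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        dist = comm.bray_curtis(asv(rng.integers(1, 20, (7, 9)) * 1.0))
        z1, l1 = comm.upgma_cluster(dist)
        z2, l2 = comm.upgma_cluster(dist)
        assert np.array_equal(z1, z2)
        assert l1.equals(l2)

    def test_too_few_samples(self):
        dist = comm.DistanceMatrix(pd.DataFrame([[0.0]], index=["a"], columns=["a"]))
        with pytest.raises(ValueError, match=">= 2"):
            comm.upgma_cluster(dist)
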