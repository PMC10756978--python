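import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from omicsgsn import pacmap_core as pc
from omicsgsn.io_preprocess import ValidationError


def brute_force_sigmas(points):
    """Independent oracle: full sorted distance lists per point."""
    pts = np.asarray(points, float)
    n = pts.shape[0]
    sigma = np.zeros(n)
    for i in range(n):
        d = sorted(np.linalg.norm(pts[j] - pts[i]) for j in range(n) if j != i)
        sigma[i] = np.mean(d[3:6])
    return sigma


class TestScaledDistances:
    def test_colinear_sigma_hand_values(self, colinear_points):
        cache = pc.compute_sigmas(colinear_points)
        assert cache.sigma[0] == pytest.approx(5.0)       # mean(4, 5, 6)
        assert cache.sigma[1] == pytest.approx(4.0)       # mean(3, 4, 5)
        assert cache.scaled_sq_dist[0, 1] == pytest.approx(1 / 20)

    def test_symmetry_and_zero_diagonal(self, colinear_points):
        cache = pc.compute_sigmas(colinear_points)
        np.testing.assert_allclose(cache.scaled_sq_dist, cache.scaled_sq_dist.T)
        np.testing.assert_array_equal(np.diag(cache.scaled_sq_dist), 0.0)

    def test_zero_iff_coincident(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        pts[5] = pts[2]  # one duplicate pair
        cache = pc.compute_sigmas(pts)
        zeros = np.argwhere(np.isclose(cache.scaled_sq_dist, 0.0))
        for i, j in zeros:
            assert i == j or np.allclose(pts[i], pts[j])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_sigma_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(7, 30), rng.integers(2, 6)))
        cache = pc.compute_sigmas(pts)
        np.testing.assert_allclose(cache.sigma, brute_force_sigmas(pts), rtol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            pc.compute_sigmas(np.zeros((6, 2)))


class TestNeighborSelection:
    def test_zero_neighbors(self, colinear_points):
        cache = pc.compute_sigmas(colinear_points)
        assert pc.select_neighbor_pairs(colinear_points, cache, 0).shape == (0, 2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_full_sort_oracle(self, seed):
        """Neighbor pairs equal a brute-force full-sort on the scaled distance."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        pts = rng.normal(size=(n, 5))
        n_nb = int(rng.integers(1, min(8, n - 1)))
        cache = pc.compute_sigmas(pts)
        got = pc.select_neighbor_pairs(pts, cache, n_nb)
        for i in range(n):
            d = cache.scaled_sq_dist[i]
            expected = sorted(range(n), key=lambda j: (d[j], j))
            expected = [j for j in expected if j != i][:n_nb]
            mine = got[got[:, 0] == i, 1].tolist()
            assert mine == expected

    def test_tie_takes_smaller_index(self):
        # mirror-symmetric layout: point 0 has identical scaled distance to
        # points 1 (+1) and 2 (-1); the smaller index wins
        xs = [0.0, 1, -1, 2, -2, 3, -3, 4, -4]
        pts = np.column_stack([xs, np.zeros(len(xs))])
        cache = pc.compute_sigmas(pts)
        assert cache.scaled_sq_dist[0, 1] == pytest.approx(cache.scaled_sq_dist[0, 2])
        nb = pc.select_neighbor_pairs(pts, cache, 1)
        assert nb[nb[:, 0] == 0, 1][0] == 1

    def test_n_nb_too_large_rejected(self, colinear_points):
        cache = pc.compute_sigmas(colinear_points)
        with pytest.raises(ValidationError):
            pc.select_neighbor_pairs(colinear_points, cache, 10)


class TestRandomPairs:
    def test_zero_counts_empty(self, colinear_points):
        assert pc.select_midnear_pairs(colinear_points, 0).shape == (0, 2)
        nb = np.empty((0, 2), int)
        assert pc.select_further_pairs(colinear_points, nb, 0).shape == (0, 2)

    def test_seeded_determinism(self, colinear_points):
        a = pc.select_midnear_pairs(colinear_points, 3, seed=5)
        b = pc.select_midnear_pairs(colinear_points, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_midnear_never_pairs_anchor_with_itself(self, cluster_points):
        pts, _ = cluster_points
        mn = pc.select_midnear_pairs(pts, 4, seed=0)
        assert (mn[:, 0] != mn[:, 1]).all()

    def test_further_excludes_neighbors_of_anchor(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 4))
        cache = pc.compute_sigmas(pts)
        nb = pc.select_neighbor_pairs(pts, cache, 6)
        fp = pc.select_further_pairs(pts, nb, 5, seed=9)
        nb_set = {tuple(p) for p in nb}
        for a, b in fp:
            assert (a, b) not in nb_set and a != b


class TestLosses:
    def test_coincident_points_closed_forms(self):
        emb = pc.Embedding2D(["a", "b"], np.zeros((2, 2)))
        assert pc.pair_losses(emb, (0, 1), "neighbor") == pytest.approx(1 / 11)
        assert pc.pair_losses(emb, (0, 1), "midnear") == pytest.approx(1 / 10001)
        assert pc.pair_losses(emb, (0, 1), "further") == pytest.approx(0.5)

    def test_hand_evaluated_at_dt_6(self):
        emb = pc.Embedding2D(["a", "b"], np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert pc.pair_losses(emb, (0, 1), "neighbor") == pytest.approx(0.375)
        assert pc.pair_losses(emb, (0, 1), "midnear") == pytest.approx(6 / 10006)
        assert pc.pair_losses(emb, (0, 1), "further") == pytest.approx(1 / 7)

    def test_asymptotes(self):
        far = pc.Embedding2D(["a", "b"], np.array([[0.0, 0.0], [1e6, 0.0]]))
        assert pc.pair_losses(far, (0, 1), "neighbor") == pytest.approx(1.0, abs=1e-6)
        assert pc.pair_losses(far, (0, 1), "further") == pytest.approx(0.0, abs=1e-6)

    def test_monotonicity_on_grid(self):
        """NB and MN strictly increase in dt, FP strictly decreases."""
        dt = np.logspace(0, 6, 200)
        nb = dt / (10 + dt)
        mn = dt / (10000 + dt)
        fp = 1 / (1 + dt)
        assert (np.diff(nb) > 0).all()
        assert (np.diff(mn) > 0).all()
        assert (np.diff(fp) < 0).all()

    def test_total_loss_empty_pairs(self):
        emb = pc.Embedding2D(["a"], np.zeros((1, 2)))
        out = pc.total_loss(emb, pc.PairSet.empty(), pc.LossWeights(1, 1, 1))
        assert out.total == out.loss_nb_total == out.loss_mn_total == 0

    def test_single_neighbor_pair_weighted(self):
        emb = pc.Embedding2D(["a", "b"], np.array([[0.0, 0.0], [1.0, 2.0]]))
        pairs = pc.PairSet(np.array([[0, 1]]), np.empty((0, 2), int), np.empty((0, 2), int))
        out = pc.total_loss(emb, pairs, pc.LossWeights(1, 0, 0))
        assert out.total == pytest.approx(0.375)

    def test_weights_linear(self, cluster_points):
        pts, _ = cluster_points
        pairs = pc.build_pairs(pts, pc.PacmapConfig(n_nb=5, n_mn=3, n_fp=8, seed=0))
        coords = np.random.default_rng(0).normal(size=(60, 2))
        one = pc.total_loss(coords, pairs, pc.LossWeights(1, 2, 3))
        two = pc.total_loss(coords, pairs, pc.LossWeights(2, 4, 6))
        assert two.total == pytest.approx(2 * one.total)


class TestGradient:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 4))
        pairs = pc.build_pairs(pts, pc.PacmapConfig(n_nb=3, n_mn=2, n_fp=4, seed=1))
        coords = rng.normal(size=(10, 2))
        w = pc.LossWeights(2.0, 5.0, 1.0)
        analytic = pc.loss_gradient(coords, pairs, w)
        h = 1e-6
        fd = np.zeros_like(coords)
        for i in range(10):
            for d in range(2):
                cp, cm = coords.copy(), coords.copy()
                cp[i, d] += h
                cm[i, d] -= h
                fd[i, d] = (pc.total_loss(cp, pairs, w).total
                            - pc.total_loss(cm, pairs, w).total) / (2 * h)
        rel = np.abs(analytic - fd) / np.maximum(np.abs(fd), 1e-8)
        assert rel.max() < 1e-4


class TestPCAInit:
    def test_axis_aligned_2d_identity_up_to_sign(self):
        # exactly axis-decorrelated 2-D layout (diagonal sample covariance)
        pts = np.array([[2.0, 1.0], [2.0, -1.0], [-2.0, 1.0], [-2.0, -1.0],
                        [4.0, 0.0], [-4.0, 0.0]])
        emb = pc.pca_initialize(pts, scale=1.0)
        centered = pts - pts.mean(axis=0)
        for axis in range(2):
            match = (np.allclose(emb.coords[:, axis], centered[:, axis], atol=1e-8)
                     or np.allclose(emb.coords[:, axis], -centered[:, axis], atol=1e-8))
            assert match

    def test_projection_variance_matches_eigenvalues(self):
        """Per-axis variances equal the top-2 covariance eigenvalues."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        emb = pc.pca_initialize(pts, scale=1.0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(pts.T)))[::-1][:2]
        proj_var = emb.coords.var(axis=0, ddof=1)
        np.testing.assert_allclose(np.sort(proj_var)[::-1], eigvals, atol=1e-8)

    def test_identical_points_rejected(self):
        with pytest.raises(ValidationError):
            pc.pca_initialize(np.ones((5, 3)))


class TestOptimization:
    def test_clusters_embed_compactly(self, cluster_points):
        pts, labels = cluster_points
        emb = pc.pacmap_embed(pts, pc.PacmapConfig(seed=0))
        D = squareform(pdist(emb.coords))
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert D[same & off].mean() < D[~same].mean()

    def test_final_loss_below_initial(self, cluster_points):
        pts, _ = cluster_points
        cfg = pc.PacmapConfig(seed=0)
        pairs = pc.build_pairs(pts, cfg)
        init = pc.pca_initialize(pts, scale=cfg.init_scale)
        final, trace = pc.optimize_embedding(init, pairs, cfg.schedule)
        w_end = cfg.schedule.weights_at(cfg.schedule.total_iters - 1)
        assert (pc.total_loss(final.coords, pairs, w_end).total
                < pc.total_loss(init.coords, pairs, w_end).total)
        assert all(np.isfinite(t.total) for t in trace)

    def test_smoothed_loss_decreases_within_phases(self, cluster_points):
        """Within each phase the smoothed loss trace trends downward
        (transient increases below 5% allowed)."""
        pts, _ = cluster_points
        cfg = pc.PacmapConfig(seed=0)
        pairs = pc.build_pairs(pts, cfg)
        init = pc.pca_initialize(pts, scale=cfg.init_scale)
        _, trace = pc.optimize_embedding(init, pairs, cfg.schedule)
        total = np.array([t.total for t in trace])
        s = cfg.schedule
        for lo, hi in ((0, s.t1), (s.t1, s.t1 + s.t2), (s.t1 + s.t2, s.total_iters)):
            seg = total[lo:hi]
            window = 10
            smooth = np.convolve(seg, np.ones(window) / window, mode="valid")
            # Interior trend: each smoothed point at most 5% above the
            # running minimum so far.
            running_min = np.minimum.accumulate(smooth)
            assert (smooth <= 1.05 * running_min + 1e-9).all()

    def test_zero_iterations_returns_initialization(self, cluster_points):
        pts, _ = cluster_points
        cfg = pc.PacmapConfig(seed=0, schedule=pc.PhaseSchedule(t1=0, t2=0, t3=0))
        pairs = pc.build_pairs(pts, cfg)
        init = pc.pca_initialize(pts, scale=cfg.init_scale)
        final, trace = pc.optimize_embedding(init, pairs, cfg.schedule)
        np.testing.assert_array_equal(final.coords, init.coords)
        assert trace == []

    def test_determinism_bitwise(self, cluster_points):
        pts, _ = cluster_points
        a = pc.pacmap_embed(pts, pc.PacmapConfig(seed=11))
        b = pc.pacmap_embed(pts, pc.PacmapConfig(seed=11))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_translation_equivariance(self, cluster_points):
        """Translating the inputs leaves the embedding unchanged (distances
        and the centered PCA projection are translation-invariant)."""
        pts, _ = cluster_points
        a = pc.pacmap_embed(pts, pc.PacmapConfig(seed=4))
        b = pc.pacmap_embed(pts + 13.5, pc.PacmapConfig(seed=4))
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)

    def test_rotation_invariance_of_loss(self, cluster_points):
        pts, _ = cluster_points
        cfg = pc.PacmapConfig(seed=0)
        pairs = pc.build_pairs(pts, cfg)
        coords = np.random.default_rng(2).normal(size=(60, 2))
        theta = 0.73
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        w = pc.LossWeights(2, 3, 1)
        assert (pc.total_loss(coords @ rot.T, pairs, w).total
                == pytest.approx(pc.total_loss(coords, pairs, w).total))

    def test_gene_matrix_shape_contract(self, small_generated):
        _, data = small_generated
        from omicsgsn.io_preprocess import normalize_matrix
        sub = normalize_matrix(data.expression).values[:14]
        emb = pc.pacmap_embed(sub, pc.PacmapConfig(seed=0))
        assert emb.coords.shape == (14, 2)
        assert np.isfinite(emb.coords).all()


def test_embedding_tsv_roundtrip(tmp_path, cluster_points):
    pts, _ = cluster_points
    emb = pc.pacmap_embed(pts[:10], pc.PacmapConfig(n_nb=3, n_mn=2, n_fp=3, seed=0))
    p = tmp_path / "emb.tsv"
    pc.write_embedding_tsv(emb, p)
    back = pc.read_embedding_tsv(p)
    assert back.point_ids == emb.point_ids
    np.testing.assert_array_equal(back.coords, emb.coords)
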