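"""Embeddings, posterior trajectories, DiSTATIS and density fields."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from buds import (DissimilarityCube, DissimilarityMatrix, NoiseScales,
                  PosteriorSamples, density_and_contours, distatis,
                  generate_model_draw, pcoa, sample_dissimilarity_cube,
                  trajectory_paths, tsne_embed)

from conftest import euclidean_dissimilarity


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([0.0, 1.0, 2.0, 4.0])
        emb = pcoa(euclidean_dissimilarity(pts), k=3)
        # line data: one dominant positive eigenvalue
        assert emb.eigenvalues[0] > 1e-8
        assert np.all(np.abs(emb.eigenvalues[1:]) < 1e-8)
        got = emb.coords[:, 0]
        gaps = np.abs(np.diff(got))
        np.testing.assert_allclose(gaps, np.abs(np.diff(pts)), atol=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        v = np.ones((3, 3)) - np.eye(3)
        emb = pcoa(DissimilarityMatrix(values=v), k=2)
        assert emb.eigenvalues[0] == pytest.approx(emb.eigenvalues[1], rel=1e-10)

    @pytest.mark.parametrize("n,k,seed", [(10, 3, 0), (30, 4, 1), (50, 5, 2)])
    def test_gower_distances_reproduced(self, n, k, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, k))
        D = euclidean_dissimilarity(pts)
        emb = pcoa(D, k=min(k, n - 1))
        rec = euclidean_dissimilarity(emb.coords)
        np.testing.assert_allclose(rec.values, D.values, atol=1e-8)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        D = euclidean_dissimilarity(rng.standard_normal((12, 3)))
        ours = pcoa(D, k=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D.values))
        np.testing.assert_allclose(
            np.abs(ours.coords), np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-8
        )
        np.testing.assert_allclose(ours.eigenvalues, ref.eigvals[:3], atol=1e-8)

    def test_variance_percent_over_positive_eigenvalues(self):
        rng = np.random.default_rng(4)
        D = euclidean_dissimilarity(rng.standard_normal((8, 2)))
        emb = pcoa(D, k=2)
        assert emb.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(emb.pct_variance <= 100.0)

    def test_shrinks_k_with_warning(self):
        pts = np.array([0.0, 1.0, 2.0, 4.0])
        with pytest.warns(UserWarning, match="shrinking"):
            emb = pcoa(euclidean_dissimilarity(pts), k=3)
        del emb


class TestTsne:
    def test_deterministic_per_seed(self):
        D, _, _ = generate_model_draw(n=40, seed=1)
        a = tsne_embed(D, seed=3, perplexity=8)
        b = tsne_embed(D, seed=3, perplexity=8)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_gradient_order_visible_in_embedding(self):
        D, tau, _ = generate_model_draw(n=45, sigma_eps=0.1, seed=2)
        emb = tsne_embed(D, seed=0, perplexity=10)
        # project onto the embedding's dominant direction
        c = emb.coords - emb.coords.mean(axis=0)
        u = np.linalg.svd(c, full_matrices=False)[2][0]
        proj = c @ u
        assert abs(spearmanr(proj, tau).statistic) >= 0.8

    def test_rejects_large_perplexity(self):
        D, _, _ = generate_model_draw(n=20, seed=3)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(D, perplexity=7)


def _toy_samples(tau_draws, sigma=0.1, b=0.02, rho=1.0):
    T = tau_draws.shape[0]
    return PosteriorSamples(
        tau=tau_draws, alpha_tau=np.ones(T), beta_tau=np.ones(T),
        sigma_eps=np.full(T, sigma), b=np.full(T, b), rho=np.full(T, rho),
        seed=0, backend_tag="toy", oriented=True,
    )


class TestTrajectoryPaths:
    def test_identical_draws_identical_paths(self):
        tau = np.tile(np.array([0.3, 0.1, 0.9, 0.5]), (60, 1))
        paths, mode = trajectory_paths(_toy_samples(tau), n_paths=50,
                                       n_highlight=4)
        expected = np.argsort(tau[0])
        assert len(paths) == 50
        for p in paths:
            np.testing.assert_array_equal(p, expected)

    def test_mode_path_full_ordering_when_highlighting_all(self):
        rng = np.random.default_rng(0)
        tau = np.tile(rng.uniform(size=6), (20, 1))
        _, mode = trajectory_paths(_toy_samples(tau), n_paths=5, n_highlight=100)
        np.testing.assert_array_equal(mode, np.argsort(tau[0]))

    def test_grid_nearest_endpoints(self):
        tau = np.tile(np.array([0.0, 0.5, 1.0]), (10, 1))
        _, mode = trajectory_paths(_toy_samples(tau), n_paths=2, n_highlight=2)
        np.testing.assert_array_equal(mode, [0, 2])

    def test_shrinks_n_paths_with_warning(self):
        tau = np.tile(np.array([0.2, 0.8, 0.5]), (5, 1))
        with pytest.warns(UserWarning, match="shrinking"):
            paths, _ = trajectory_paths(_toy_samples(tau), n_paths=50)
        assert len(paths) == 5


class TestDissimilarityCube:
    def test_slices_satisfy_invariants(self, fitted):
        _, _, samples, _ = fitted
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(samples.n),
                                         t=20, seed=1)
        for s in range(cube.t):
            M = cube.slices[s]
            np.testing.assert_allclose(M, M.T)
            np.testing.assert_allclose(np.diag(M), 0.0)
            off = M[~np.eye(samples.n, dtype=bool)]
            assert np.all(off > 0)

    def test_reproducible_per_seed(self, fitted):
        _, _, samples, _ = fitted
        S = NoiseScales.uniform(samples.n)
        a = sample_dissimilarity_cube(samples, S, t=5, seed=9)
        b = sample_dissimilarity_cube(samples, S, t=5, seed=9)
        np.testing.assert_array_equal(a.slices, b.slices)

    def test_small_sigma_limit_approaches_latent_distances(self):
        tau = np.tile(np.array([0.1, 0.4, 0.8, 0.95]), (30, 1))
        samples = _toy_samples(tau, sigma=1e-4)
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(4),
                                         t=10, seed=0)
        delta = samples.b[0] + samples.rho[0] * np.abs(tau[0][:, None]
                                                       - tau[0][None, :])
        np.fill_diagonal(delta, 0.0)
        np.testing.assert_allclose(cube.slices.mean(axis=0), delta, atol=1e-2)

    def test_entry_mean_matches_gamma_identity(self):
        """Empirical mean over t=2000 slices sits within 3 sigma of the
        latent distance delta*_ij (Gamma mean identity)."""
        tau0 = np.array([0.05, 0.35, 0.6, 0.9])
        tau = np.tile(tau0, (2000, 1))
        sigma = 0.2
        samples = _toy_samples(tau, sigma=sigma, b=0.05)
        S = NoiseScales.uniform(4)
        cube = sample_dissimilarity_cube(samples, S, t=2000, seed=2)
        delta = 0.05 + np.abs(tau0[:, None] - tau0[None, :])
        for i in range(4):
            for j in range(i + 1, 4):
                mc_sd = sigma / np.sqrt(2000)
                assert abs(cube.slices[:, i, j].mean() - delta[i, j]) < 3 * mc_sd

    def test_rejects_more_slices_than_draws(self, fitted):
        _, _, samples, _ = fitted
        with pytest.raises(ValueError):
            sample_dissimilarity_cube(samples, NoiseScales.uniform(samples.n),
                                      t=samples.T + 1, seed=0)


def distatis_oracle(slices, k):
    """Straight-from-definition DiSTATIS in explicit loops."""
    t, n, _ = slices.shape
    J = np.eye(n) - np.ones((n, n)) / n
    mats = []
    for s in range(t):
        S = -0.5 * J @ (slices[s] ** 2) @ J
        S = (S + S.T) / 2
        lead = max(np.linalg.eigvalsh(S))
        mats.append(S / lead)
    C = np.zeros((t, t))
    for a in range(t):
        for b in range(t):
            C[a, b] = (np.trace(mats[a] @ mats[b])
                       / np.sqrt(np.trace(mats[a] @ mats[a])
                                 * np.trace(mats[b] @ mats[b])))
    w, V = np.linalg.eigh(C)
    alpha = V[:, np.argmax(w)]
    if alpha.sum() < 0:
        alpha = -alpha
    alpha = np.clip(alpha, 0, None)
    alpha /= alpha.sum()
    Sp = sum(a * M for a, M in zip(alpha, mats))
    w, V = np.linalg.eigh(Sp)
    order = np.argsort(w)[::-1][:k]
    lam, V = w[order], V[:, order]
    return alpha, V * np.sqrt(lam), lam


class TestDistatis:
    def test_identical_slices_uniform_alpha_equals_pcoa(self):
        D = euclidean_dissimilarity(np.array([0.0, 0.4, 0.9, 1.7, 2.0]))
        cube = DissimilarityCube(slices=np.tile(D.values, (4, 1, 1)),
                                 draw_ids=np.arange(4), seed=0)
        res = distatis(cube, k=2)
        np.testing.assert_allclose(res.alpha, 0.25, atol=1e-10)
        ref = pcoa(D, k=2)
        # compromise is the normalized cross-product; coordinates agree
        # with classical scaling up to the leading-eigenvalue scale and sign
        scale = np.abs(ref.coords[:, 0]).max() / np.abs(res.consensus[:, 0]).max()
        np.testing.assert_allclose(
            np.abs(res.consensus * scale), np.abs(ref.coords), atol=1e-8
        )

    def test_matches_from_definition_oracle_t2_n3(self):
        rng = np.random.default_rng(7)
        slices = np.zeros((2, 3, 3))
        for s in range(2):
            pts = rng.uniform(size=(3, 2))
            slices[s] = euclidean_dissimilarity(pts).values
        cube = DissimilarityCube(slices=slices, draw_ids=np.arange(2), seed=0)
        res = distatis(cube, k=2)
        alpha_o, cons_o, lam_o = distatis_oracle(slices, 2)
        np.testing.assert_allclose(res.alpha, alpha_o, atol=1e-8)
        np.testing.assert_allclose(np.abs(res.consensus), np.abs(cons_o), atol=1e-8)
        np.testing.assert_allclose(res.eigenvalues, lam_o, atol=1e-8)

    def test_alpha_nonnegative_sums_to_one_and_compromise_psd(self, fitted):
        _, _, samples, _ = fitted
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(samples.n),
                                         t=15, seed=3)
        res = distatis(cube, k=2)
        assert np.all(res.alpha >= 0)
        assert res.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.eigenvalues > -1e-8)

    def test_projection_mean_near_consensus_for_uniform_alpha(self):
        D = euclidean_dissimilarity(np.array([0.0, 0.5, 1.1, 1.9]))
        cube = DissimilarityCube(slices=np.tile(D.values, (3, 1, 1)),
                                 draw_ids=np.arange(3), seed=0)
        res = distatis(cube, k=2)
        np.testing.assert_allclose(res.slice_projections.mean(axis=0),
                                   res.consensus, atol=1e-8)


@pytest.fixture(scope="module")
def field(fitted):
    _, _, samples, est = fitted
    cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(samples.n),
                                     t=40, seed=4)
    res = distatis(cube, k=2, orient_by=est.tau_hat)
    sel = [0, samples.n // 2, samples.n - 1]
    return res, density_and_contours(res, selected=sel)


class TestDensityAndContours:
    def test_density_normalizes_within_2pct(self, field):
        _, f = field
        assert f.integral() == pytest.approx(1.0, abs=0.02)
        assert np.all(f.density >= 0)

    def test_contour_areas_nest(self, field):
        _, f = field
        for c in f.per_point_contours:
            if c.degenerate:
                continue
            assert c.areas[0.95] >= c.areas[0.8] >= c.areas[0.5] > 0

    def test_bandwidth_recorded(self, field):
        _, f = field
        assert f.bandwidth_rule == "scott"
        assert len(f.bandwidth) == 2 and all(b > 0 for b in f.bandwidth)

    def test_degenerate_cloud_flagged(self):
        tau = np.tile(np.array([0.1, 0.5, 0.9, 0.7]), (20, 1))
        samples = _toy_samples(tau, sigma=0.15)
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(4),
                                         t=20, seed=5)
        res = distatis(cube, k=2)
        res.slice_projections[:, 2, :] = res.slice_projections[0, 2, :]
        f = density_and_contours(res, selected=[2])
        assert f.per_point_contours[0].degenerate

    def test_rejects_few_slices_for_contours(self):
        tau = np.random.default_rng(0).uniform(size=(8, 5))
        samples = _toy_samples(tau)
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(5),
                                         t=8, seed=6)
        res = distatis(cube, k=2)
        with pytest.raises(ValueError, match="at least 10"):
            density_and_contours(res, selected=[0])

    def test_sparse_region_contours_larger(self):
        """Samples from the sparsely covered end of a skewed gradient get
        larger 0.95-contour areas than samples from the dense end.

        Per-sample KDE areas are noisy at moderate slice counts, so the
        comparison pools the tercile areas over three generative seeds.
        """
        from buds import fit, orient, summarize

        sparse_areas, dense_areas = [], []
        for seed in (21, 22, 23):
            D, tau, _ = generate_model_draw(n=40, seed=seed, tau_beta=(3.0, 1.0))
            samples = orient(fit(D, seed=seed, draws=300), D)
            est = summarize(samples)
            t = tau if spearmanr(est.tau_hat, tau).statistic > 0 else 1 - tau
            cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(40),
                                             t=150, seed=seed)
            res = distatis(cube, k=2, orient_by=est.tau_hat)
            terc = np.clip((t * 3).astype(int), 0, 2)
            counts = np.bincount(terc, minlength=3)
            occupied = np.flatnonzero(counts > 0)
            sparse_t = occupied[np.argmin(counts[occupied])]
            dense_t = int(np.argmax(counts))
            sparse_idx = np.flatnonzero(terc == sparse_t)
            dense_idx = np.flatnonzero(terc == dense_t)
            f = density_and_contours(res,
                                     selected=list(sparse_idx) + list(dense_idx))
            areas = {c.sample_index: c.areas[0.95] for c in f.per_point_contours
                     if not c.degenerate}
            sparse_areas += [areas[i] for i in sparse_idx if i in areas]
            dense_areas += [areas[i] for i in dense_idx if i in areas]
        assert np.mean(sparse_areas) > np.mean(dense_areas)

    def test_end_to_end_consensus_axis_tracks_tau(self, fitted):
        _, tau, samples, est = fitted
        cube = sample_dissimilarity_cube(samples, NoiseScales.uniform(samples.n),
                                         t=30, seed=7)
        res = distatis(cube, k=2, orient_by=est.tau_hat)
        rho = spearmanr(res.consensus[:, 0], est.tau_hat).statistic
        assert abs(rho) >= 0.9
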