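import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from corax.morphospace import (LandmarkSet, allometry_test, alpha_hull_area,
                               centroid_size, gpa_align,
                               landmarks_from_frame, ppca, project_shape,
                               reconstruct_extreme_shape,
                               size_free_residuals, species_mean_shapes)
from corax.simulate import (SimulationConfig, simulate_landmarks,
                            simulate_traits)

TRI = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def similarity(config, theta, scale, shift):
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return scale * config @ R.T + shift


class TestCentroidSize:
    def test_unit_square(self):
        corners = [[.5, .5], [.5, -.5], [-.5, .5], [-.5, -.5]]
        assert centroid_size(corners) == pytest.approx(np.sqrt(2))

    def test_coincident_points(self):
        assert centroid_size([[1, 1]] * 5) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(23, 2))
        direct = np.sqrt(((X - X.mean(axis=0)) ** 2).sum())
        assert centroid_size(X) == pytest.approx(direct, abs=1e-12)


class TestGPA:
    def test_similarity_invariance(self):
        l = LandmarkSet(["a", "b"], ["s", "s"],
                        np.stack([TRI, similarity(TRI, np.pi / 2, 3.0,
                                                  [5.0, -2.0])]))
        al = gpa_align(l)
        assert np.linalg.norm(al.coords[0] - al.coords[1]) < 1e-8
        assert al.centroid_sizes[1] == pytest.approx(
            3 * al.centroid_sizes[0])

    def test_alignment_fixpoint(self):
        rng = np.random.default_rng(1)
        configs = TRI + rng.normal(0, 0.05, size=(6, 3, 2))
        l = LandmarkSet([f"s{i}" for i in range(6)], ["sp"] * 6, configs)
        al = gpa_align(l)
        al2 = gpa_align(al)
        assert np.abs(al2.coords - al.coords).max() < 1e-6

    def test_invariant_to_input_transforms(self):
        rng = np.random.default_rng(2)
        configs = TRI + rng.normal(0, 0.05, size=(5, 3, 2))
        l1 = gpa_align(LandmarkSet(list("abcde"), ["s"] * 5, configs))
        jumbled = np.stack([
            similarity(c, rng.uniform(-np.pi, np.pi),
                       rng.uniform(0.5, 4.0), rng.normal(0, 10, 2))
            for c in configs])
        l2 = gpa_align(LandmarkSet(list("abcde"), ["s"] * 5, jumbled))
        assert np.abs(l1.coords - l2.coords).max() < 1e-6

    def test_pairwise_procrustes_oracle(self):
        # after GPA, distances between aligned configurations agree with a
        # brute-force ordinary-Procrustes superimposition of each pair
        from scipy.spatial import procrustes
        rng = np.random.default_rng(3)
        configs = TRI + rng.normal(0, 0.08, size=(4, 3, 2))
        al = gpa_align(LandmarkSet(list("abcd"), ["s"] * 4, configs))
        for i in range(4):
            for j in range(i + 1, 4):
                _, _, d2 = procrustes(al.coords[i], al.coords[j])
                d_gpa = np.linalg.norm(al.coords[i] - al.coords[j])
                assert np.sqrt(d2) <= d_gpa + 1e-6
                assert d_gpa < np.sqrt(d2) * 1.5 + 1e-6

    def test_collinear_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            gpa_align(LandmarkSet(["a"], ["s"], line[None]))


class TestPPCA:
    def test_percent_variance_sums_to_100(self, yule80):
        X = simulate_traits(yule80, sigma2=1.0, seed=4, n_traits=4)
        res = ppca(yule80, X, model="BM")
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.allclose(res.loadings.T @ res.loadings,
                           np.eye(4), atol=1e-8)

    def test_scores_gls_centered(self, yule80):
        from corax.phylo import phylo_covariance
        X = simulate_traits(yule80, sigma2=1.0, seed=5, n_traits=3)
        res = ppca(yule80, X, model="BM")
        C = phylo_covariance(yule80, "BM")
        w = np.linalg.solve(C, np.ones(yule80.n_tips))
        m = w @ res.scores.to_numpy() / w.sum()
        assert np.abs(m).max() < 1e-8

    def test_dominant_axis_recovery(self, yule80):
        rng = np.random.default_rng(6)
        ok = 0
        direction = np.array([3.0, 1.0, 0.5])
        direction /= np.linalg.norm(direction)
        for _ in range(20):
            z = simulate_traits(yule80, sigma2=4.0, rng=rng)["trait1"]
            noise = simulate_traits(yule80, sigma2=0.05, rng=rng,
                                    n_traits=3)
            X = pd.DataFrame(np.outer(z, direction) + noise.to_numpy(),
                             index=yule80.tip_labels)
            res = ppca(yule80, X, model="BM")
            # loadings live in the standardized space: a variable with
            # signal coefficient d_j and SD s_j contributes d_j / s_j there
            v_true = direction / res.trait_sd
            v_true /= np.linalg.norm(v_true)
            cosang = abs(v_true @ res.loadings[:, 0])
            ok += cosang >= np.cos(np.radians(10))
        assert ok >= 16

    def test_column_permutation_equivariance(self, yule80):
        X = simulate_traits(yule80, sigma2=1.0, seed=7, n_traits=3)
        res1 = ppca(yule80, X, model="BM")
        perm = [2, 0, 1]
        res2 = ppca(yule80, X.iloc[:, perm], model="BM")
        assert np.allclose(np.abs(res1.scores.to_numpy()),
                           np.abs(res2.scores.to_numpy()), atol=1e-8)
        assert np.allclose(np.abs(res1.loadings[perm]),
                           np.abs(res2.loadings), atol=1e-8)

    def test_too_many_traits_rejected(self, tree3):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                         index=["A", "B", "C"])
        with pytest.raises(ValueError, match="trait"):
            ppca(tree3, X)


class TestExtremeShapes:
    @pytest.fixture()
    def landmark_ppca(self, yule80):
        cfg = SimulationConfig(n_specimens=2)
        df = simulate_landmarks(yule80, cfg, rng=np.random.default_rng(8))
        al = gpa_align(landmarks_from_frame(df))
        shapes, _ = species_mean_shapes(al)
        return ppca(yule80, shapes.reindex(yule80.tip_labels), model="BM",
                    is_landmark=True)

    def test_score_zero_is_mean(self, landmark_ppca):
        cfg = reconstruct_extreme_shape(landmark_ppca, 0, 0.0)
        assert np.allclose(cfg.ravel(), landmark_ppca.phylo_mean)

    def test_symmetry_about_mean(self, landmark_ppca):
        hi = reconstruct_extreme_shape(landmark_ppca, 0, 1.5)
        lo = reconstruct_extreme_shape(landmark_ppca, 0, -1.5)
        mean = landmark_ppca.phylo_mean.reshape(-1, 2)
        assert np.allclose(hi - mean, -(lo - mean), atol=1e-10)

    def test_projection_roundtrip(self, landmark_ppca):
        cfg = reconstruct_extreme_shape(landmark_ppca, 1, 0.8)
        assert project_shape(landmark_ppca, cfg)[1] == pytest.approx(
            0.8, abs=1e-8)

    def test_non_landmark_rejected(self, yule80):
        X = simulate_traits(yule80, sigma2=1.0, seed=9, n_traits=3)
        res = ppca(yule80, X, model="BM")
        with pytest.raises(ValueError):
            reconstruct_extreme_shape(res, 0, 1.0)


class TestAllometry:
    def test_determinism(self, yule80):
        cfg = SimulationConfig(n_specimens=2)
        df = simulate_landmarks(yule80, cfg, rng=np.random.default_rng(10))
        al = gpa_align(landmarks_from_frame(df))
        shapes, ls = species_mean_shapes(al)
        a1 = allometry_test(yule80, shapes, np.exp(ls), nperm=200, seed=3)
        a2 = allometry_test(yule80, shapes, np.exp(ls), nperm=200, seed=3)
        assert a1.pvalue == a2.pvalue

    def test_power_with_strong_allometry(self, yule80):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(10):
            cfg = SimulationConfig(shape_allometry=0.2, n_specimens=2,
                                   sigma2_shape=0.0002)
            df = simulate_landmarks(yule80, cfg, rng=rng)
            al = gpa_align(landmarks_from_frame(df))
            shapes, ls = species_mean_shapes(al)
            a = allometry_test(yule80, shapes, np.exp(ls), nperm=200,
                               seed=int(rng.integers(2**31)))
            hits += a.pvalue < 0.05
        assert hits >= 9

    def test_type_one_error_without_allometry(self, yule80):
        rng = np.random.default_rng(12)
        rejections = 0
        n = 40
        for _ in range(n):
            cfg = SimulationConfig(shape_allometry=0.0, n_specimens=2)
            df = simulate_landmarks(yule80, cfg, rng=rng)
            al = gpa_align(landmarks_from_frame(df))
            shapes, ls = species_mean_shapes(al)
            a = allometry_test(yule80, shapes, np.exp(ls), nperm=100,
                               seed=int(rng.integers(2**31)))
            rejections += a.pvalue < 0.05
        # binomial(40, 0.05): 99.5% of mass below 8
        assert rejections <= 8

    def test_size_free_residuals_orthogonal(self, yule80):
        from corax.phylo import phylo_covariance
        cfg = SimulationConfig(shape_allometry=0.15, n_specimens=2)
        df = simulate_landmarks(yule80, cfg, rng=np.random.default_rng(13))
        al = gpa_align(landmarks_from_frame(df))
        shapes, ls = species_mean_shapes(al)
        resid = size_free_residuals(yule80, shapes, np.exp(ls))
        C = phylo_covariance(yule80, "EB", rate=-1.0 / yule80.root_age)
        s = np.log(np.exp(ls.reindex(yule80.tip_labels)))
        Ci_r = np.linalg.solve(C, resid.reindex(yule80.tip_labels))
        assert np.abs(s.to_numpy() @ Ci_r).max() < 1e-6

    def test_perfect_allometry_leaves_no_residual(self, yule80):
        s = simulate_traits(yule80, sigma2=0.05, seed=14)["trait1"]
        shape = pd.DataFrame(np.outer(s, [1.0, -0.5, 2.0]),
                             index=yule80.tip_labels)
        resid = size_free_residuals(yule80, shape, np.exp(s))
        assert np.abs(resid.to_numpy()).max() < 1e-8


class TestAlphaHull:
    def test_square_convex_limit(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert alpha_hull_area(sq, 100.0) == pytest.approx(1.0)

    def test_monotone_in_alpha(self):
        pts = np.random.default_rng(15).normal(size=(40, 2))
        areas = [alpha_hull_area(pts, a) for a in (0.3, 0.6, 1.2, 2.4, 10)]
        assert all(a1 <= a2 + 1e-12 for a1, a2 in zip(areas, areas[1:]))

    def test_matches_convex_hull_for_large_alpha(self):
        pts = np.random.default_rng(16).normal(size=(20, 2))
        assert alpha_hull_area(pts, 1e9) == pytest.approx(
            ConvexHull(pts).volume, abs=1e-9)

    def test_collinear_warns_zero(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="collinear"):
            assert alpha_hull_area(line, 1.0) == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            alpha_hull_area(np.zeros((4, 2)), 0.0)
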