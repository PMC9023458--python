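import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from corax.phylo import CladePartition, parse_newick, phylo_covariance
from corax.simulate import simulate_traits, simulate_yule_tree
from corax.traitmodels import (PGLS, ancestral_states, compare_models,
                               fit_trait_model, pgls, phenogram_coords,
                               time_slice_means)


class TestFitTraitModel:
    def test_two_tip_star_closed_form(self, star2):
        f = fit_trait_model(star2, [0.0, 2.0], "BM")
        assert f.z0 == pytest.approx(1.0)
        assert f.sigma2 == pytest.approx(1.0)
        assert f.loglik == pytest.approx(-np.log(2 * np.pi) - 1.0, abs=1e-10)

    def test_lambda_star_unidentifiable_warns(self):
        star = parse_newick("(A:1,B:1,C:1);")
        f = fit_trait_model(star, [0.0, 1.0, 2.0], "lambda")
        assert any("star" in m or "boundary" in m for m in f.messages)

    def test_sigma2_recovery(self, yule150):
        rng = np.random.default_rng(7)
        est = [fit_trait_model(
            yule150, simulate_traits(yule150, sigma2=2.0, rng=rng)["trait1"],
            "BM").sigma2 for _ in range(40)]
        assert 1.8 <= np.median(est) <= 2.2

    @pytest.mark.parametrize("model", ["EB", "OUfixedRoot", "lambda"])
    def test_nested_bm_dominance(self, yule80, model):
        # the stationary-root OU is excluded: its alpha->0 limit has
        # divergent stationary variance and does not nest BM
        rng = np.random.default_rng(13)
        for _ in range(3):
            x = simulate_traits(yule80, sigma2=1.0, rng=rng)["trait1"]
            bm = fit_trait_model(yule80, x, "BM")
            f = fit_trait_model(yule80, x, model)
            assert f.loglik >= bm.loglik - 1e-6

    def test_lambda_recovery_near_one(self, yule150):
        rng = np.random.default_rng(17)
        good = sum(
            fit_trait_model(yule150,
                            simulate_traits(yule150, sigma2=1.0,
                                            rng=rng)["trait1"],
                            "lambda").lam > 0.9
            for _ in range(25))
        assert good >= 20    # >= 80% of reps

    def test_aic_counts_parameters(self, yule80):
        x = simulate_traits(yule80, sigma2=1.0, seed=1)["trait1"]
        bm = fit_trait_model(yule80, x, "BM")
        eb = fit_trait_model(yule80, x, "EB")
        assert bm.aic == pytest.approx(4 - 2 * bm.loglik)
        assert eb.aic == pytest.approx(6 - 2 * eb.loglik)


class TestCompareModels:
    def test_single_candidate_ranks_first(self, yule80):
        x = simulate_traits(yule80, sigma2=1.0, seed=2)["trait1"]
        cm = compare_models(yule80, x, models=("EB",))
        assert cm["model"].iloc[0] == "EB"

    def test_bm_data_keeps_bm_close(self, yule150):
        rng = np.random.default_rng(23)
        ok = 0
        for _ in range(15):
            x = simulate_traits(yule150, sigma2=1.0, rng=rng)["trait1"]
            cm = compare_models(yule150, x)
            ok += cm.loc[cm.model == "BM", "delta_aic"].iloc[0] <= 2.0
        assert ok >= 12     # >= 80% of reps

    def test_eb_data_beats_bm(self, yule150):
        rng = np.random.default_rng(29)
        ok = 0
        for _ in range(15):
            x = simulate_traits(yule150, model="EB", r=-0.3, sigma2=1.0,
                                rng=rng)["trait1"]
            cm = compare_models(yule150, x, models=("BM", "EB"))
            ok += cm["model"].iloc[0] == "EB"
        assert ok >= 12

    def test_failed_fit_flagged_not_fatal(self, star2):
        # models with a shape parameter need >= 3 species
        cm = compare_models(star2, [0.0, 2.0], models=("BM", "EB"))
        assert cm["model"].iloc[0] == "BM"
        assert cm.loc[cm.model == "EB", "error"].iloc[0] is not None


class TestPGLS:
    def test_lambda_zero_equals_ols(self, tree3):
        y = pd.Series({"A": 1.0, "B": 0.2, "C": -0.5})
        X = pd.DataFrame({"x": [0.3, -1.2, 0.7]}, index=["A", "B", "C"])
        r = pgls(tree3, y, X, model="lambda", lam=0.0)
        Xm = np.column_stack([np.ones(3), X.loc[tree3.tip_labels, "x"]])
        beta = np.linalg.lstsq(Xm, y[tree3.tip_labels].to_numpy(),
                               rcond=None)[0]
        assert np.allclose(r.params.to_numpy(), beta)

    def test_slope_recovery(self, yule80):
        rng = np.random.default_rng(31)
        slopes = []
        for _ in range(25):
            x = simulate_traits(yule80, sigma2=1.0, rng=rng)["trait1"]
            y = 0.75 * x + simulate_traits(yule80, sigma2=0.05,
                                           rng=rng)["trait1"]
            slopes.append(pgls(yule80, y, x.to_frame("x"),
                               model="BM").params["x"])
        assert 0.70 <= np.median(slopes) <= 0.80

    def test_residuals_gls_orthogonal(self, yule80):
        rng = np.random.default_rng(37)
        x = simulate_traits(yule80, sigma2=1.0, rng=rng)["trait1"]
        y = simulate_traits(yule80, sigma2=1.0, rng=rng)["trait1"]
        r = pgls(yule80, y, x.to_frame("x"), model="BM")
        C = phylo_covariance(yule80, "BM")
        Ci_r = np.linalg.solve(C, r.resid.to_numpy())
        X = np.column_stack([np.ones(yule80.n_tips),
                             x[yule80.tip_labels].to_numpy()])
        assert np.abs(X.T @ Ci_r).max() < 1e-6

    def test_collinear_rejected(self, yule80):
        x = pd.Series(np.ones(yule80.n_tips), index=yule80.tip_labels)
        with pytest.raises(ValueError, match="rank|collinear"):
            pgls(yule80, x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_group_test_type_one_error(self, yule80):
        rng = np.random.default_rng(41)
        g = pd.Series((np.arange(yule80.n_tips) % 2).astype(float),
                      index=yule80.tip_labels, name="g")
        rej = sum(
            pgls(yule80, simulate_traits(yule80, sigma2=1.0,
                                         rng=rng)["trait1"],
                 g.to_frame(), model="BM").pvalues["g"] < 0.05
            for _ in range(100))
        assert rej <= 13    # binomial(100, .05) 99.9% upper bound


class TestAncestralStates:
    def test_symmetric_two_tip(self, star2):
        a = ancestral_states(star2, [0.0, 2.0])
        assert a.states[star2.root] == pytest.approx(1.0)

    def test_constant_trait(self, tree3):
        a = ancestral_states(tree3, [5.0, 5.0, 5.0])
        assert np.allclose(a.states, 5.0)
        assert np.allclose(a.var[tree3.tip_indices], 0.0)

    def test_matches_gls_formula(self):
        rng = np.random.default_rng(43)
        t = simulate_yule_tree(5, 0.5, rng)
        x = simulate_traits(t, sigma2=1.0, rng=rng)["trait1"].to_numpy()
        a = ancestral_states(t, x)
        C = phylo_covariance(t, "BM")
        one = np.ones(t.n_tips)
        z0 = (one @ np.linalg.solve(C, x)) / (one @ np.linalg.solve(C, one))
        assert a.states[t.root] == pytest.approx(z0, abs=1e-8)

    def test_missing_values_rejected(self, tree3):
        with pytest.raises(ValueError):
            ancestral_states(tree3, pd.Series({"A": 1.0, "B": 2.0}))


class TestTimeSlices:
    def test_slice_at_present_is_tip_mean(self, tree3):
        x = pd.Series({"A": 1.0, "B": 3.0, "C": 2.0})
        a = ancestral_states(tree3, x)
        df = time_slice_means(tree3, a, [0.0])
        assert df["mean_state"].iloc[0] == pytest.approx(2.0)
        assert df["n_lineages"].iloc[0] == 3

    def test_slice_at_root_is_root_state(self, tree3):
        x = pd.Series({"A": 1.0, "B": 3.0, "C": 2.0})
        a = ancestral_states(tree3, x)
        df = time_slice_means(tree3, a, [tree3.root_age])
        assert df["mean_state"].iloc[0] == pytest.approx(
            a.states[tree3.root])

    def test_constant_trait_constant_series(self, yule80):
        x = pd.Series(np.full(yule80.n_tips, 2.5), index=yule80.tip_labels)
        a = ancestral_states(yule80, x)
        df = time_slice_means(yule80, a,
                              np.linspace(0, yule80.root_age, 7))
        assert np.allclose(df["mean_state"], 2.5)

    def test_out_of_range_rejected(self, tree3):
        x = pd.Series({"A": 1.0, "B": 3.0, "C": 2.0})
        a = ancestral_states(tree3, x)
        with pytest.raises(ValueError):
            time_slice_means(tree3, a, [tree3.root_age + 1.0])


class TestPhenogram:
    def test_two_tip_segments_share_root(self, star2):
        x = pd.Series({"A": 0.0, "B": 2.0})
        segs = phenogram_coords(star2, x)
        assert segs.shape == (2, 4)
        assert segs[0, 0] == segs[1, 0] == 0.0
        assert segs[0, 1] == segs[1, 1]

    def test_tip_endpoints_equal_observations(self, yule80):
        x = simulate_traits(yule80, sigma2=1.0, seed=5)["trait1"]
        segs = phenogram_coords(yule80, x)
        assert segs.shape[0] == yule80.n_nodes - 1   # one per branch
        depths = yule80.depths()
        tip_vals = {round(depths[t], 9): None for t in yule80.tip_indices}
        T = yule80.root_age
        end_at_present = segs[np.isclose(segs[:, 2], T)]
        assert sorted(np.round(end_at_present[:, 3], 9)) == \
            sorted(np.round(x.to_numpy(), 9))
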