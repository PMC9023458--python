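import numpy as np
import pandas as pd
import pytest

from corax.niche import (build_presence_grid, climate_pca,
                         count_sympatric_assemblages, range_area,
                         thin_occurrences)


@pytest.fixture()
def toy_table():
    # 7 records, 2 species, 3 occupied cells at the ~0.099 degree thinning
    # resolution: species A in cells (0,0) and (1,0); B in (0,0) and (1,0)
    return pd.DataFrame({
        "species": ["A", "A", "A", "B", "B", "B", "B"],
        "lon": [0.01, 0.02, 0.15, 0.01, 0.02, 0.15, 0.16],
        "lat": [0.01, 0.03, 0.01, 0.01, 0.02, 0.01, 0.02],
        "temp1": np.arange(7.0),
        "prec1": np.arange(7.0)[::-1],
    })


class TestThinning:
    def test_toy_table_brute_force(self, toy_table):
        out = thin_occurrences(toy_table)
        assert len(out) == 4
        key = out.apply(lambda r: (r.species, int(r.lon // (11 / 111)),
                                   int(r.lat // (11 / 111))), axis=1)
        assert key.is_unique

    def test_distinct_cells_unchanged(self):
        t = pd.DataFrame({"species": ["A", "A"], "lon": [0.0, 5.0],
                          "lat": [0.0, 5.0]})
        assert len(thin_occurrences(t)) == 2

    def test_idempotent(self, toy_table):
        once = thin_occurrences(toy_table)
        twice = thin_occurrences(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = thin_occurrences(pd.DataFrame(
                columns=["species", "lon", "lat"]))
        assert len(out) == 0


class TestClimatePCA:
    @pytest.fixture()
    def gradient_table(self):
        rng = np.random.default_rng(0)
        n = 400
        grad = rng.normal(size=n) * 2.0
        wet = rng.normal(size=n)
        return pd.DataFrame({
            "species": rng.choice(list("ABCD"), n),
            "lon": rng.uniform(-10, 10, n), "lat": rng.uniform(-10, 10, n),
            "temp1": grad + rng.normal(0, 0.2, n),
            "temp2": 0.9 * grad + rng.normal(0, 0.2, n),
            "prec1": wet + rng.normal(0, 0.2, n),
        })

    def test_eigenvalues_sum_to_nvars(self, gradient_table):
        cp = climate_pca(gradient_table)
        assert cp.explained_variance.sum() == pytest.approx(3.0, abs=1e-9)

    def test_temperature_gradient_on_first_axis(self):
        rng = np.random.default_rng(1)
        ok = 0
        for _ in range(20):
            n = 300
            grad = rng.normal(size=n) * 3.0
            t = pd.DataFrame({
                "species": rng.choice(list("AB"), n),
                "lon": np.zeros(n), "lat": np.zeros(n),
                "temp1": grad + rng.normal(0, 0.3, n),
                "temp2": 0.8 * grad + rng.normal(0, 0.3, n),
                "prec1": rng.normal(size=n),
                "prec2": rng.normal(size=n),
            })
            cp = climate_pca(t)
            ok += cp.loadings["PC1"].abs().idxmax().startswith("temp")
        assert ok >= 18      # >= 90%

    def test_duplication_invariance(self, gradient_table):
        cp1 = climate_pca(gradient_table)
        cp2 = climate_pca(pd.concat([gradient_table, gradient_table],
                                    ignore_index=True))
        assert np.allclose(cp1.loadings, cp2.loadings, atol=1e-9)
        pd.testing.assert_frame_equal(cp1.species_means, cp2.species_means)

    def test_species_means_inside_score_hull(self, gradient_table):
        from scipy.spatial import ConvexHull, Delaunay
        cp = climate_pca(gradient_table)
        for sp, row in cp.species_means.iterrows():
            pts = cp.scores.loc[cp.scores.species == sp,
                                ["PC1", "PC2"]].to_numpy()
            hull = Delaunay(pts)
            assert hull.find_simplex(row.to_numpy()) >= 0

    def test_zero_variance_column_dropped(self, gradient_table):
        t = gradient_table.copy()
        t["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            cp = climate_pca(t)
        assert "flat" in cp.dropped


class TestPresenceGrid:
    def test_single_record_single_cell(self):
        g = build_presence_grid(pd.DataFrame(
            {"species": ["X"], "lon": [10.03], "lat": [-3.07]}))
        assert len(g.species_cells["X"]) == 1

    def test_boundary_goes_to_floor_cell(self):
        g = build_presence_grid(pd.DataFrame(
            {"species": ["X"], "lon": [0.1], "lat": [0.2]}), resolution=0.1)
        assert g.species_cells["X"] == {(1, 2)}

    def test_toy_enumeration(self):
        t = pd.DataFrame({"species": list("AABBC"),
                          "lon": [0.01, 0.23, 0.01, 0.29, 0.01],
                          "lat": [0.01, 0.01, 0.01, 0.01, 0.11]})
        g = build_presence_grid(t, resolution=0.1)
        assert g.species_cells["A"] == {(0, 0), (2, 0)}
        assert g.species_cells["B"] == {(0, 0), (2, 0)}
        assert g.species_cells["C"] == {(0, 1)}

    def test_bad_resolution(self):
        with pytest.raises(ValueError):
            build_presence_grid(pd.DataFrame(
                {"species": ["X"], "lon": [0.0], "lat": [0.0]}),
                resolution=0.0)


class TestRangeArea:
    def test_equatorial_cell(self):
        g = build_presence_grid(pd.DataFrame(
            {"species": ["X"], "lon": [0.05], "lat": [0.05]}))
        R, d = 6371.0, np.radians(0.1)
        expected = (R * d) * (R * d * np.cos(np.radians(0.05)))
        assert range_area(g, "X") == pytest.approx(expected, rel=1e-12)
        assert range_area(g, "X") == pytest.approx(123.6, abs=0.2)

    def test_high_latitude_half_area(self):
        g = build_presence_grid(pd.DataFrame(
            {"species": ["X", "Y"], "lon": [0.05, 0.05],
             "lat": [0.001, 60.001]}))
        ratio = range_area(g, "Y") / range_area(g, "X")
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_union_subadditive(self):
        t = pd.DataFrame({"species": ["X", "Y", "Y"],
                          "lon": [0.05, 0.05, 1.05],
                          "lat": [0.05, 0.05, 0.05]})
        g = build_presence_grid(t)
        assert range_area(g, ["X", "Y"]) <= \
            range_area(g, "X") + range_area(g, "Y") + 1e-9
        assert range_area(g, ["X", "Y"]) == pytest.approx(
            range_area(g, "Y"), rel=1e-12)

    def test_unknown_species(self):
        g = build_presence_grid(pd.DataFrame(
            {"species": ["X"], "lon": [0.0], "lat": [0.0]}))
        with pytest.raises(KeyError):
            range_area(g, "Z")


class TestSympatry:
    def make_grid(self, cells):
        rows = []
        for i, sps in enumerate(cells):
            for sp in sps:
                rows.append({"species": sp, "lon": i + 0.05, "lat": 0.05})
        return build_presence_grid(pd.DataFrame(rows), resolution=1.0)

    def test_unique_assemblages(self):
        g = self.make_grid([{"A", "B"}, {"A", "B"}, {"A", "C"}])
        out = count_sympatric_assemblages(g, {s: "g" for s in "ABC"})
        assert out["g"] == 2

    def test_allopatric_species_zero(self):
        g = self.make_grid([{"A"}, {"B"}, {"C"}])
        out = count_sympatric_assemblages(g, {s: "g" for s in "ABC"})
        assert out["g"] == 0

    def test_maximal_set_not_subsets(self):
        g = self.make_grid([{"A", "B", "C"}])
        out = count_sympatric_assemblages(g, {s: "g" for s in "ABC"})
        assert out["g"] == 1

    def test_pairs_mode(self):
        g = self.make_grid([{"A", "B", "C"}])
        out = count_sympatric_assemblages(g, {s: "g" for s in "ABC"},
                                          pairs=True)
        assert out["g"] == 3

    def test_invariant_to_duplication(self):
        g1 = self.make_grid([{"A", "B"}])
        g2 = self.make_grid([{"A", "B"}, {"A", "B"}])
        gm = {s: "g" for s in "AB"}
        assert count_sympatric_assemblages(g1, gm)["g"] == \
            count_sympatric_assemblages(g2, gm)["g"]

    def test_genus_separation(self):
        g = self.make_grid([{"A", "B", "X"}])
        out = count_sympatric_assemblages(
            g, {"A": "g1", "B": "g1", "X": "g2"})
        assert out["g1"] == 1 and out["g2"] == 0
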