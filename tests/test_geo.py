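"""Spatial join, densities, SEI and quartile stratification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from foodenv.classify import UNCLASSIFIED, classify_frame
from foodenv.config import CATEGORIES, CityConfig
from foodenv.geo import (
    CRSMismatchError,
    assign_points,
    build_metrics,
    compute_density,
    quartile_table,
    read_neighbourhoods_geojson,
    social_environment_index,
    write_neighbourhoods_geojson,
)
from foodenv.synthetic import generate_establishments, generate_neighbourhoods


def _two_cells() -> pd.DataFrame:
    df = pd.DataFrame({
        "id": ["A", "B"],
        "city": ["U", "U"],
        "x0": [0.0, 1.0], "y0": [0.0, 0.0], "x1": [1.0, 2.0], "y1": [1.0, 1.0],
        "area_km2": [1.0, 1.0],
        "population": [1000.0, 2000.0],
    })
    df.attrs["crs"] = "planar_km"
    return df


class TestAssign:
    def test_point_strictly_inside(self):
        nb = _two_cells()
        est = pd.DataFrame({"x": [0.5], "y": [0.5]})
        est.attrs["crs"] = "planar_km"
        assert assign_points(est, nb).iloc[0] == "A"

    def test_boundary_tie_break_smallest_id(self):
        nb = _two_cells()
        est = pd.DataFrame({"x": [1.0], "y": [0.5]})  # on the A|B shared edge
        est.attrs["crs"] = "planar_km"
        assert assign_points(est, nb).iloc[0] == "A"

    def test_outside_all_is_unassigned(self):
        nb = _two_cells()
        est = pd.DataFrame({"x": [5.0], "y": [5.0]})
        est.attrs["crs"] = "planar_km"
        assert assign_points(est, nb).isna().all()

    def test_crs_mismatch_raises(self):
        nb = _two_cells()
        est = pd.DataFrame({"x": [0.5], "y": [0.5]})
        est.attrs["crs"] = "lonlat"
        with pytest.raises(CRSMismatchError):
            assign_points(est, nb)

    def test_uniform_points_all_assigned_vs_brute_force(self):
        """Points uniform over the tiling: zero unassigned; agreement with a
        per-point brute-force containment scan."""
        cfg = CityConfig(n_neighbourhoods=40, city_weights=(1,), city_labels=("U",),
                         seed=3)
        nb = generate_neighbourhoods(cfg)
        rng = np.random.default_rng(5)
        cell = rng.integers(0, len(nb), 300)   # uniform over the tiling
        xs = rng.uniform(nb["x0"].to_numpy()[cell], nb["x1"].to_numpy()[cell])
        ys = rng.uniform(nb["y0"].to_numpy()[cell], nb["y1"].to_numpy()[cell])
        est = pd.DataFrame({"x": xs, "y": ys})
        est.attrs["crs"] = "planar_km"
        got = assign_points(est, nb)
        polys = [box(r.x0, r.y0, r.x1, r.y1) for r in nb.itertuples(index=False)]
        from shapely.geometry import Point
        for i in range(len(est)):
            hits = sorted(
                nb["id"].iloc[j] for j, p in enumerate(polys)
                if p.intersects(Point(xs[i], ys[i]))
            )
            expected = hits[0] if hits else None
            assert (got.iloc[i] == expected) or (expected is None and pd.isna(got.iloc[i]))
        assert got.notna().all()


class TestDensity:
    def test_count_over_area(self):
        nb = _two_cells()
        nb["area_km2"] = [2.0, 1.0]
        cls = pd.DataFrame({
            "neighbourhood_id": ["A"] * 10,
            "category": ["supermarket"] * 10,
        })
        d = compute_density(nb, cls)
        assert d.loc[d["id"] == "A", "density_total"].iloc[0] == pytest.approx(5.0)
        assert d.loc[d["id"] == "B", "density_total"].iloc[0] == 0.0

    def test_unclassified_in_total_only(self):
        nb = _two_cells()
        cls = pd.DataFrame({
            "neighbourhood_id": ["A", "A", "A"],
            "category": ["supermarket", UNCLASSIFIED, UNCLASSIFIED],
        })
        d = compute_density(nb, cls)
        a = d[d["id"] == "A"].iloc[0]
        assert a["density_total"] == pytest.approx(3.0)
        assert a["density_supermarket"] == pytest.approx(1.0)
        cat_sum = sum(a[f"density_{c}"] for c in CATEGORIES)
        assert cat_sum <= a["density_total"]

    def test_area_scale_equivariance(self):
        """Doubling every area halves every density exactly."""
        cfg = CityConfig(n_neighbourhoods=50, city_weights=(1,), city_labels=("U",),
                         seed=8)
        nb = generate_neighbourhoods(cfg)
        est = classify_frame(generate_establishments(nb, cfg))
        d1 = compute_density(nb, est)
        nb2 = nb.copy()
        nb2["area_km2"] = nb2["area_km2"] * 2
        d2 = compute_density(nb2, est)
        cols = [c for c in d1.columns if c.startswith("density_")]
        assert np.allclose(d1[cols].to_numpy(), 2 * d2[cols].to_numpy())

    def test_conservation_against_groupby_oracle(self):
        cfg = CityConfig(n_neighbourhoods=80, city_weights=(1,), city_labels=("U",),
                         seed=9)
        nb = generate_neighbourhoods(cfg)
        est = classify_frame(generate_establishments(nb, cfg))
        assignment = assign_points(est, nb)
        d = compute_density(nb, est, assignment)
        total_counted = (d["density_total"].to_numpy() * nb["area_km2"].to_numpy()).sum()
        assert total_counted + assignment.isna().sum() == pytest.approx(len(est))


class TestSEI:
    def _nb(self, dims):
        df = pd.DataFrame(dims)
        df["id"] = [f"N{i}" for i in range(len(df))]
        return df

    def test_mean_zero_and_unit_case(self):
        rng = np.random.default_rng(0)
        nb = self._nb({f"dim_{k}": rng.normal(size=50) for k in range(1, 5)})
        sei = social_environment_index(nb)
        assert abs(sei.mean()) < 1e-9
        # a neighbourhood exactly 1 SD above on every dimension scores 1
        stats = {c: (nb[c].mean(), nb[c].std(ddof=0)) for c in nb.columns if c.startswith("dim")}
        row = {c: m + s for c, (m, s) in stats.items()}
        nb2 = pd.concat([nb, pd.DataFrame([{**row, "id": "HI"}])], ignore_index=True)
        # recompute: the appended row shifts means slightly, so check the
        # exact-1 property on the original frame's scale instead
        z = np.mean([(row[c] - m) / s for c, (m, s) in stats.items()])
        assert z == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        nb = self._nb({f"dim_{k}": rng.normal(size=30) for k in range(1, 5)})
        sei1 = social_environment_index(nb)
        nb2 = nb.copy()
        nb2["dim_2"] = 100.0 + 7.5 * nb2["dim_2"]
        sei2 = social_environment_index(nb2)
        assert np.allclose(sei1, sei2)

    def test_direction_flip(self):
        rng = np.random.default_rng(2)
        nb = self._nb({"dim_1": rng.normal(size=20)})
        s_plus = social_environment_index(nb)
        s_minus = social_environment_index(nb, directions={"dim_1": -1})
        assert np.allclose(s_plus, -s_minus)

    def test_zero_variance_names_dimension(self):
        nb = self._nb({"dim_1": [1.0, 1.0, 1.0], "dim_2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="dim_1"):
            social_environment_index(nb)


class TestQuartiles:
    def test_self_stratified_means(self):
        m = pd.DataFrame({"density_total": np.arange(1.0, 9.0)})
        t = quartile_table(m, "density_total", value_columns=["density_total"])
        assert t.loc[t["quartile"] == "Q1", "density_total_mean"].iloc[0] == 1.5
        assert t.loc[t["quartile"] == "Q4", "density_total_mean"].iloc[0] == 7.5
        assert t["n_neighbourhoods"].sum() == 8

    def test_constant_stratifier_raises(self):
        m = pd.DataFrame({"density_total": [1.0] * 8, "sei": [0.5] * 8})
        with pytest.raises(ValueError, match="constant"):
            quartile_table(m, "sei", value_columns=["density_total"])

    def test_row_count_conservation(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"density_total": rng.exponential(5, 101),
                          "sei": rng.normal(size=101)})
        t = quartile_table(m, "sei", value_columns=["density_total"])
        assert t["n_neighbourhoods"].sum() == 101


def test_geojson_round_trip(tmp_path):
    cfg = CityConfig(n_neighbourhoods=12, city_weights=(8, 4), city_labels=("A", "B"),
                     seed=1)
    nb = generate_neighbourhoods(cfg)
    p = tmp_path / "nb.geojson"
    write_neighbourhoods_geojson(nb, p)
    back = read_neighbourhoods_geojson(p)
    assert list(back["id"]) == list(nb["id"])
    assert back.attrs["crs"] == "planar_km"
    assert np.allclose(back["population"], nb["population"])
    assert back["geometry"].iloc[0].area == pytest.approx(nb["area_km2"].iloc[0])


def test_build_metrics_shape(small_config):
    nb = generate_neighbourhoods(small_config)
    est = classify_frame(generate_establishments(nb, small_config))
    assignment = assign_points(est, nb)
    m = build_metrics(nb, est, assignment)
    assert len(m) == len(nb)
    assert {"popdens", "sei", "density_total"} <= set(m.columns)
    assert (m.filter(like="density_") >= 0).all().all()
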