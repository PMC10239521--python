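"""Range-shift velocities and colonisation-route inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from climshift import SimulationConfig
from climshift.circular import circular_mean
from climshift.geo import ProvinceMap
from climshift.occupancy import OccupancyCube
from climshift.rangeshift import (
    infer_colonisation_vectors,
    northward_velocity,
    province_mean_shift_direction,
    velocity_correlation_by_period,
)
from climshift.synth import (
    generate_occupancy,
    generate_province_map,
    generate_traits,
    simulate_dataset,
)

TP = [1901, 1936, 1987, 2009, 2019]


def grid_map(nrows, ncols, lat0=55.0, lon0=15.0, dlat=1.0, dlon=2.0):
    """Rectangular lattice of provinces with known centroids."""
    ids, polys = [], []
    for i in range(nrows):
        for j in range(ncols):
            ids.append(f"R{i}C{j}")
            polys.append(
                box(lon0 + j * dlon, lat0 + i * dlat, lon0 + (j + 1) * dlon,
                    lat0 + (i + 1) * dlat)
            )
    return ProvinceMap(province_ids=ids, polygons=polys)


def cube_from_events(pmap, events, tp=TP, species=("S1",)):
    """events: {species: {province: first_time_point}}."""
    pres = np.zeros((len(species), len(pmap), len(tp)), dtype=bool)
    for s, sp in enumerate(species):
        for prov, t0 in events.get(sp, {}).items():
            j = tp.index(t0)
            pres[s, pmap.province_ids.index(prov), j:] = True
    return OccupancyCube(list(species), list(pmap.province_ids), np.array(tp), pres)


class TestNorthwardVelocity:
    def test_no_new_provinces_zero(self):
        pmap = grid_map(2, 1)
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1901}})
        v = northward_velocity(cube, pmap)
        assert (v["velocity_km_per_yr"] == 0).all()

    def test_two_degree_jump_velocity(self):
        # northernmost centroid moves 60.0 -> 62.0 N over 1901-1936
        pmap = grid_map(2, 1, lat0=59.5, dlat=1.0)
        # centroids at 60.0 and 61.0; use dlat=2 rows for a 2-degree jump
        pmap = grid_map(2, 1, lat0=59.0, dlat=2.0)  # centroids 60.0, 62.0
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1901, "R1C0": 1936}})
        v = northward_velocity(cube, pmap)
        row = v[(v.start == 1901)].iloc[0]
        assert row.velocity_km_per_yr == pytest.approx(222.39 / 35.0, rel=1e-3)
        assert row.origin_lat == pytest.approx(60.0)

    def test_southward_colonisation_gives_zero(self):
        pmap = grid_map(3, 1, lat0=59.0, dlat=1.0)
        cube = cube_from_events(pmap, {"S1": {"R2C0": 1901, "R0C0": 1936}})
        v = northward_velocity(cube, pmap)
        assert v[(v.start == 1901)]["velocity_km_per_yr"].item() == 0.0

    def test_species_absent_at_period_start_omitted(self):
        pmap = grid_map(2, 1)
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1987}})
        v = northward_velocity(cube, pmap)
        assert set(v["start"]) == {1987, 2009}

    def test_sample_sizes_grow_with_new_arrivals(self, default_dataset):
        v = northward_velocity(default_dataset["cube"], default_dataset["map"])
        n_by_period = v.groupby("start").size()
        assert n_by_period.is_monotonic_increasing

    def test_northernmost_latitude_non_decreasing(self, default_dataset):
        cube, pmap = default_dataset["cube"], default_dataset["map"]
        lats = np.array([pmap.centroid(p).lat for p in cube.province_ids])
        eff = cube.effective_presence()
        for s in range(0, cube.n_species, 7):
            maxlat = [
                lats[eff[s, :, j]].max() for j in range(len(cube.time_points))
                if eff[s, :, j].any()
            ]
            assert all(b >= a - 1e-12 for a, b in zip(maxlat, maxlat[1:]))


class TestColonisationVectors:
    def test_single_source_due_north(self):
        pmap = grid_map(2, 1, lat0=59.5, dlat=1.0)  # centroids 60.0, 61.0 at same lon
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1901, "R1C0": 1936}})
        vec = infer_colonisation_vectors(cube, pmap)
        assert len(vec) == 1
        row = vec.iloc[0]
        assert row.direction_deg == pytest.approx(0.0, abs=1e-9)
        assert row.magnitude_km == pytest.approx(111.19, abs=0.05)
        assert row.source_province_id == "R0C0"

    def test_equidistant_tie_broken_by_id(self):
        # two sources east and west, equidistant from the colonised province
        pmap = grid_map(1, 3, lat0=59.5, dlat=1.0, dlon=2.0)
        cube = cube_from_events(
            pmap, {"S1": {"R0C0": 1901, "R0C2": 1901, "R0C1": 1936}}
        )
        v1 = infer_colonisation_vectors(cube, pmap)
        v2 = infer_colonisation_vectors(cube, pmap)
        assert v1.iloc[0].source_province_id == "R0C0"  # lexicographically first
        pd.testing.assert_frame_equal(v1, v2)

    def test_debut_species_uses_period_end_sources(self):
        pmap = grid_map(1, 2, lat0=59.5)
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1936, "R0C1": 1936}})
        vec = infer_colonisation_vectors(cube, pmap)
        # both provinces debut: each draws its source from the other
        assert len(vec) == 2
        assert set(vec["source_province_id"]) == {"R0C0", "R0C1"}

    def test_single_province_debut_skipped(self):
        pmap = grid_map(1, 2, lat0=59.5)
        cube = cube_from_events(pmap, {"S1": {"R0C0": 1936}})
        vec = infer_colonisation_vectors(cube, pmap)
        assert len(vec) == 0

    def test_species_relabelling_preserves_vector_multiset(self, small_dataset):
        cube = small_dataset["cube"]
        pmap = small_dataset["map"]
        v1 = infer_colonisation_vectors(cube, pmap)
        perm = np.random.default_rng(0).permutation(cube.n_species)
        shuffled = OccupancyCube(
            [cube.species_ids[i] for i in perm],
            list(cube.province_ids),
            cube.time_points,
            cube.presence[perm],
        )
        v2 = infer_colonisation_vectors(shuffled, pmap)
        key = ["province_id", "source_province_id", "start", "end", "north_km", "east_km"]
        m1 = v1[key].sort_values(key).reset_index(drop=True)
        m2 = v2[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)


class TestProvinceMeanDirection:
    def test_single_vector(self):
        df = pd.DataFrame(
            [{"province_id": "A", "start": 1901, "end": 1936, "magnitude_km": 10.0,
              "direction_deg": 10.0}]
        )
        out = province_mean_shift_direction(df)
        assert out.iloc[0].mean_direction_deg == pytest.approx(10.0)
        assert out.iloc[0].n == 1

    def test_circular_averaging(self):
        df = pd.DataFrame(
            [
                {"province_id": "A", "start": 1901, "end": 1936, "magnitude_km": 1.0,
                 "direction_deg": d}
                for d in (350.0, 10.0)
            ]
        )
        out = province_mean_shift_direction(df)
        assert out.iloc[0].mean_direction_deg == pytest.approx(0.0, abs=1e-9)

    def test_resultant_for_orthogonal_pair(self):
        df = pd.DataFrame(
            [
                {"province_id": "A", "start": 1901, "end": 1936, "magnitude_km": 1.0,
                 "direction_deg": d}
                for d in (0.0, 90.0)
            ]
        )
        out = province_mean_shift_direction(df)
        assert out.iloc[0].mean_direction_deg == pytest.approx(45.0, abs=1e-9)
        assert out.iloc[0].resultant_length == pytest.approx(np.cos(np.pi / 4), rel=1e-9)


class TestNorthwardModeRecovery:
    def test_forced_northward_colonisation_points_north(self):
        """When the generator forces nearest-northern-neighbour colonisation,
        inferred route directions concentrate on due north."""
        means = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_provinces=100, n_species=30)
            data = simulate_dataset(cfg)
            cube = generate_occupancy(
                cfg, data["map"], data["province_temps"], data["traits"],
                mode="northward",
            )
            vec = infer_colonisation_vectors(cube, data["map"])
            dirs = province_mean_shift_direction(vec)
            m, _ = circular_mean(dirs["mean_direction_deg"].dropna())
            means.append(m)
        grand, _ = circular_mean(means)
        assert min(grand, 360.0 - grand) <= 10.0

    def test_northward_mode_velocities_non_negative(self):
        cfg = SimulationConfig(seed=3, n_provinces=60, n_species=20)
        data = simulate_dataset(cfg)
        cube = generate_occupancy(
            cfg, data["map"], data["province_temps"], data["traits"], mode="northward"
        )
        v = northward_velocity(cube, data["map"])
        assert (v["velocity_km_per_yr"] >= 0).all()


class TestVelocityCorrelation:
    def _fake_inputs(self, rho, n, seed):
        rng = np.random.default_rng(seed)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        return xy[:, 0], xy[:, 1]

    def test_perfect_correlation(self, small_dataset):
        grid = small_dataset["grid"]
        # species velocity == temperature velocity at the same cells
        cells = grid.cell_ids[:20]
        cv = pd.DataFrame(
            {
                "cell_id": cells,
                "start": 1901,
                "end": 1936,
                "north_km": np.linspace(10, 200, len(cells)),
            }
        )
        rv = pd.DataFrame(
            {
                "species_id": [f"S{i}" for i in range(len(cells))],
                "start": 1901,
                "end": 1936,
                "velocity_km_per_yr": np.linspace(10, 200, len(cells)) / 35.0,
                "origin_lat": [grid.centroid(int(c)).lat for c in cells],
                "origin_lon": [grid.centroid(int(c)).lon for c in cells],
            }
        )
        out = velocity_correlation_by_period(rv, cv, grid)
        pooled = out[out.period == "pooled"].iloc[0]
        assert pooled.r == pytest.approx(1.0, abs=1e-9)

    def test_constant_velocity_flagged_undefined(self, small_dataset):
        grid = small_dataset["grid"]
        cells = grid.cell_ids[:10]
        cv = pd.DataFrame(
            {"cell_id": cells, "start": 1901, "end": 1936, "north_km": 50.0}
        )
        rv = pd.DataFrame(
            {
                "species_id": [f"S{i}" for i in range(len(cells))],
                "start": 1901,
                "end": 1936,
                "velocity_km_per_yr": np.linspace(0, 1, len(cells)),
                "origin_lat": [grid.centroid(int(c)).lat for c in cells],
                "origin_lon": [grid.centroid(int(c)).lon for c in cells],
            }
        )
        out = velocity_correlation_by_period(rv, cv, grid)
        assert np.isnan(out[out.period == "pooled"].iloc[0].r)

    def test_sampling_distribution_of_r(self):
        """Pearson r at n=500, rho=0.5: estimate lands in [0.42, 0.58]."""
        x, y = self._fake_inputs(0.5, 500, seed=8)
        r, _ = stats.pearsonr(x, y)
        assert 0.42 <= r <= 0.58
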