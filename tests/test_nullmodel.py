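import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare
from shapely.geometry import MultiPolygon, Point, box

from parep.grid import GridSpec
from parep.nullmodel import (
    PlacementInfeasibleError,
    ReplicateFailureError,
    build_null_network,
    climate_randomization,
    rand_test,
    randomize_decade,
    replicate_seed,
    sample_transform,
)
from parep.representation import DecadalCohort, ProtectedArea
from parep.sdm import BinaryRangeMap

STUDY = box(0.0, 0.0, 30.0, 30.0)


class TestSampleTransform:
    def test_area_and_perimeter_preserved(self, rng):
        poly = box(0, 0, 4, 7)
        for _ in range(50):
            _, out = sample_transform(poly, STUDY, rng)
            assert abs(out.area - poly.area) / poly.area < 1e-9
            assert abs(out.length - poly.length) / poly.length < 1e-9

    def test_placement_stays_inside_study(self, rng):
        poly = box(0, 0, 5, 5)
        for _ in range(100):
            _, out = sample_transform(poly, STUDY, rng)
            assert STUDY.covers(out)

    def test_too_large_polygon_infeasible(self, rng):
        with pytest.raises(PlacementInfeasibleError):
            sample_transform(box(0, 0, 40, 40), STUDY, rng)

    def test_multipart_moves_as_rigid_unit(self, rng):
        mp = MultiPolygon([box(0, 0, 2, 2), box(5, 0, 7, 2)])
        for _ in range(20):
            _, out = sample_transform(mp, STUDY, rng)
            parts = list(out.geoms)
            # relative distance between part centroids is preserved
            d = parts[0].centroid.distance(parts[1].centroid)
            assert d == pytest.approx(5.0, abs=1e-9)

    def test_disc_centers_uniform_over_feasible_region(self, rng):
        # a disc is rotation-invariant, so accepted centers should be
        # uniform over the feasible square; chi-square on a 4x4 partition
        disc = Point(0.0, 0.0).buffer(3.0, quad_segs=64)
        lo, hi = 3.0, 27.0
        counts = np.zeros((4, 4))
        n = 4000
        for _ in range(n):
            _, out = sample_transform(disc, STUDY, rng)
            c = out.centroid
            i = min(int((c.y - lo) / (hi - lo) * 4), 3)
            j = min(int((c.x - lo) / (hi - lo) * 4), 3)
            counts[i, j] += 1
        stat, p = chisquare(counts.ravel())
        assert p > 0.001

    def test_non_rectangular_study_containment(self, rng):
        tri = box(0, 0, 30, 30).difference(box(15, 15, 31, 31))
        poly = box(0, 0, 3, 3)
        for _ in range(50):
            _, out = sample_transform(poly, tri, rng)
            assert tri.covers(out)


def _cohort(areas, label="d", y0=2000, y1=2009):
    members = [
        ProtectedArea(f"{label}_{i}", box(0, 0, np.sqrt(a), np.sqrt(a)), y0)
        for i, a in enumerate(areas)
    ]
    return DecadalCohort(label, y0, y1, members)


class TestBuildNullNetwork:
    def test_placements_disjoint_and_area_conserved(self, rng):
        cohort = _cohort([36.0, 25.0, 16.0, 9.0])
        fixed = [ProtectedArea("f", box(10, 10, 16, 16), 1990)]
        placed = build_null_network(cohort, fixed, STUDY, rng)
        geoms = [g for (_, _, g) in placed]
        total = sum(g.area for g in geoms)
        assert total == pytest.approx(cohort.total_area_km2, rel=1e-9)
        all_geoms = geoms + [f.geometry for f in fixed]
        for i in range(len(all_geoms)):
            for j in range(i + 1, len(all_geoms)):
                assert all_geoms[i].intersection(all_geoms[j]).area < 1e-9

    def test_same_seed_identical_placements(self):
        cohort = _cohort([25.0, 16.0])
        p1 = build_null_network(cohort, [], STUDY, np.random.default_rng(42))
        p2 = build_null_network(cohort, [], STUDY, np.random.default_rng(42))
        for (id1, t1, g1), (id2, t2, g2) in zip(p1, p2):
            assert id1 == id2 and t1 == t2
            assert g1.equals_exact(g2, 0)

    def test_largest_first_order(self, rng):
        cohort = _cohort([9.0, 36.0, 16.0])
        placed = build_null_network(cohort, [], STUDY, rng)
        areas = [g.area for (_, _, g) in placed]
        assert areas == sorted(areas, reverse=True)

    def test_pigeonhole_infeasible(self, rng):
        cohort = _cohort([500.0, 450.0])  # 950 > 900 study area
        with pytest.raises(PlacementInfeasibleError):
            build_null_network(cohort, [], STUDY, rng)


class TestRandTest:
    def test_observed_above_all_nulls(self):
        res = rand_test(50.0, np.linspace(0, 40, 100))
        assert res.p_value == pytest.approx(1.0 / 101.0)
        assert res.significant

    def test_observed_equal_to_all_nulls(self):
        res = rand_test(10.0, np.full(100, 10.0))
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_observed_below_all_nulls_one_sided(self):
        res = rand_test(1.0, np.linspace(10, 20, 100))
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_minimum_null_size_for_alpha(self):
        # with N = 19 the smallest attainable p is 1/20 = alpha
        res = rand_test(5.0, np.zeros(19))
        assert res.p_value == pytest.approx(0.05)
        assert res.significant
        with pytest.raises(ValueError):
            rand_test(1.0, [])


def _toy_species(grid, n=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    maps = {}
    groups = ["bird", "bird", "plant", "plant", "amphibian", "reptile"]
    for i in range(n):
        sid = f"s{i}"
        p = np.zeros(grid.shape, bool)
        r0, c0 = rng.integers(0, grid.n_rows - 4), rng.integers(0, grid.n_cols - 4)
        p[r0 : r0 + 3, c0 : c0 + 3] = True
        maps[sid] = BinaryRangeMap(sid, "current", p, grid)
        rows.append(
            {"species_id": sid, "group": groups[i % len(groups)],
             "threatened": i % 3 == 0}
        )
    return pd.DataFrame(rows), maps


class TestRandomizeDecade:
    grid = GridSpec(15, 15, cell_side=2.0)

    def test_single_replicate_and_determinism(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        cohort = _cohort([36.0, 16.0])
        reps1, obs1 = randomize_decade(
            cohort, [], study, self.grid, table, maps, targets,
            n_replicates=1, seed=9,
        )
        reps2, obs2 = randomize_decade(
            cohort, [], study, self.grid, table, maps, targets,
            n_replicates=1, seed=9,
        )
        assert len(reps1) == 1
        assert obs1 == obs2
        assert reps1[0].seed == replicate_seed(9, 1)
        assert reps1[0].group_representation == reps2[0].group_representation

    def test_different_master_seeds_differ(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        cohort = _cohort([36.0, 16.0])
        reps1, _ = randomize_decade(cohort, [], study, self.grid, table, maps,
                                    targets, n_replicates=3, seed=1)
        reps2, _ = randomize_decade(cohort, [], study, self.grid, table, maps,
                                    targets, n_replicates=3, seed=2)
        g1 = [g for r in reps1 for (_, _, g) in r.placed]
        g2 = [g for r in reps2 for (_, _, g) in r.placed]
        assert any(not a.equals(b) for a, b in zip(g1, g2))

    def test_replicate_failure_names_cohort_and_replicate(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        # fixed network fills nearly everything -> placement infeasible
        fixed = [ProtectedArea("f", box(0, 0, 29.9, 29.9), 1990)]
        cohort = _cohort([100.0], label="tight")
        with pytest.raises(ReplicateFailureError, match="tight"):
            randomize_decade(cohort, fixed, study, self.grid, table, maps,
                             targets, n_replicates=1, seed=3)


class TestPower:
    """Reserves targeted at species blocks must look non-random, with
    detection frequency monotone in how many reserves are on target."""

    grid = GridSpec(20, 20, cell_side=1.0)
    blocks = [(3, 3), (3, 13), (13, 3), (13, 13)]  # far-apart 3x3 ranges
    off_target = [(8.5, 0.5), (8.5, 5.5), (8.5, 10.5), (8.5, 15.5)]

    def _corner_species(self):
        rows, maps = [], {}
        for i, (r0, c0) in enumerate(self.blocks):
            p = np.zeros(self.grid.shape, bool)
            p[r0 : r0 + 3, c0 : c0 + 3] = True
            maps[f"s{i}"] = BinaryRangeMap(f"s{i}", "current", p, self.grid)
            rows.append({"species_id": f"s{i}", "group": "bird",
                         "threatened": False})
        return pd.DataFrame(rows), maps

    def _cohort(self, n_on_target):
        pas = []
        for j in range(4):
            if j < n_on_target:
                r0, c0 = self.blocks[j]
                geom = box(c0 - 0.5, r0 - 0.5, c0 + 3.5, r0 + 3.5)
            else:
                y, x = self.off_target[j]
                geom = box(x, y, x + 4.0, y + 4.0)
            pas.append(ProtectedArea(f"p{j}", geom, 2000))
        return DecadalCohort("d", 2000, 2009, pas)

    def test_significance_monotone_in_placement_bias(self):
        table, maps = self._corner_species()
        targets = {s: 0.9 for s in maps}
        study = box(*self.grid.bounds)
        rejections = []
        for n_on_target in (0, 2, 4):
            sig = 0
            for seed in range(5):
                reps, obs = randomize_decade(
                    self._cohort(n_on_target), [], study, self.grid, table,
                    maps, targets, n_replicates=80, seed=seed,
                )
                nulls = [r.group_representation["bird"] for r in reps]
                sig += rand_test(obs["bird"], nulls).significant
            rejections.append(sig)
        assert rejections == sorted(rejections)
        assert rejections[0] == 0  # untargeted cohort looks random
        assert rejections[-1] == 5  # fully targeted cohort always detected


class TestClimateRandomization:
    grid = GridSpec(15, 15, cell_side=2.0)

    def test_future_equal_to_current_reproduces_current_test(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        cohort = _cohort([36.0, 16.0], label="2006-2015", y0=2006, y1=2015)
        fut45 = {
            s: BinaryRangeMap(s, "rcp45", m.presence, self.grid)
            for s, m in maps.items()
        }
        out = climate_randomization(
            cohort, [], study, self.grid, table, {"rcp45": fut45}, targets,
            n_replicates=5, seed=4,
        )
        reps, obs = randomize_decade(
            cohort, [], study, self.grid, table, maps, targets,
            n_replicates=5, seed=replicate_seed(4, 104729),
        )
        all_row = out[out["stratum"] == "bird"].iloc[0]
        assert all_row["observed"] == pytest.approx(obs["bird"])

    def test_all_future_ranges_empty_gives_p_one(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        cohort = _cohort([36.0], label="2006-2015", y0=2006, y1=2015)
        empty = {
            s: BinaryRangeMap(s, "rcp85", np.zeros(self.grid.shape, bool),
                              self.grid)
            for s in maps
        }
        out = climate_randomization(
            cohort, [], study, self.grid, table, {"rcp85": empty}, targets,
            n_replicates=5, seed=4,
        )
        assert (out["observed"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()
        assert not out["significant"].any()

    def test_missing_future_species_listed(self):
        study = box(*self.grid.bounds)
        table, maps = _toy_species(self.grid)
        targets = {s: 0.3 for s in maps}
        cohort = _cohort([36.0], label="2006-2015", y0=2006, y1=2015)
        with pytest.raises(ValueError, match="s0"):
            climate_randomization(
                cohort, [], study, self.grid, table, {"rcp45": {}}, targets,
                n_replicates=2, seed=4,
            )
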