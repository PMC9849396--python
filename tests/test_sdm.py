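import numpy as np
import pytest

from parep.grid import GridSpec
from parep.sdm import (
    BinaryRangeMap,
    SuitabilityMap,
    UnmodellableSpeciesError,
    apply_dispersal,
    average_gcms,
    clip_to_occurrences,
    ensemble,
    evaluate_auc,
    evaluate_tss,
    filter_members,
    qc_ensemble,
    range_edge,
    threshold_10pct,
)

G8 = GridSpec(8, 8, cell_side=1.0)


def centers(grid):
    cx, cy = grid.cell_centers()
    return np.column_stack([cx, cy])


def suit(values, grid=G8, tss=0.9, auc=0.9, sid="sp", tag="m"):
    return SuitabilityMap(sid, tag, np.asarray(values, float), grid, tss, auc)


def brute_force_auc(sp, sa):
    wins = sum(
        1.0 if p > a else 0.5 if p == a else 0.0 for p in sp for a in sa
    )
    return wins / (len(sp) * len(sa))


class TestTSS:
    def test_perfect_prediction_scores_one(self):
        pred = np.zeros(G8.shape, bool)
        pred[:, :4] = True
        pres = np.array([[0.5, 0.5], [1.5, 1.5]])
        abse = np.array([[6.5, 6.5], [7.5, 7.5]])
        assert evaluate_tss(pred, pres, abse, G8) == pytest.approx(1.0)

    def test_sens_and_spec_combine_linearly(self):
        # sens 0.9, spec 0.8 -> 0.7 by definition
        grid = GridSpec(1, 20, cell_side=1.0)
        pred = np.zeros(grid.shape, bool)
        pred[0, :9] = True  # 9 of 10 presences predicted present
        pred[0, 10:12] = True  # 2 of 10 absences predicted present
        pres = np.column_stack([np.arange(10) + 0.5, np.full(10, 0.5)])
        abse = np.column_stack([np.arange(10, 20) + 0.5, np.full(10, 0.5)])
        assert evaluate_tss(pred, pres, abse, grid) == pytest.approx(0.7)

    def test_uninformative_prediction_scores_zero(self):
        grid = GridSpec(1, 4, cell_side=1.0)
        pred = np.array([[True, False, True, False]])
        pres = np.array([[0.5, 0.5], [1.5, 0.5]])
        abse = np.array([[2.5, 0.5], [3.5, 0.5]])
        assert evaluate_tss(pred, pres, abse, grid) == pytest.approx(0.0)

    def test_off_grid_point_named_in_error(self):
        pred = np.zeros(G8.shape, bool)
        with pytest.raises(ValueError, match="9.5"):
            evaluate_tss(pred, np.array([[9.5, 1.0]]), np.array([[0.5, 0.5]]), G8)


class TestAUC:
    def test_perfect_separation(self):
        grid = GridSpec(1, 4, cell_side=1.0)
        s = np.array([[0.9, 0.8, 0.2, 0.1]])
        pres = np.array([[0.5, 0.5], [1.5, 0.5]])
        abse = np.array([[2.5, 0.5], [3.5, 0.5]])
        assert evaluate_auc(s, pres, abse, grid) == pytest.approx(1.0)

    def test_three_of_four_concordant_pairs(self):
        # presence scores {0.9, 0.4}, absence {0.5, 0.1} -> 3/4 concordant
        grid = GridSpec(1, 4, cell_side=1.0)
        s = np.array([[0.9, 0.4, 0.5, 0.1]])
        pres = np.array([[0.5, 0.5], [1.5, 0.5]])
        abse = np.array([[2.5, 0.5], [3.5, 0.5]])
        assert evaluate_auc(s, pres, abse, grid) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        grid = GridSpec(1, 4, cell_side=1.0)
        s = np.full((1, 4), 0.3)
        pres = np.array([[0.5, 0.5], [1.5, 0.5]])
        abse = np.array([[2.5, 0.5], [3.5, 0.5]])
        assert evaluate_auc(s, pres, abse, grid) == pytest.approx(0.5)

    def test_rank_formula_equals_brute_force_pair_count(self, rng):
        # 50 random instances up to 200 points, exact agreement
        for _ in range(50):
            n_p = int(rng.integers(1, 100))
            n_a = int(rng.integers(1, 100))
            n = n_p + n_a
            grid = GridSpec(1, n, cell_side=1.0)
            scores = rng.choice([0.0, 0.1, 0.25, 0.5, 0.77, 1.0], size=n)
            pts = np.column_stack([np.arange(n) + 0.5, np.full(n, 0.5)])
            pres, abse = pts[:n_p], pts[n_p:]
            got = evaluate_auc(scores.reshape(1, -1), pres, abse, grid)
            want = brute_force_auc(scores[:n_p], scores[n_p:])
            assert abs(got - want) < 1e-12

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 60
        grid = GridSpec(1, n, cell_side=1.0)
        scores = rng.random(n)
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 1, 0
        pts = np.column_stack([np.arange(n) + 0.5, np.full(n, 0.5)])
        got = evaluate_auc(
            scores.reshape(1, -1), pts[labels == 1], pts[labels == 0], grid
        )
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestFilterAndQC:
    def test_strict_member_filter(self):
        z = np.zeros(G8.shape)
        keep = suit(z, tss=0.85, auc=0.90)
        boundary = suit(z, tss=0.80, auc=0.95)
        low_auc = suit(z, tss=0.95, auc=0.80)
        out = filter_members([keep, boundary, low_auc])
        assert out == [keep]
        assert filter_members([]) == []

    def test_filter_idempotent(self):
        z = np.zeros(G8.shape)
        members = [suit(z, tss=t, auc=a) for t, a in
                   [(0.85, 0.9), (0.5, 0.9), (0.9, 0.7)]]
        once = filter_members(members)
        assert filter_members(once) == once

    @pytest.mark.parametrize(
        "tss,auc,kept",
        [(0.942, 0.987, True), (0.69, 0.95, False), (0.7, 0.8, True),
         (0.9, 0.79, False)],
    )
    def test_ensemble_qc_rule(self, tss, auc, kept):
        assert qc_ensemble(tss, auc) is kept

    def test_member_qc_table_mirrors_filter(self, tmp_path):
        from parep.sdm import member_qc_table

        z = np.zeros(G8.shape)
        members = [suit(z, tss=t, auc=a, tag=f"m{i}")
                   for i, (t, a) in enumerate([(0.85, 0.9), (0.8, 0.95),
                                               (0.95, 0.5)])]
        table = member_qc_table(members)
        assert list(table.columns) == ["species_id", "technique", "tss",
                                       "auc", "kept"]
        assert table["kept"].tolist() == [True, False, False]
        kept_ids = {m.technique_tag for m in filter_members(members)}
        assert set(table[table["kept"]]["technique"]) == kept_ids
        table.to_csv(tmp_path / "qc.csv", index=False)
        assert (tmp_path / "qc.csv").exists()


class TestEnsemble:
    def test_single_member_identity(self):
        m = suit(np.random.default_rng(0).random(G8.shape), tss=0.9)
        out = ensemble([m])
        np.testing.assert_allclose(out.values, m.values)

    def test_equal_tss_gives_mean(self):
        a = suit(np.full(G8.shape, 0.2), tss=0.85)
        b = suit(np.full(G8.shape, 0.6), tss=0.85)
        np.testing.assert_allclose(ensemble([a, b]).values, 0.4)

    def test_tss_weight_ratio(self):
        # cells 1.0 and 0.0 with TSS 0.9 vs 0.8 -> 0.9/1.7
        a = suit(np.ones(G8.shape), tss=0.9)
        b = suit(np.zeros(G8.shape), tss=0.8)
        np.testing.assert_allclose(
            ensemble([a, b]).values, 0.9 / 1.7, atol=1e-12
        )

    def test_output_bounded_by_members(self, rng):
        members = [suit(rng.random(G8.shape), tss=t) for t in (0.82, 0.9, 0.95)]
        out = ensemble(members).values
        stack = np.stack([m.values for m in members])
        assert (out <= stack.max(0) + 1e-12).all()
        assert (out >= stack.min(0) - 1e-12).all()

    def test_no_members_marks_species_unmodellable(self):
        with pytest.raises(UnmodellableSpeciesError):
            ensemble([])


class TestThreshold:
    def test_linear_interpolation_percentile(self):
        # presences at suitabilities 0.1..1.0 -> 10th percentile = 0.19
        grid = GridSpec(1, 10, cell_side=1.0)
        vals = (np.arange(10) + 1) / 10.0
        s = suit(vals.reshape(1, -1), grid=grid)
        pts = np.column_stack([np.arange(10) + 0.5, np.full(10, 0.5)])
        out = threshold_10pct(s, pts)
        expected = vals >= 0.19
        np.testing.assert_array_equal(out.presence[0], expected)
        # ≥ 90% of training presences inside the predicted range
        rc = grid.points_to_cells(pts)
        assert out.presence[rc[:, 0], rc[:, 1]].mean() >= 0.9

    def test_single_presence_threshold_is_its_suitability(self):
        s = suit(np.linspace(0, 1, 64).reshape(8, 8))
        pt = np.array([[3.5, 3.5]])
        out = threshold_10pct(s, pt)
        rc = G8.points_to_cells(pt)
        assert out.presence[rc[0, 0], rc[0, 1]]
        t = s.values[rc[0, 0], rc[0, 1]]
        np.testing.assert_array_equal(out.presence, s.values >= t)

    def test_uniform_suitability_predicts_everywhere(self):
        s = suit(np.full(G8.shape, 0.5))
        out = threshold_10pct(s, np.array([[0.5, 0.5]]))
        assert out.presence.all()

    def test_nodata_only_presences_rejected(self):
        vals = np.full(G8.shape, np.nan)
        vals[0, 0] = 0.4
        s = suit(vals)
        with pytest.raises(ValueError, match="nodata"):
            threshold_10pct(s, np.array([[5.5, 5.5]]))


class TestClipToOccurrences:
    def make_range(self, presence):
        return BinaryRangeMap("sp", "current", presence, G8)

    def test_distance_beyond_diagonal_is_identity(self, rng):
        presence = rng.random(G8.shape) > 0.4
        r = self.make_range(presence)
        out = clip_to_occurrences(r, np.array([[4.0, 4.0]]), max_dist=100.0)
        np.testing.assert_array_equal(out.presence, presence)

    def test_neighborhood_clip_matches_brute_force(self, rng):
        presence = np.ones(G8.shape, bool)
        r = self.make_range(presence)
        occ = np.array([[3.5, 4.5], [6.1, 1.2]])
        max_dist = 2.0
        out = clip_to_occurrences(r, occ, max_dist)
        cx, cy = G8.cell_centers()
        for i, (x, y) in enumerate(zip(cx, cy)):
            d = min(np.hypot(x - ox, y - oy) for ox, oy in occ)
            assert out.presence.ravel()[i] == (d <= max_dist)

    def test_empty_range_stays_empty(self):
        r = self.make_range(np.zeros(G8.shape, bool))
        out = clip_to_occurrences(r, np.array([[1.0, 1.0]]), 3.0)
        assert out.is_empty

    def test_requires_occurrences(self):
        r = self.make_range(np.ones(G8.shape, bool))
        with pytest.raises(ValueError):
            clip_to_occurrences(r, np.empty((0, 2)), 3.0)


class TestGcmAveraging:
    def test_mean_of_two(self):
        a = suit(np.full(G8.shape, 0.2))
        b = suit(np.full(G8.shape, 0.6))
        np.testing.assert_allclose(average_gcms([a, b]).values, 0.4)

    def test_single_input_identity(self):
        a = suit(np.random.default_rng(3).random(G8.shape))
        np.testing.assert_allclose(average_gcms([a]).values, a.values)

    def test_grid_mismatch_rejected(self):
        a = suit(np.zeros(G8.shape))
        b = suit(np.zeros((4, 4)), grid=GridSpec(4, 4, cell_side=1.0))
        with pytest.raises(ValueError, match="mismatch"):
            average_gcms([a, b])


class TestDispersal:
    def make_maps(self, cur, fut):
        return (
            BinaryRangeMap("sp", "rcp45", fut, G8),
            BinaryRangeMap("sp", "current", cur, G8),
        )

    def test_infinite_distance_is_identity(self, rng):
        fut, cur = self.make_maps(rng.random(G8.shape) > 0.5,
                                  rng.random(G8.shape) > 0.5)
        out = apply_dispersal(fut, cur, np.inf)
        np.testing.assert_array_equal(out.presence, fut.presence)

    def test_zero_distance_restricts_to_current_overlap(self, rng):
        fut, cur = self.make_maps(rng.random(G8.shape) > 0.5,
                                  rng.random(G8.shape) > 0.5)
        out = apply_dispersal(fut, cur, 0.0)
        np.testing.assert_array_equal(
            out.presence, fut.presence & cur.presence
        )

    def test_retained_cells_within_distance_of_current(self):
        cur = np.zeros(G8.shape, bool)
        cur[4, 4] = True
        fut = np.ones(G8.shape, bool)
        fmap, cmap = self.make_maps(cur, fut)
        out = apply_dispersal(fmap, cmap, 2.0)
        cx, cy = G8.cell_centers()
        d = np.hypot(cx - 4.5, cy - 4.5).reshape(G8.shape)
        np.testing.assert_array_equal(out.presence, d <= 2.0)

    def test_edge_cells_identified_with_border_as_absent(self):
        p = np.ones((3, 3), bool)
        edge = range_edge(p)
        want = np.ones((3, 3), bool)
        want[1, 1] = False
        np.testing.assert_array_equal(edge, want)


class TestAntiExtensivity:
    def test_postprocessing_chain_never_adds_cells(self, rng):
        for _ in range(25):
            vals = rng.random(G8.shape)
            s = suit(vals)
            n_occ = int(rng.integers(1, 6))
            occ = rng.uniform(0.2, 7.8, size=(n_occ, 2))
            binary = threshold_10pct(s, occ)
            clipped = clip_to_occurrences(binary, occ, float(rng.uniform(1, 6)))
            assert not (clipped.presence & ~binary.presence).any()
            fut = BinaryRangeMap("sp", "rcp85", rng.random(G8.shape) > 0.4, G8)
            disp = apply_dispersal(fut, clipped, float(rng.uniform(0, 4)))
            assert not (disp.presence & ~fut.presence).any()
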