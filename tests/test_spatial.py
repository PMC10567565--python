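"""Neighbor graph, crowding and interaction statistics, growth kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from camii import fixtures as fx
from camii import spatial as sp
from camii.stats import bh_adjust, holm_adjust, mann_whitney


def _colonies(rows):
    df = pd.DataFrame(rows, columns=["colony_id", "x_px", "y_px", "radius_px"])
    df["plate_barcode"] = "P1"
    return df


class TestNeighborGraph:
    def test_threshold_rule_45px_neighbors_55px_not(self):
        near = _colonies([("a", 0.0, 0.0, 10.0), ("b", 45.0, 0.0, 10.0)])
        g = sp.build_neighbor_graph(near)
        assert g.has_edge("a", "b")  # 45 < 30 + 10 + 10
        far = _colonies([("a", 0.0, 0.0, 10.0), ("b", 55.0, 0.0, 10.0)])
        assert sp.build_neighbor_graph(far).number_of_edges() == 0

    def test_single_colony_no_edges(self):
        g = sp.build_neighbor_graph(_colonies([("a", 0.0, 0.0, 5.0)]))
        assert g.number_of_edges() == 0 and g.nodes["a"]["n_neighbors"] == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sp.build_neighbor_graph(
                _colonies([("a", 0.0, 0.0, 5.0), ("a", 90.0, 0.0, 5.0)])
            )

    def test_edges_only_within_plates(self):
        df = _colonies([("a", 0.0, 0.0, 10.0), ("b", 45.0, 0.0, 10.0)])
        df.loc[1, "plate_barcode"] = "P2"
        assert sp.build_neighbor_graph(df).number_of_edges() == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_irreflexive_translation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        df = _colonies(
            [
                (f"c{i}", float(rng.uniform(0, 300)), float(rng.uniform(0, 300)),
                 float(rng.uniform(2, 15)))
                for i in range(n)
            ]
        )
        g = sp.build_neighbor_graph(df)
        assert all(u != v for u, v in g.edges)
        shifted = df.assign(x_px=df.x_px + 123.4, y_px=df.y_px - 55.5)
        g2 = sp.build_neighbor_graph(shifted)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, g2.edges))


class TestMannWhitney:
    def test_separated_groups_exact_enumeration(self):
        # all 3 high ranks on one side: 1 of C(6,3)=20 splits
        assert mann_whitney([4, 5, 6], [1, 2, 3], "greater").p == pytest.approx(1 / 20)

    def test_fully_tied_p_one_either_direction(self):
        a = [5.0] * 6
        assert mann_whitney(a, a, "greater").p == 1.0
        assert mann_whitney(a, a, "less").p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_path_matches_scipy_oracle(self, alternative, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        x = rng.normal(size=n1)  # continuous: no ties, scipy exact applies
        y = rng.normal(size=n2)
        mine = mann_whitney(x, y, alternative)
        ref = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        assert mine.method == "exact"
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_asymptotic_path_close_to_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 80)
        mine = mann_whitney(x, y, "greater")
        ref = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert mine.method == "asymptotic"
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        ps = [
            mann_whitney(rng.normal(size=30), rng.normal(size=30), "greater").p
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestAdjustments:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_bh_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_against_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(
                holm_adjust(p), multipletests(p, method="holm")[1], atol=1e-12
            )
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        p = np.array(p)
        for adj in (holm_adjust(p), bh_adjust(p)):
            assert np.all(adj >= p - 1e-12)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCrowding:
    def test_exact_p_on_separated_groups(self):
        res = sp.crowding_test(
            areas=[1, 2, 3, 4, 5, 6], neighbor_counts=[0, 1, 1, 4, 5, 6],
            alternative="greater",
        )
        assert res.p == pytest.approx(0.05)
        assert (res.n_low, res.n_high) == (3, 3)

    def test_constant_areas_fully_tied(self):
        res = sp.crowding_test([7.0] * 8, [0, 0, 1, 1, 4, 4, 5, 5], alternative="greater")
        assert res.p == 1.0
        res = sp.crowding_test([7.0] * 8, [0, 0, 1, 1, 4, 4, 5, 5], alternative="less")
        assert res.p == 1.0

    def test_empty_group_named(self):
        with pytest.raises(ValueError, match="high-crowding"):
            sp.crowding_test([1, 2], [0, 1])


class TestInteractionNetwork:
    def test_planted_fold_recovered_and_significant(self):
        profiles = [
            fx.GenusProfile("A", np.zeros(14), 1.0, 8.0, 0.5),
            fx.GenusProfile("B", np.zeros(14), 1.0, 8.0, 0.5),
        ]
        spec = fx.CommunitySpec(
            genera=profiles, interactions=[("A", "B", 1.5)], n_colonies=1000, seed=13
        )
        table, _ = fx.generate_spatial_community(spec)
        edges = {(e.source, e.target): e for e in sp.interaction_network(table)}
        e = edges[("A", "B")]
        assert 1.35 <= e.effect_size <= 1.65
        assert e.p_adjusted < 0.05 and e.direction == "promoting"

    def test_holm_spans_all_tests_and_orders_p(self):
        profiles = [
            fx.GenusProfile(g, np.zeros(14), 1.0, 8.0, 1 / 3) for g in "ABC"
        ]
        table, _ = fx.generate_spatial_community(
            fx.CommunitySpec(genera=profiles, n_colonies=600, seed=14)
        )
        edges = sp.interaction_network(table)
        assert edges, "expected testable genus pairs"
        for e in edges:
            assert e.p_adjusted >= e.p_raw - 1e-12
            assert e.n_with >= 5 and e.n_without >= 5

    def test_fewer_than_two_genera_rejected(self):
        df = pd.DataFrame(
            {"colony_id": ["a", "b"], "x_px": [0.0, 200.0], "y_px": [0.0, 0.0],
             "radius_px": [5.0, 5.0], "area_px2": [10.0, 12.0], "genus": ["A", "A"]}
        )
        with pytest.raises(ValueError, match="2 genera"):
            sp.interaction_network(df)


class TestTracking:
    @staticmethod
    def _day(day, rows):
        return pd.DataFrame(
            [(cid, x, y, a, day) for cid, x, y, a in rows],
            columns=["colony_id", "x_px", "y_px", "area_px2", "day"],
        )

    def test_drifting_colony_forms_one_track(self):
        tracks = sp.track_colonies(
            [self._day(3, [("a", 100.0, 100.0, 10.0)]),
             self._day(6, [("b", 101.0, 100.0, 30.0)])],
            tolerance=5,
        )
        assert len(tracks) == 1 and tracks[0].first_day == 3
        assert sorted(tracks[0].detections) == [3, 6]

    def test_distant_colonies_stay_separate(self):
        tracks = sp.track_colonies(
            [self._day(1, [("a", 0.0, 0.0, 1.0)]),
             self._day(2, [("b", 100.0, 0.0, 1.0)])],
            tolerance=5,
        )
        assert len(tracks) == 2

    def test_equidistant_tie_broken_to_lowest_id(self):
        tracks = sp.track_colonies(
            [self._day(5, [("p", 100.0, 100.0, 1.0)]),
             self._day(6, [("q2", 103.0, 100.0, 1.0), ("q1", 97.0, 100.0, 1.0)])],
            tolerance=5,
        )
        matched = [t for t in tracks if t.first_day == 5][0]
        assert matched.colony_ids[6] == "q1"
        assert len(tracks) == 2

    def test_days_out_of_order_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            sp.track_colonies(
                [self._day(6, [("a", 0.0, 0.0, 1.0)]),
                 self._day(3, [("b", 0.0, 0.0, 1.0)])]
            )


class TestDetectableProportion:
    @staticmethod
    def _staggered_tracks():
        tables = [
            pd.DataFrame(
                [(f"c{i}_{d}", 50.0 * i, 0.0, 1.0, d) for i in range(1, 5) if i <= d],
                columns=["colony_id", "x_px", "y_px", "area_px2", "day"],
            )
            for d in (1, 2, 3, 4)
        ]
        return sp.track_colonies(tables, tolerance=5)

    def test_staggered_appearance_cumulative_row(self):
        tracks = self._staggered_tracks()
        labels = {f"c{i}_4": "G" for i in range(1, 5)}
        prop = sp.detectable_proportion(tracks, labels)
        assert prop.loc["G"].tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_rows_non_decreasing_and_end_at_one(self):
        tracks = self._staggered_tracks()
        labels = {f"c{i}_4": ("G1" if i % 2 else "G2") for i in range(1, 5)}
        prop = sp.detectable_proportion(tracks, labels)
        for _, row in prop.iterrows():
            assert np.all(np.diff(row.to_numpy()) >= 0)
            assert row.iloc[-1] == 1.0

    def test_half_visible_midway(self):
        tracks = self._staggered_tracks()
        labels = {f"c{i}_4": "G" for i in range(1, 5)}
        prop = sp.detectable_proportion(tracks, labels)
        assert prop.loc["G", 2] == 0.5
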