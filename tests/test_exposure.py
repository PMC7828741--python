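"""Shortest paths, percentile maps, 500-m segmentation, exposure profiles,
maximum-difference statistics, permutation test, shares and overlays."""

import numpy as np
import networkx as nx
import pytest
from scipy import stats
from shapely.geometry import LineString

import ciclovia as cv
from ciclovia import exposure as expo
from ciclovia.core import StreetNetwork, ValidationError, route_from_nodes
from ciclovia.exposure import (ExposureDataset, RoutingError,
                               SegmentExposureProfile, add_one_p_value,
                               max_percentile_difference, polyline_pieces,
                               segment_values, ses_percentile_map)
from conftest import exposure_dataset, make_units, route_trajectories


def lattice(rows, cols, side=500.0):
    """Corner-node lattice over a rows x cols grid of cells."""
    g = nx.Graph()
    for r in range(rows + 1):
        for c in range(cols + 1):
            g.add_node(r * (cols + 1) + c, x=c * side, y=r * side)
    for r in range(rows + 1):
        for c in range(cols + 1):
            if c < cols:
                g.add_edge(r * (cols + 1) + c, r * (cols + 1) + c + 1,
                           length_m=side)
            if r < rows:
                g.add_edge(r * (cols + 1) + c, (r + 1) * (cols + 1) + c,
                           length_m=side)
    return StreetNetwork(g)


class TestShortestPath:
    def test_origin_equals_destination(self):
        net = lattice(2, 2)
        t = expo.shortest_path_trajectory(net, 3, 3)
        assert t.nodes == (3,) and t.total_length_m == 0.0

    def test_lattice_corner_to_corner_manhattan(self):
        net = lattice(2, 2)  # 3x3 nodes
        t = expo.shortest_path_trajectory(net, 0, 8)
        assert t.total_length_m == pytest.approx(4 * 500.0)
        # lexicographically smallest tie-break: straight east then north
        assert t.nodes == (0, 1, 2, 5, 8)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            g = nx.gnm_random_graph(n, int(rng.integers(n, 2 * n)),
                                    seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g.edges[u, v]["length_m"] = float(rng.uniform(10, 500))
            comp = max(nx.connected_components(g), key=len)
            g = g.subgraph(comp).copy()
            if g.number_of_nodes() < 2:
                continue
            for node in g.nodes:
                g.nodes[node]["x"] = g.nodes[node]["y"] = 0.0
            net = StreetNetwork(g)
            nodes = sorted(g.nodes)
            o, d = rng.choice(nodes, size=2, replace=False)
            t = expo.shortest_path_trajectory(net, int(o), int(d))
            oracle = expo.brute_force_shortest_length(net, int(o), int(d))
            assert t.total_length_m == pytest.approx(oracle, rel=1e-12)

    def test_disconnected_pair_names_both_nodes(self):
        g = nx.Graph()
        g.add_node(1, x=0.0, y=0.0)
        g.add_node(2, x=1.0, y=0.0)
        g.add_node(3, x=2.0, y=0.0)
        g.add_edge(1, 2, length_m=1.0)
        with pytest.raises(RoutingError, match="1.*3|3.*1"):
            expo.shortest_path_trajectory(StreetNetwork(g), 1, 3)


class TestPercentileMap:
    def test_two_equal_population_units(self):
        units = make_units([(200, 0, 0), (0, 0, 200)])
        pmap = ses_percentile_map(units)
        assert pmap[0] == pytest.approx(25.0)
        assert pmap[1] == pytest.approx(75.0)

    def test_all_tied_scores_share_fifty(self):
        units = make_units([(10, 10, 10)] * 4, cols=4)
        pmap = ses_percentile_map(units)
        assert all(v == pytest.approx(50.0) for v in pmap.values())

    def test_population_weighted_mean_is_fifty(self):
        rng = np.random.default_rng(3)
        units = make_units(rng.integers(1, 300, size=(30, 3)), cols=6)
        pmap = ses_percentile_map(units)
        pops = np.array([u.population for u in units], float)
        pcts = np.array([pmap[u.unit_id] for u in units])
        assert np.dot(pops, pcts) / pops.sum() == pytest.approx(50.0, abs=0.5)

    def test_zero_population_raises(self):
        units = make_units([(0, 0, 0), (0, 0, 0)])
        with pytest.raises(ValidationError):
            ses_percentile_map(units)


class TestSegmentation:
    def test_single_unit_path(self):
        # 1200 m wholly inside a percentile-80 unit -> three bands of 80
        vals = segment_values([(1200.0, 7)], {7: 80.0})
        assert vals == [80.0, 80.0, 80.0]

    def test_two_unit_construction(self):
        vals = segment_values([(500.0, 1), (500.0, 2)], {1: 20.0, 2: 90.0})
        assert vals == [20.0, 90.0]

    def test_three_unit_mid_band_weighted_mean(self):
        # hand-computed: band 0 = (400*10 + 100*50)/500 = 18
        pieces = [(400.0, 0), (600.0, 1), (300.0, 2)]
        pmap = {0: 10.0, 1: 50.0, 2: 90.0}
        vals = segment_values(pieces, pmap)
        assert vals[0] == pytest.approx(18.0, abs=1e-9)
        assert vals[1] == pytest.approx(50.0, abs=1e-9)
        assert vals[2] == pytest.approx(90.0, abs=1e-9)

    def test_short_tail_dropped(self):
        vals = segment_values([(1020.0, 0)], {0: 60.0})
        assert len(vals) == 2
        vals = segment_values([(1050.0, 0)], {0: 60.0})
        assert len(vals) == 3

    def test_geometric_pieces_match_hand_geometry(self):
        # diagonal line crossing two 500-m squares: equal halves
        units = make_units([(10, 0, 0), (0, 0, 10)])
        line = LineString([(250, 250), (750, 250)])
        pieces = polyline_pieces(line, units)
        assert [(round(ln), uid) for ln, uid in pieces] == [(250, 0), (250, 1)]

    def test_outside_tessellation_raises(self):
        units = make_units([(10, 0, 0)])
        with pytest.raises(expo.JoinError):
            polyline_pieces(LineString([(10_000, 10_000), (10_500, 10_000)]),
                            units)


class TestProfilesAndMaxDiff:
    def test_single_participant_variance_zero(self, planted_city):
        parts = cv.generate_participants(planted_city, 3, seed=0)
        ds = exposure_dataset(planted_city, parts)
        for g in np.unique(ds.labels):
            prof = ds.profile(g)
            assert np.all(prof.variance[prof.n_participants == 1] == 0.0)

    def test_two_participant_band_arithmetic(self):
        values = np.array([[20.0], [40.0]])
        ds = ExposureDataset(values, np.array([20.0, 40.0]),
                             np.array(["low", "low"]), np.arange(2))
        prof = ds.profile("low")
        assert prof.mean_percentile[0] == pytest.approx(30.0)
        assert prof.variance[0] == pytest.approx(200.0)

    def test_participants_per_band_non_increasing(self, planted_city):
        parts = cv.generate_participants(planted_city, 200, seed=2)
        ds = exposure_dataset(planted_city, parts)
        for g in np.unique(ds.labels):
            n = ds.profile(g).n_participants
            assert np.all(np.diff(n) <= 0)

    def test_flat_profile_zero_diff_first_band(self):
        prof = SegmentExposureProfile("low", np.array([30.0, 30.0]),
                                      np.zeros(2), np.array([50, 50]))
        res = max_percentile_difference(prof, 30.0)
        assert res.max_diff == 0.0
        assert res.distance_km == pytest.approx(0.25)

    def test_constructed_profile_max(self):
        prof = SegmentExposureProfile("low", np.array([10.0, 30.0, 55.0]),
                                      np.zeros(3), np.array([60, 40, 20]))
        res = max_percentile_difference(prof, 10.0)
        assert res.max_diff == pytest.approx(45.0)
        assert res.distance_km == pytest.approx(1.25)

    def test_min_n_gating_and_undefined(self):
        prof = SegmentExposureProfile("low", np.array([10.0, 90.0]),
                                      np.zeros(2), np.array([50, 3]))
        res = max_percentile_difference(prof, 10.0, min_n=10)
        assert res.max_diff == pytest.approx(0.0)  # far band ineligible
        res2 = max_percentile_difference(prof, 10.0, min_n=100)
        assert not res2.defined

    def test_signs_by_origin_group_over_seeds(self):
        for seed in range(20):
            cfg = cv.CityConfig(grid_rows=4, grid_cols=12,
                                gradient_strength=6.0, mixing_noise=12.0,
                                seed=seed)
            city = cv.generate_city(cfg)
            parts = cv.generate_participants(city, 250, seed=seed)
            ds = exposure_dataset(city, parts)
            assert ds.max_difference("low", min_n=5).max_diff > 0
            assert ds.max_difference("high", min_n=5).max_diff < 0


class TestPermutation:
    def test_add_one_formula(self):
        assert add_one_p_value(0, 99) == pytest.approx(1 / 100)
        assert add_one_p_value(99, 99) == 1.0
        with pytest.raises(ValidationError):
            add_one_p_value(100, 99)

    def test_zero_statistic_gives_p_one(self):
        values = np.full((20, 2), 50.0)
        ds = ExposureDataset(values, np.full(20, 50.0),
                             np.array(["low"] * 10 + ["high"] * 10),
                             np.arange(20))
        assert ds.permutation_test("low", B=99, seed=0, min_n=2) == 1.0

    def test_single_label_roster_raises(self):
        ds = ExposureDataset(np.ones((5, 1)), np.ones(5),
                             np.array(["low"] * 5), np.arange(5))
        with pytest.raises(ValidationError):
            ds.permutation_test("low", B=99, seed=0)

    def test_null_p_values_uniform_ks(self):
        """Labels independent of trajectories -> p-values uniform."""
        city = cv.generate_city(cv.CityConfig(
            grid_rows=4, grid_cols=10, gradient_strength=2.0,
            mixing_noise=6.0, seed=9))
        parts = cv.generate_participants(city, 80, seed=9)
        ds = exposure_dataset(city, parts)
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(500):
            labels = rng.permutation(ds.labels)
            shuffled = ExposureDataset(ds.values, ds.origin_percentile,
                                       labels, ds.participant_ids)
            ps.append(shuffled.permutation_test(
                "low", B=99, seed=int(rng.integers(2**31)), min_n=5))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSharesAndOverlay:
    def test_share_constructions(self):
        units = make_units([(0, 100, 0), (0, 100, 0)])
        net = lattice(1, 2)
        traj = expo.shortest_path_trajectory(net, 0, 2, 0, "middle")
        assignment = expo.EdgeUnitAssignment(net, units)
        shares = expo.trajectory_ses_shares([traj], assignment)
        assert shares["middle"] == pytest.approx(
            {"low": 0.0, "middle": 1.0, "high": 0.0})

        units2 = make_units([(100, 0, 0), (0, 100, 0)])
        assignment2 = expo.EdgeUnitAssignment(net, units2)
        shares2 = expo.trajectory_ses_shares(
            [expo.shortest_path_trajectory(net, 0, 2, 0, "low")], assignment2)
        assert shares2["low"] == pytest.approx(
            {"low": 0.5, "middle": 0.5, "high": 0.0})

    def test_zero_length_excluded_with_warning(self):
        units = make_units([(0, 100, 0)])
        net = lattice(1, 1)
        assignment = expo.EdgeUnitAssignment(net, units)
        t0 = expo.shortest_path_trajectory(net, 0, 0, 0, "middle")
        t1 = expo.shortest_path_trajectory(net, 0, 1, 1, "middle")
        with pytest.warns(UserWarning, match="zero-length"):
            shares = expo.trajectory_ses_shares([t0, t1], assignment)
        assert shares["middle"]["middle"] == pytest.approx(1.0)

    def test_per_participant_shares_sum_to_one(self, gradient_city):
        parts = cv.generate_participants(gradient_city, 60, seed=8)
        assignment = expo.EdgeUnitAssignment(gradient_city.network,
                                             gradient_city.units)
        for t in route_trajectories(gradient_city, parts):
            if t.total_length_m <= 0:
                continue
            pieces = assignment.trajectory_pieces(t)
            assert sum(ln for ln, _ in pieces) == pytest.approx(
                t.total_length_m, abs=1e-6)

    def test_overlay_single_unit_route(self):
        units = make_units([(0, 0, 100)])
        net = lattice(1, 1)
        route = route_from_nodes(net, [0, 1])
        ov = expo.route_overlay(route, units, {0: "highly_segregated"})
        assert ov.by_ses["high"] == pytest.approx(1.0)
        assert ov.by_class["highly_segregated"] == pytest.approx(1.0)

    def test_overlay_fractions_sum_to_one(self, gradient_city):
        res = cv.theil_index(cv.CompositionTable.from_units(
            gradient_city.units))
        classes = dict(zip(res.per_unit["unit_id"],
                           res.per_unit["entropy_class"]))
        ov = expo.route_overlay(gradient_city.route, gradient_city.units,
                                classes)
        assert sum(ov.by_ses.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(ov.by_class.values()) == pytest.approx(1.0, abs=1e-9)
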