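"""Interaction graphs, network extraction and lymphoid-aggregate calls."""

import numpy as np
import pandas as pd
import pytest

import marrowmap as mm
from marrowmap.networks import (LABEL_LA, LABEL_T_DOMINANT, SIZE_BELOW,
                                SIZE_LARGE, SIZE_NETWORK)

from _oracles import brute_force_pruned_edges


def cells_df(xy):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"cell_id": np.arange(len(xy)),
                         "x_um": xy[:, 0], "y_um": xy[:, 1]})


def chain(n, spacing=8.0):
    return [[i * spacing, 0.0] for i in range(n)]


class TestInteractionGraph:
    def test_two_cells_within_threshold(self):
        g = mm.build_interaction_graph(cells_df([[0, 0], [5, 0]]))
        assert g.edges == {(0, 1)}
        assert g.mode == "distance_graph"  # n < 3 falls back

    def test_two_cells_beyond_threshold(self):
        g = mm.build_interaction_graph(cells_df([[0, 0], [15, 0]]))
        assert g.edges == set()

    def test_threshold_inclusive(self):
        g = mm.build_interaction_graph(cells_df([[0, 0], [10, 0]]))
        assert g.edges == {(0, 1)}

    def test_collinear_points_fall_back_to_distance_graph(self):
        g = mm.build_interaction_graph(cells_df(chain(5)))
        assert g.mode == "distance_graph"
        assert len(g.edges) == 4

    def test_matches_circumcircle_oracle(self, rng):
        # pruned Delaunay edges equal the brute-force empty-circumcircle
        # enumeration on random 25-point maps
        for _ in range(20):
            xy = rng.uniform(0, 60, (25, 2))
            g = mm.build_interaction_graph(cells_df(xy), delta_um=10.0)
            assert g.mode == "delaunay_pruned"
            assert g.edges == brute_force_pruned_edges(xy, 10.0)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            mm.build_interaction_graph(cells_df([[1, 1], [1, 1], [5, 5]]))

    def test_duplicate_jitter_is_deterministic(self):
        df = cells_df([[1, 1], [1, 1], [5, 5], [9, 1]])
        g1 = mm.build_interaction_graph(df, jitter_duplicates=True, jitter_seed=4)
        g2 = mm.build_interaction_graph(df, jitter_duplicates=True, jitter_seed=4)
        assert g1.edges == g2.edges

    def test_pruned_delaunay_is_subgraph_of_distance_graph(self, rng):
        xy = rng.uniform(0, 120, (80, 2))
        pruned = mm.build_interaction_graph(cells_df(xy), mode="delaunay_pruned")
        dist = mm.build_interaction_graph(cells_df(xy), mode="distance_graph")
        assert pruned.edges <= dist.edges

    def test_component_refinement(self, rng):
        # every pruned-Delaunay component is inside one distance component
        import networkx as nx
        xy = rng.uniform(0, 150, (120, 2))
        pruned = mm.build_interaction_graph(cells_df(xy), mode="delaunay_pruned")
        dist = mm.build_interaction_graph(cells_df(xy), mode="distance_graph")
        dist_comp = {n: i for i, c in enumerate(nx.connected_components(dist.graph))
                     for n in c}
        for comp in nx.connected_components(pruned.graph):
            assert len({dist_comp[n] for n in comp}) == 1


class TestExtractNetworks:
    def test_nine_cell_chain_below_threshold(self):
        g = mm.build_interaction_graph(cells_df(chain(9)))
        nets = mm.extract_networks(g)
        assert len(nets) == 1
        assert nets[0].size_class == SIZE_BELOW

    def test_ten_cell_chain_is_network(self):
        g = mm.build_interaction_graph(cells_df(chain(10)))
        nets = mm.extract_networks(g)
        assert nets[0].size == 10
        assert nets[0].size_class == SIZE_NETWORK

    def test_boundary_99_vs_100(self):
        for n, expected in ((99, SIZE_NETWORK), (100, SIZE_LARGE)):
            side = 10
            xy = [[7.0 * (i % side), 7.0 * (i // side)] for i in range(n)]
            g = mm.build_interaction_graph(cells_df(xy))
            nets = mm.extract_networks(g)
            assert nets[0].size == n
            assert nets[0].size_class == expected

    def test_components_partition_cells(self, rng):
        xy = rng.uniform(0, 200, (150, 2))
        g = mm.build_interaction_graph(cells_df(xy))
        nets = mm.extract_networks(g)
        assert sum(n.size for n in nets) == 150
        all_ids = [cid for n in nets for cid in n.cell_ids]
        assert len(set(all_ids)) == 150

    def test_monotone_in_delta(self, rng):
        xy = rng.uniform(0, 100, (60, 2))
        sizes = []
        for delta in (5.0, 10.0, 20.0):
            g = mm.build_interaction_graph(cells_df(xy), delta_um=delta,
                                           mode="distance_graph")
            sizes.append(max(n.size for n in mm.extract_networks(g)))
        assert sizes == sorted(sizes)

    def test_raising_n_min_never_increases_network_count(self, rng):
        xy = rng.uniform(0, 150, (200, 2))
        g = mm.build_interaction_graph(cells_df(xy))
        counts = [sum(1 for n in mm.extract_networks(g, n_min=k) if n.size >= k)
                  for k in (2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_collinear_hull_degenerate(self):
        g = mm.build_interaction_graph(cells_df(chain(4)))
        nets = mm.extract_networks(g)
        assert nets[0].hull_area_um2 == 0.0

    def test_translation_rotation_invariance(self, rng):
        xy = rng.uniform(0, 100, (80, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + [1000.0, -400.0]
        for mode in ("delaunay_pruned", "distance_graph"):
            n1 = mm.extract_networks(mm.build_interaction_graph(cells_df(xy), mode=mode))
            n2 = mm.extract_networks(mm.build_interaction_graph(cells_df(moved), mode=mode))
            assert sorted(n.size for n in n1) == sorted(n.size for n in n2)


class TestLymphoidAggregates:
    def grid(self, n, pitch=7.0, origin=(0.0, 0.0)):
        side = int(np.ceil(np.sqrt(n)))
        return [[origin[0] + pitch * (i % side), origin[1] + pitch * (i // side)]
                for i in range(n)]

    def large_t_network(self, origin=(0.0, 0.0)):
        g = mm.build_interaction_graph(cells_df(self.grid(120, origin=origin)))
        nets = mm.extract_networks(g)
        assert nets[0].size_class == SIZE_LARGE
        return nets

    def test_no_b_cells_means_t_dominant(self):
        t_nets = self.large_t_network()
        calls = mm.detect_lymphoid_aggregates(t_nets, [])
        assert [c.label for c in calls] == [LABEL_T_DOMINANT]
        assert isinstance(calls[0].mixing_score, mm.Undefined)

    def test_interleaved_b_cells_make_la(self, rng):
        t_nets = self.large_t_network()
        b_xy = rng.uniform(0, 70, (30, 2))  # inside the T grid footprint
        b_nets = mm.extract_networks(mm.build_interaction_graph(
            cells_df(b_xy), mode="distance_graph"))
        if b_nets[0].size < 10:  # ensure a dense B network
            b_xy = np.array(self.grid(30, pitch=6.0, origin=(10.0, 10.0)))
            b_nets = mm.extract_networks(mm.build_interaction_graph(cells_df(b_xy)))
        calls = mm.detect_lymphoid_aggregates(t_nets, b_nets)
        assert calls[0].label == LABEL_LA
        assert calls[0].n_b >= 10

    def test_colocalization_distance_inclusive(self):
        t_nets = self.large_t_network()
        t_coords = t_nets[0].coords
        x_max = t_coords[:, 0].max()
        # B chain exactly coloc_delta away from the nearest T cell
        b_xy = [[x_max + 20.0, 0.0 + 6.0 * i] for i in range(12)]
        b_nets = mm.extract_networks(mm.build_interaction_graph(cells_df(b_xy)))
        calls = mm.detect_lymphoid_aggregates(t_nets, b_nets, coloc_delta_um=20.0)
        assert calls[0].label == LABEL_LA
        assert calls[0].colocalization_distance_um == pytest.approx(20.0)
        # just beyond: T-dominant
        b_far = [[x_max + 20.001, 0.0 + 6.0 * i] for i in range(12)]
        b_nets_far = mm.extract_networks(mm.build_interaction_graph(cells_df(b_far)))
        calls_far = mm.detect_lymphoid_aggregates(t_nets, b_nets_far,
                                                  coloc_delta_um=20.0)
        assert calls_far[0].label == LABEL_T_DOMINANT

    def test_sparse_b_network_does_not_qualify(self):
        t_nets = self.large_t_network()
        b_nets = mm.extract_networks(mm.build_interaction_graph(
            cells_df([[5.0, 5.0], [11.0, 5.0]])))
        calls = mm.detect_lymphoid_aggregates(t_nets, b_nets)
        assert calls[0].label == LABEL_T_DOMINANT


class TestMixingScore:
    def test_fully_mixed_is_one(self):
        # alternating T/B lattice: every B cell has T neighbours
        t, b = [], []
        for i in range(10):
            for j in range(10):
                (t if (i + j) % 2 == 0 else b).append([7.0 * i, 7.0 * j])
        assert mm.mixing_score(np.array(t), np.array(b), k=5) == 1.0

    def test_zonated_layout_scores_low(self, rng):
        # compact central B disc ringed by distant T cells
        angles = rng.uniform(0, 2 * np.pi, 200)
        radii = 15.0 * np.sqrt(rng.uniform(0, 1, 200))
        b = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        ring_angles = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        t = np.column_stack([300 * np.cos(ring_angles), 300 * np.sin(ring_angles)])
        assert mm.mixing_score(t, b, k=5) < 0.5

    def test_no_b_cells_undefined(self):
        res = mm.mixing_score(np.array([[0, 0], [5, 0]]), np.empty((0, 2)))
        assert isinstance(res, mm.Undefined)

    def test_k_too_large_fails(self):
        with pytest.raises(ValueError, match="k="):
            mm.mixing_score(np.array([[0, 0]]), np.array([[1, 0]]), k=5)


class TestPlantedRecovery:
    def make_map(self, seed, n_agg_cells=120, background=50.0):
        cfg = mm.CellMapSimConfig(
            background_intensity={"T": background},
            aggregates=[mm.AggregateSpec({"T": 1.0}, n_agg_cells, 4.0)]
            if n_agg_cells else [],
            min_cell_spacing_um=1.0, seed=seed)
        return mm.simulate_cellmap(cfg)

    def test_planted_aggregates_recovered(self):
        for seed in range(5):
            m, truth = self.make_map(seed)
            nets = mm.extract_networks(mm.graph_for_phenotype(m, "T"))
            assert sum(1 for n in nets if n.size_class == SIZE_LARGE) == 1

    def test_two_planted_aggregates_counted(self):
        cfg = mm.CellMapSimConfig(
            background_intensity={"T": 30.0},
            aggregates=[
                mm.AggregateSpec({"T": 1.0}, 120, 4.0, center=(200.0, 200.0)),
                mm.AggregateSpec({"T": 1.0}, 120, 4.0, center=(700.0, 700.0))],
            min_cell_spacing_um=1.0, seed=3)
        m, _ = mm.simulate_cellmap(cfg)
        nets = mm.extract_networks(mm.graph_for_phenotype(m, "T"))
        summary = mm.summarize_networks(m, nets)
        assert summary.n_large_networks == 2

    def test_background_only_has_no_large_networks(self):
        for seed in range(5):
            m, _ = self.make_map(seed + 100, n_agg_cells=0, background=200.0)
            nets = mm.extract_networks(mm.graph_for_phenotype(m, "T"))
            assert all(n.size_class != SIZE_LARGE for n in nets)


class TestSummaries:
    def test_networks_per_mm2(self, cellmap_factory):
        xy = (chain(12) + [[x + 500, y] for x, y in chain(15)]
              + [[x, y + 500] for x, y in chain(11)])
        m = cellmap_factory(xy, ["T"] * len(xy), area_mm2=0.5)
        nets = mm.extract_networks(mm.graph_for_phenotype(m, "T"))
        s = mm.summarize_networks(m, nets)
        assert s.n_networks == 3
        assert s.networks_per_mm2 == pytest.approx(6.0)
        assert s.networks_per_mm2 * m.tissue_area_mm2 == pytest.approx(3)

    def test_empty_map_all_zero(self, cellmap_factory):
        m = cellmap_factory(np.empty((0, 2)), [], area_mm2=1.0)
        nets = mm.extract_networks(mm.graph_for_phenotype(m, "T"))
        s = mm.summarize_networks(m, nets)
        assert (s.n_networks, s.n_large_networks, s.n_lymphoid_aggregates) == (0, 0, 0)
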