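"""LSMI patch growth: hand traces, the no-retrace ledger, and an exhaustive
comparison against an independent brute-force patch enumerator."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import patchboot as pb
from patchboot.lsmi import lsmi, sample_seeds, subpatch


def brute_force_patch(adj: dict, seed: int, d: int):
    """Independent reference LSMI: explicit edge ledger, wave by wave.

    Returns a list of per-wave Counters of recorded vertices (multiplicity =
    number of distinct untraced edges through which the vertex was first
    reached at that wave).
    """
    untraced = {frozenset(e) for u in adj for e in ((u, v) for v in adj[u])}
    recorded = {seed}
    frontier = {seed}
    waves = []
    for _ in range(d):
        counts = Counter()
        crossing = [e for e in untraced if e & frontier]
        for e in crossing:
            untraced.discard(e)
        for e in crossing:
            ends = set(e)
            newcomers = ends - recorded
            for v in newcomers - frontier:
                counts[v] += 1
        waves.append(counts)
        recorded |= set(counts)
        frontier = set(counts)
    return waves


class TestHandTraces:
    def test_path_one_wave(self, path_graph):
        ps = lsmi(path_graph, [1], 1)
        patch = ps.patches[0]
        assert patch.seed_degree == 2
        assert sorted(d for _, d in patch.waves[0]) == [1, 2]

    def test_depth_zero_records_seeds_only(self, path_graph):
        ps = lsmi(path_graph, [0, 2], 0)
        assert all(p.waves == () for p in ps.patches)
        np.testing.assert_array_equal(ps.seed_degrees(), [1, 2])
        assert ps.nonseed_degrees().size == 0

    def test_triangle_no_retrace(self, triangle):
        # wave 1 reaches both neighbours; the third edge is traced at wave 2
        # but both endpoints are already recorded, so wave 2 is empty
        ps = lsmi(triangle, [0], 2)
        patch = ps.patches[0]
        assert sorted(d for _, d in patch.waves[0]) == [2, 2]
        assert patch.waves[1] == ()

    def test_square_multiple_inclusion(self):
        # 0-1, 0-2, 1-3, 2-3: vertex 3 is reached at wave 2 through two
        # distinct untraced edges and is recorded twice
        g = pb.SimpleGraph.from_edges(4, [(0, 1), (0, 2), (1, 3), (2, 3)])
        patch = lsmi(g, [0], 2).patches[0]
        assert [v for v, _ in patch.waves[1]] == [3, 3]

    def test_seed_in_anothers_patch_is_recorded(self, path_graph):
        # patches grow independently: seed 2 appears in seed 1's wave
        ps = lsmi(path_graph, [1, 2], 1)
        wave1_vertices = [v for v, _ in ps.patches[0].waves[0]]
        assert 2 in wave1_vertices

    def test_errors(self, path_graph):
        with pytest.raises(ValueError):
            lsmi(path_graph, [9], 1)
        with pytest.raises(ValueError):
            lsmi(path_graph, [1, 1], 1)
        with pytest.raises(ValueError):
            lsmi(path_graph, [1], -1)


class TestExhaustiveAgainstBruteForce:
    def test_all_small_connected_graphs(self):
        """Every connected graph on ≤ 6 vertices, every seed, every d ≤ 3."""
        atlas = [
            g
            for g in nx.graph_atlas_g()
            if 2 <= g.number_of_nodes() <= 6
            and g.number_of_edges()
            and nx.is_connected(g)
        ]
        assert len(atlas) > 100
        for nxg in atlas:
            graph = pb.SimpleGraph.from_edges(nxg.number_of_nodes(), nxg.edges())
            adj = {v: set(graph.adjacency[v]) for v in range(graph.n)}
            for seed in range(graph.n):
                for d in range(4):
                    patch = lsmi(graph, [seed], d).patches[0]
                    expected = brute_force_patch(adj, seed, d)
                    got = [Counter(v for v, _ in wave) for wave in patch.waves]
                    assert got == expected, (sorted(nxg.edges()), seed, d)

    def test_edge_ledger_bound(self, fixture_graph_23):
        # inclusion records in a patch never exceed edges incident to it:
        # every record consumes one previously untraced edge
        g = fixture_graph_23
        for seed in range(g.n):
            patch = lsmi(g, [seed], 3).patches[0]
            n_records = sum(len(w) for w in patch.waves)
            assert n_records <= g.num_edges


class TestSampleSeeds:
    def test_exhaustive_when_m_equals_n(self, fixture_graph_23, rng):
        seeds = sample_seeds(fixture_graph_23, 23, rng)
        assert sorted(seeds.tolist()) == list(range(23))

    def test_bounds(self, fixture_graph_23, rng):
        with pytest.raises(ValueError):
            sample_seeds(fixture_graph_23, 24, rng)

    def test_uniformity_chi2(self, fixture_graph_23):
        rng = np.random.default_rng(8)
        counts = np.zeros(23)
        draws = 10_000
        for _ in range(draws):
            counts[sample_seeds(fixture_graph_23, 1, rng)[0]] += 1
        stat = ((counts - draws / 23) ** 2 / (draws / 23)).sum()
        assert stat < stats.chi2.ppf(0.99, df=22)


class TestSubpatch:
    def test_identity(self, fixture_graph_23, rng):
        ps = lsmi(fixture_graph_23, sample_seeds(fixture_graph_23, 10, rng), 3)
        assert subpatch(ps, ps.m, ps.d_max) == ps

    def test_zero_waves_view(self, fixture_graph_23, rng):
        ps = lsmi(fixture_graph_23, sample_seeds(fixture_graph_23, 10, rng), 3)
        view = subpatch(ps, 5, 0)
        assert view.m == 5 and view.nonseed_degrees().size == 0

    def test_nested_monotonicity(self, fixture_graph_23, rng):
        ps = lsmi(fixture_graph_23, sample_seeds(fixture_graph_23, 10, rng), 3)
        sizes = {
            (m, w): subpatch(ps, m, w).nonseed_degrees().size
            for m in range(1, 11)
            for w in range(4)
        }
        for m in range(1, 11):
            for w in range(4):
                if m > 1:
                    assert sizes[(m, w)] >= sizes[(m - 1, w)]
                if w > 0:
                    assert sizes[(m, w)] >= sizes[(m, w - 1)]

    def test_bounds(self, fixture_graph_23, rng):
        ps = lsmi(fixture_graph_23, sample_seeds(fixture_graph_23, 10, rng), 3)
        with pytest.raises(ValueError):
            subpatch(ps, 11, 1)
        with pytest.raises(ValueError):
            subpatch(ps, 5, 4)


class TestStatisticalProperties:
    def test_seeds_only_mean_is_unbiased(self, ztp_graph_2000):
        """Grand mean of seeds-only estimates over many samplings matches the
        realized mean degree within 3 Monte-Carlo standard errors."""
        g = ztp_graph_2000
        rng = np.random.default_rng(77)
        reps, m = 10_000, 30
        degs = g.degrees
        ests = np.array(
            [degs[rng.choice(g.n, m, replace=False)].mean() for _ in range(reps)]
        )
        se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - degs.mean()) < 3 * se

    def test_waves_reduce_bootstrap_spread(self):
        """Adding waves of non-seeds shrinks the bootstrap SD of the mean
        degree (the variance half of the bias-variance trade-off)."""
        rng = np.random.default_rng(303)
        g = pb.generate_graph(pb.polylog_model(0.1, 2), 10_000, rng)
        seeds = sample_seeds(g, 30, rng)
        ps = lsmi(g, seeds, 2)
        sd = {}
        for w in (0, 2):
            bs = pb.resample_patches(subpatch(ps, 30, w), 500, rng)
            sd[w] = bs.mean_degree.std(ddof=1)
        assert sd[2] < sd[0]

    def test_serialization_roundtrip(self, fixture_graph_23, rng):
        ps = lsmi(fixture_graph_23, sample_seeds(fixture_graph_23, 5, rng), 2)
        assert pb.PatchSet.from_json(ps.to_json()) == ps
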