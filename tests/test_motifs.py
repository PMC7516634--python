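"""Subgraph enumeration, canonical labeling, null models and Z-scores."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motifemerge as me
from motifemerge.motifs import (
    MotifCensus,
    NullModelConfig,
    ProfileEntry,
    SignificanceProfile,
    adjacency_string,
    decode_matrix,
    skeleton_code,
)
from conftest import random_digraph


def _adj(edges, k):
    m = np.zeros((k, k), dtype=np.int64)
    for i, j in edges:
        m[i, j] = 1
    return m


class TestCanonicalCode:
    def test_relabelings_of_a_chain_share_a_code(self):
        chain = _adj([(0, 1), (1, 2)], 3)
        relabeled = _adj([(2, 0), (0, 1)], 3)  # same chain, nodes renamed
        assert me.canonical_code(chain) == me.canonical_code(relabeled)

    def test_chain_and_fan_distinct(self):
        chain = _adj([(0, 1), (1, 2)], 3)
        fan = _adj([(0, 1), (0, 2)], 3)
        assert me.canonical_code(chain) != me.canonical_code(fan)

    def test_thirteen_weakly_connected_triad_classes(self):
        """Exhaustive enumeration of all 2^6 arc sets on 3 labelled nodes
        yields exactly 13 weakly connected isomorphism classes."""
        arcs = [(i, j) for i in range(3) for j in range(3) if i != j]
        codes = set()
        for mask in range(2 ** 6):
            edges = [arcs[b] for b in range(6) if mask >> b & 1]
            und = nx.Graph(edges)
            und.add_nodes_from(range(3))
            if not nx.is_connected(und):
                continue
            codes.add(me.canonical_code(_adj(edges, 3)))
        assert len(codes) == 13

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 12 - 1), st.permutations(list(range(4))))
    def test_permutation_invariance_random_k4(self, mask, perm):
        arcs = [(i, j) for i in range(4) for j in range(4) if i != j]
        m = np.zeros((4, 4), dtype=np.int64)
        for b in range(12):
            if mask >> b & 1:
                m[arcs[b]] = 1
        permuted = m[np.ix_(perm, perm)]
        assert me.canonical_code(m) == me.canonical_code(permuted)

    def test_colored_codes_separate_color_patterns(self):
        plain = _adj([(0, 1), (1, 2)], 3)
        colored = plain.copy()
        colored[0, 1] = 2  # strong positive arc
        assert me.canonical_code(plain, colored=True) != \
            me.canonical_code(colored, colored=True)
        # their uncolored skeletons agree
        code = me.canonical_code(colored, colored=True)
        assert skeleton_code(code, 3) == me.canonical_code(plain)

    def test_decode_inverts_encode(self):
        m = _adj([(0, 1), (1, 2), (2, 0)], 3)
        code = me.canonical_code(m)
        decoded = decode_matrix(code, 3)
        assert me.canonical_code(decoded) == code
        assert adjacency_string(code, 3) == "".join(
            str(d) for d in decoded.ravel())


class TestESU:
    def test_directed_four_path(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 3)])
        census = me.enumerate_connected_subgraphs(g, 4)
        assert census.total == 1
        assert list(census.counts.values()) == [1]

    def test_bifan_single_class(self):
        g = nx.DiGraph([(0, 2), (0, 3), (1, 2), (1, 3)])
        census = me.enumerate_connected_subgraphs(g, 4)
        assert census.total == 1
        bifan = _adj([(0, 2), (0, 3), (1, 2), (1, 3)], 4)
        assert set(census.counts) == {me.canonical_code(bifan)}

    def test_layered_2_2_1_matches_subset_oracle(self):
        g = nx.DiGraph()
        for u in (0, 1):
            for v in (2, 3):
                g.add_edge(u, v)
        for v in (2, 3):
            g.add_edge(v, 4)
        esu = me.enumerate_connected_subgraphs(g, 4)
        oracle = me.brute_force_census(g, 4)
        assert esu.counts == oracle.counts
        assert esu.total == oracle.total

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_esu_equals_brute_force_on_random_digraphs(self, k):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(k, 11))
            g = random_digraph(n, 0.3, rng)
            esu = me.enumerate_connected_subgraphs(g, k)
            oracle = me.brute_force_census(g, k)
            assert esu.counts == oracle.counts

    def test_colored_and_uncolored_totals_agree(self):
        rng = np.random.default_rng(7)
        g = random_digraph(9, 0.35, rng)
        cats = ["mild", "strong_positive", "strong_negative"]
        for u, v in g.edges:
            g.edges[u, v]["category"] = cats[int(rng.integers(0, 3))]
        plain = me.enumerate_connected_subgraphs(g, 4, colored=False)
        colored = me.enumerate_connected_subgraphs(g, 4, colored=True)
        assert plain.total == colored.total
        assert len(colored.counts) >= len(plain.counts)

    def test_k_larger_than_graph_gives_empty_census(self):
        g = nx.DiGraph([(0, 1)])
        assert me.enumerate_connected_subgraphs(g, 4).total == 0

    def test_layered_graph_subgraphs_span_consecutive_layers(self):
        params = me.initialize(me.MLPArchitecture.from_preset("240120"),
                               "glorot", np.random.default_rng(1))
        g = me.model_to_graph(params, me.PruneConfig())
        layers = nx.get_node_attributes(g, "layer")
        census = me.enumerate_connected_subgraphs(g, 4)
        assert census.total > 0
        # layeredness of the host graph forces it on every induced subgraph
        assert all(layers[v] == layers[u] + 1 for u, v in g.edges)


def _layered_test_graph(seed=11):
    params = me.initialize(me.MLPArchitecture.from_preset("240120"),
                           "glorot", np.random.default_rng(seed))
    return me.model_to_graph(params, me.PruneConfig())


class TestSwitchRandomize:
    def test_degree_sequences_preserved(self):
        g = _layered_test_graph()
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=5, seed=3)
        replica = me.switch_randomize(g, cfg, np.random.default_rng(3))
        assert dict(replica.in_degree()) == dict(g.in_degree())
        assert dict(replica.out_degree()) == dict(g.out_degree())
        assert replica.number_of_edges() == g.number_of_edges()
        # the shuffle actually moved something
        assert set(replica.edges) != set(g.edges)

    def test_single_edge_graph_unchanged(self):
        g = nx.DiGraph()
        g.add_node(0, layer=0)
        g.add_node(1, layer=1)
        g.add_edge(0, 1)
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=10, seed=0)
        replica = me.switch_randomize(g, cfg, np.random.default_rng(0))
        assert set(replica.edges) == {(0, 1)}

    def test_layer_preserving_replicas_stay_layered(self):
        g = _layered_test_graph()
        layers = nx.get_node_attributes(g, "layer")
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=3,
                              mode="layer_preserving", seed=5)
        rng = np.random.default_rng(5)
        for _ in range(5):
            replica = me.switch_randomize(g, cfg, rng)
            assert all(layers[v] == layers[u] + 1 for u, v in replica.edges)

    def test_global_mode_may_break_layers_but_not_degrees(self):
        g = _layered_test_graph()
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=3, mode="global",
                              seed=6)
        replica = me.switch_randomize(g, cfg, np.random.default_rng(6))
        assert dict(replica.in_degree()) == dict(g.in_degree())
        assert dict(replica.out_degree()) == dict(g.out_degree())

    def test_no_self_loops_or_duplicates(self):
        g = _layered_test_graph()
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=10, seed=7)
        replica = me.switch_randomize(g, cfg, np.random.default_rng(7))
        assert nx.number_of_selfloops(replica) == 0

    def test_categories_travel_with_source_half(self):
        g = _layered_test_graph()
        out_cats = {}
        for u, v, d in g.edges(data=True):
            out_cats.setdefault(u, []).append(d["category"])
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=3, seed=8)
        replica = me.switch_randomize(g, cfg, np.random.default_rng(8))
        for u in out_cats:
            rep = [d["category"] for _, _, d in replica.out_edges(u, data=True)]
            assert sorted(rep) == sorted(out_cats[u])


class TestNullEnsemble:
    def test_zero_swaps_give_degenerate_ensemble(self):
        g = _layered_test_graph()
        cfg = NullModelConfig(n_replicas=5, swaps_per_edge=0, seed=1)
        ensemble = me.null_census_ensemble(g, 4, cfg)
        census = me.enumerate_connected_subgraphs(g, 4)
        for code, (mean, sd) in ensemble.items():
            assert sd == 0.0
            assert mean == census.counts[code]
        profile = me.z_scores(census, ensemble)
        assert profile.defined() == {}

    def test_two_replica_sd_is_two_point_sample_sd(self):
        g = _layered_test_graph()
        cfg = NullModelConfig(n_replicas=2, swaps_per_edge=3, seed=2)
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(2):
            rep = me.switch_randomize(g, cfg, rng)
            counts.append(me.enumerate_connected_subgraphs(rep, 4).counts)
        ensemble = me.null_census_ensemble(g, 4, cfg)
        for code, (mean, sd) in ensemble.items():
            a, b = counts[0].get(code, 0), counts[1].get(code, 0)
            assert mean == pytest.approx((a + b) / 2)
            assert sd == pytest.approx(abs(a - b) / np.sqrt(2))

    def test_total_count_stable_across_seeds(self):
        """Monte-Carlo stability: ensemble-mean total subgraph count from two
        independent seeds agree within 5 joint standard errors."""
        g = _layered_test_graph()
        totals = {}
        for seed in (10, 20):
            cfg = NullModelConfig(n_replicas=40, swaps_per_edge=3, seed=seed)
            rng = np.random.default_rng(seed)
            t = [me.enumerate_connected_subgraphs(
                me.switch_randomize(g, cfg, rng), 4).total
                for _ in range(cfg.n_replicas)]
            totals[seed] = (np.mean(t), np.std(t, ddof=1) / np.sqrt(len(t)))
        (m1, s1), (m2, s2) = totals.values()
        assert abs(m1 - m2) < 5 * np.hypot(s1, s2)


class TestZScores:
    def test_direct_substitution(self):
        census = MotifCensus(k=4, colored=False, counts={42: 5})
        profile = me.z_scores(census, {42: (3.0, 1.0)})
        assert profile.entries[42].z == 2.0

    def test_real_equals_mean_gives_zero(self):
        census = MotifCensus(k=4, colored=False, counts={1: 7})
        assert me.z_scores(census, {1: (7.0, 2.0)}).entries[1].z == 0.0

    def test_zero_sd_marked_undefined(self):
        census = MotifCensus(k=4, colored=False, counts={1: 7})
        profile = me.z_scores(census, {1: (7.0, 0.0)})
        assert profile.entries[1].z is None
        assert profile.defined() == {}

    def test_replica_only_classes_score_with_nreal_zero(self):
        census = MotifCensus(k=4, colored=False, counts={})
        profile = me.z_scores(census, {9: (2.0, 0.5)})
        assert profile.entries[9].n_real == 0
        assert profile.entries[9].z == -4.0


def _profile(k, entries):
    p = SignificanceProfile(k=k, colored=False)
    for code, (n, mean, sd, z) in entries.items():
        p.entries[code] = ProfileEntry(n, mean, sd, z)
    return p


class TestProfileDelta:
    def test_identical_profiles_all_zero(self):
        p = _profile(4, {1: (5, 3.0, 1.0, 2.0), 2: (1, 1.0, 0.5, 0.0)})
        assert me.profile_delta(p, p) == {1: 0.0, 2: 0.0}

    def test_class_absent_before_counts_as_zero(self):
        before = _profile(4, {})
        after = _profile(4, {1: (8, 4.0, 1.0, 4.0)})
        assert me.profile_delta(before, after) == {1: 4.0}

    def test_antisymmetry(self):
        a = _profile(4, {1: (5, 3.0, 1.0, 2.0)})
        b = _profile(4, {1: (9, 3.0, 1.0, 6.0)})
        forward = me.profile_delta(a, b)
        backward = me.profile_delta(b, a)
        assert forward == {1: 4.0}
        assert backward == {1: -4.0}

    def test_undefined_side_propagates(self):
        a = _profile(4, {1: (5, 5.0, 0.0, None)})
        b = _profile(4, {1: (9, 3.0, 1.0, 6.0)})
        assert me.profile_delta(a, b) == {1: None}


class TestTopMotifs:
    def test_single_class_under_both_modes(self):
        p = _profile(4, {5: (3, 1.0, 0.5, 4.0)})
        for mode in ("most_significant", "most_typical"):
            assert me.top_motifs(p, 3, mode) == [(5, 4.0)]

    def test_group_selection_rules(self):
        # two colored classes sharing one skeleton, Z = 1 and 5
        chain = _adj([(0, 1), (1, 2)], 3)
        strong = chain.copy()
        strong[0, 1] = 2
        c_mild = me.canonical_code(chain, colored=True)
        c_strong = me.canonical_code(strong, colored=True)
        p = SignificanceProfile(k=3, colored=True)
        p.entries[c_mild] = ProfileEntry(2, 1.0, 1.0, 1.0)
        p.entries[c_strong] = ProfileEntry(6, 1.0, 1.0, 5.0)
        sig = me.top_motifs(p, 5, "most_significant")
        assert sig == [(c_strong, 5.0)]
        typ = me.top_motifs(p, 5, "most_typical")
        # group mean Z = 3; the Z=5 member sits 2 away, as does Z=1: tie
        # resolves to the lower canonical code
        assert typ == [(min(c_mild, c_strong),
                        p.entries[min(c_mild, c_strong)].z)]

    def test_n_larger_than_class_count_returns_all(self):
        p = _profile(4, {1: (1, 0.5, 0.5, 1.0), 2: (2, 0.5, 0.5, 3.0)})
        assert me.top_motifs(p, 10) == [(2, 3.0), (1, 1.0)]


class TestProfileCSV:
    def test_csv_columns_and_undefined_rows(self, tmp_path):
        p = _profile(4, {1: (5, 3.0, 1.0, 2.0), 2: (4, 4.0, 0.0, None)})
        path = tmp_path / "profile.csv"
        from motifemerge.motifs import profile_to_csv
        profile_to_csv(p, path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["k", "canonical_code",
                                       "adjacency_string", "Nreal",
                                       "mean_random", "sd_random", "Z"]
        assert frame.loc[frame.canonical_code == 1, "Z"].iloc[0] == 2.0
        assert np.isnan(frame.loc[frame.canonical_code == 2, "Z"].iloc[0])
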