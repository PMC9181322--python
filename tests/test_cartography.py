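import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netswitch.cartography import (CartographyThresholds, apcc,
                                   average_shortest_path,
                                   build_correlation_network, classify_nodes,
                                   clusterphobic, kmeans_communities,
                                   node_cartography, robustness_curve,
                                   run_swim, select_k_scree, SwimParams,
                                   within_module_degree_z)
from netswitch.io_formats import ExpressionMatrix
from netswitch.synthetic import (SynthConfig, generate_modular_expression,
                                 switch_recovery_config)

from oracles import floyd_warshall_apl


def _matrix(values, is_log2=True):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df, pd.Series("grp", index=df.columns),
                            is_log2=is_log2)


class TestBuildNetwork:
    def test_duplicate_profile_gives_r_one(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=10)
        m = _matrix([row, row, rng.normal(size=10)])
        g = build_correlation_network(m, m.genes, r_threshold=0.7)
        assert g.has_edge("g0", "g1")
        assert g["g0"]["g1"]["weight"] == pytest.approx(1.0)

    def test_negated_profile_gives_r_minus_one(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=10)
        m = _matrix([row, -row])
        g = build_correlation_network(m, m.genes)
        assert g["g0"]["g1"]["weight"] == pytest.approx(-1.0)

    def test_edge_set_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(6, 12)))
        g = build_correlation_network(m, m.genes, r_threshold=0.7)
        vals = m.values.to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.corrcoef(vals[i], vals[j])[0, 1]
                assert g.has_edge(f"g{i}", f"g{j}") == (abs(r) >= 0.7)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(3)
        m = _matrix([np.full(8, 5.0), rng.normal(size=8)])
        g = build_correlation_network(m, m.genes)
        assert "g0" not in g.nodes

    def test_isolated_node_retained_and_flagged(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=(3, 50)))  # independent -> no edges
        g = build_correlation_network(m, m.genes, r_threshold=0.99)
        assert set(g.nodes) == {"g0", "g1", "g2"}
        assert all(g.nodes[n]["isolated"] for n in g.nodes)


class TestCommunities:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=30), rng.normal(size=30)
        rows = [2 * f1 + 0.2 * rng.normal(size=30) for _ in range(10)]
        rows += [2 * f2 + 0.2 * rng.normal(size=30) for _ in range(10)]
        m = _matrix(rows)
        res = kmeans_communities(m, m.genes, k_min=2, k_max=2, seed=0)
        labels = res.assignment
        block1 = set(labels.iloc[:10])
        block2 = set(labels.iloc[10:])
        assert len(block1) == 1 and len(block2) == 1 and block1 != block2
        # with k free, clusters may refine the blocks but never mix them
        free = kmeans_communities(m, m.genes, k_min=2, k_max=5, seed=0)
        assert not (set(free.assignment.iloc[:10]) &
                    set(free.assignment.iloc[10:]))

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(20, 15)))
        r1 = kmeans_communities(m, m.genes, k_max=6, seed=3)
        r2 = kmeans_communities(m, m.genes, k_max=6, seed=3)
        pd.testing.assert_series_equal(r1.assignment, r2.assignment)
        assert r1.sse_curve == r2.sse_curve

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(size=(40, 12)))
        res = kmeans_communities(m, m.genes, k_min=2, k_max=10, seed=1)
        sse = [res.sse_curve[k] for k in sorted(res.sse_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(sse, sse[1:]))


class TestScree:
    def test_direct_rule_application(self):
        sse = {1: 100.0, 2: 40.0, 3: 10.0, 4: 9.5, 5: 9.3}
        assert select_k_scree(sse, tau=0.1) == 3

    def test_flat_curve_returns_k_min(self):
        assert select_k_scree({2: 5.0, 3: 5.0, 4: 5.0}) == 2

    def test_geometric_decay_falls_back_to_k_max(self):
        sse = {k: 100.0 * 0.5 ** k for k in range(1, 6)}
        assert select_k_scree(sse) == 5

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            select_k_scree({2: 1.0})


class TestCoordinates:
    def test_apcc_single_neighbor(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-0.4)
        assert apcc(g)["a"] == pytest.approx(-0.4)

    def test_apcc_mean_of_weights(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("a", "c", weight=-0.3)
        assert apcc(g)["a"] == pytest.approx(0.3)

    def test_apcc_isolated_excluded(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b", weight=0.8)
        assert "lonely" not in apcc(g)

    def test_zg_zero_for_equal_degrees(self):
        g = nx.cycle_graph(4)
        zg = within_module_degree_z(g, {n: 0 for n in g.nodes})
        np.testing.assert_allclose(zg, 0.0)

    def test_zg_hand_calculation(self):
        # module degrees {1, 1, 4}: mean 2, population sd sqrt(2)
        g = nx.Graph()
        g.add_edges_from([("a", "c"), ("b", "c")])
        g.add_edges_from([("c", f"x{i}") for i in range(2)])
        modules = {"a": 0, "b": 0, "c": 0, "x0": 0, "x1": 0}
        # within-degrees: a=1, b=1, c=4, x0=1, x1=1 -> use a 3-node module
        g2 = nx.Graph()
        g2.add_edges_from([("a", "c"), ("b", "c"),
                           ("c", "d"), ("c", "e")])
        modules = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        zg = within_module_degree_z(g2, modules)
        # module 0 within-degrees: a=1, b=1, c=2 -> hand: (2-4/3)/sd
        vals = np.array([1, 1, 2])
        expect = (2 - vals.mean()) / vals.std()
        assert zg["c"] == pytest.approx(expect)

    def test_zg_mean_zero_within_modules(self):
        rng = np.random.default_rng(8)
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        modules = {n: n % 3 for n in g.nodes}
        zg = within_module_degree_z(g, modules)
        for m in range(3):
            members = [n for n in g.nodes if modules[n] == m]
            assert abs(zg[members].mean()) < 1e-9

    def test_kpi_limits_and_formula(self):
        g = nx.Graph()
        # "core": all edges internal
        g.add_edges_from([("a", "b"), ("a", "c")])
        # "out": all edges external
        g.add_edge("out", "a")
        # "mixed": 1 internal, 2 external
        g.add_edges_from([("m", "b"), ("m", "ext1"), ("m", "ext2")])
        modules = {"a": 0, "b": 0, "c": 0, "out": 1,
                   "m": 0, "ext1": 1, "ext2": 1}
        kpi = clusterphobic(g, modules)
        assert kpi["b"] == pytest.approx(0.0)  # both edges internal
        assert kpi["out"] == pytest.approx(1.0)
        assert kpi["m"] == pytest.approx(1 - (1 / 3) ** 2)
        assert ((kpi >= 0) & (kpi <= 1)).all()


class TestClassification:
    @pytest.mark.parametrize("zg,kpi,ap,expect_switch,expect_role,expect_region", [
        (1.0, 0.9, -0.2, True, "fight-club", "R4"),
        (1.0, 0.9, +0.2, False, "date", "R4"),
        (2.5, 0.9, -0.2, False, "fight-club", "R7"),  # boundary: not < 2.5
        (1.0, 0.8, -0.2, False, "fight-club", "R3"),  # boundary: not > 0.8
        (6.0, 0.1, 0.7, False, "party", "R5"),
    ])
    def test_rule_grid(self, zg, kpi, ap, expect_switch, expect_role,
                       expect_region):
        out = classify_nodes(pd.Series({"n": zg}), pd.Series({"n": kpi}),
                             pd.Series({"n": ap}))
        row = out.loc["n"]
        assert bool(row["is_switch"]) is expect_switch
        assert row["role"] == expect_role
        assert row["region"] == expect_region

    def test_hub_threshold_is_five(self):
        out = classify_nodes(pd.Series({"a": 5.1, "b": 5.0}),
                             pd.Series({"a": 0.5, "b": 0.5}),
                             pd.Series({"a": 0.1, "b": 0.1}))
        assert bool(out.loc["a", "is_hub"]) and not bool(out.loc["b", "is_hub"])

    def test_switch_subset_of_fight_club(self):
        rng = np.random.default_rng(9)
        n = 200
        out = classify_nodes(
            pd.Series(rng.normal(2, 2, n)),
            pd.Series(rng.uniform(0, 1, n)),
            pd.Series(rng.uniform(-1, 1, n)))
        switches = out[out["is_switch"]]
        assert (switches["role"] == "fight-club").all()
        assert (switches["APCC"] < 0).all()

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(10)
        g = nx.gnp_random_graph(25, 0.25, seed=2)
        nx.set_edge_attributes(
            g, {e: rng.uniform(-1, 1) for e in g.edges}, "weight")
        modules = {n: n % 3 for n in g.nodes}
        permuted = {n: (m + 1) % 3 for n, m in modules.items()}
        c1 = node_cartography(g, modules)
        c2 = node_cartography(g, permuted)
        for col in ("Zg", "Kpi", "APCC"):
            pd.testing.assert_series_equal(c1[col], c2[col])
        assert (c1["is_switch"] == c2["is_switch"]).all()
        assert (c1["role"] == c2["role"]).all()


class TestAveragePath:
    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(["A", "B", "C"])
        assert average_shortest_path(g) == pytest.approx(4 / 3)
        g.remove_node("C")
        assert average_shortest_path(g) == pytest.approx(1.0)

    def test_matches_floyd_warshall_oracle(self):
        for seed in range(10):
            g = nx.gnp_random_graph(np.random.default_rng(seed).integers(5, 30),
                                    0.2, seed=seed)
            adj = nx.to_numpy_array(g)
            assert average_shortest_path(g) == pytest.approx(
                floyd_warshall_apl(adj), abs=1e-12)


class TestRobustness:
    def test_fraction_zero_is_baseline(self):
        cfg = switch_recovery_config(seed=0)
        m, _ = generate_modular_expression(cfg)
        res = run_swim(m, ("low", "high"),
                       SwimParams(seed=0, class_replicates=3,
                                  random_replicates=10))
        base = average_shortest_path(res.network)
        for curve in res.robustness.values():
            row0 = curve[curve["fraction"] == 0.0].iloc[0]
            assert row0["apl_mean"] == pytest.approx(base)

    def test_switch_removal_leaves_random_band(self):
        cfg = switch_recovery_config(seed=2)
        m, _ = generate_modular_expression(cfg)
        res = run_swim(m, ("low", "high"), SwimParams(seed=2))
        sw = res.robustness["switch"]
        outside = (sw["apl_mean"] - sw["rand_mean"]).abs() \
            > 1.96 * sw["rand_sd"]
        assert int(outside.sum()) >= 1


class TestRunSwim:
    def test_recovers_planted_switches(self):
        cfg = switch_recovery_config(seed=0)
        m, truth = generate_modular_expression(cfg)
        res = run_swim(m, ("low", "high"),
                       SwimParams(seed=0, compute_robustness=False))
        assert set(res.switch_genes) == truth.planted_switch_genes
        assert res.heatmap.shape[0] == len(res.switch_genes)

    def test_empty_filter_clean_exit(self):
        cfg = SynthConfig(seed=1)  # no planted DE -> nothing significant
        m, _ = generate_modular_expression(cfg)
        res = run_swim(m, ("low", "high"), SwimParams(seed=1))
        assert res.empty
        assert res.switch_genes == []

    def test_same_seed_identical_switch_list(self):
        cfg = switch_recovery_config(seed=5)
        m, _ = generate_modular_expression(cfg)
        p = SwimParams(seed=5, compute_robustness=False)
        r1 = run_swim(m, ("low", "high"), p)
        r2 = run_swim(m, ("low", "high"), p)
        assert r1.switch_genes == r2.switch_genes
        pd.testing.assert_frame_equal(r1.cartography, r2.cartography)

    def test_switch_subset_chain_on_real_run(self):
        cfg = switch_recovery_config(seed=3)
        m, _ = generate_modular_expression(cfg)
        res = run_swim(m, ("low", "high"),
                       SwimParams(seed=3, compute_robustness=False))
        carto = res.cartography
        switch_set = set(carto.index[carto["is_switch"]])
        fight_club = set(carto.index[carto["role"] == "fight-club"])
        negative = set(carto.index[carto["APCC"] < 0])
        assert switch_set <= fight_club <= negative
        assert ((carto["Kpi"] >= 0) & (carto["Kpi"] <= 1)).all()
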