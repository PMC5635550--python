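from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtpaths.network import (
    InteractionNetwork,
    NetworkValidationError,
    Path,
    PathEnumerationConfig,
    enumerate_candidate_paths,
    load_network,
    path_weight,
    write_network,
)
from mtpaths.synth import SynthConfig, generate_instance

from _oracles import nx_bounded_paths


class TestLoadNetwork:
    def test_self_loop_dropped_with_warning(self):
        df = pd.DataFrame(
            [
                ("A", "B", 0.5, "ppi"),
                ("B", "T", 0.9, "regulatory"),
                ("A", "A", 0.3, "ppi"),
            ],
            columns=["node_a", "node_b", "probability", "edge_type"],
        )
        with pytest.warns(UserWarning, match="self-loop"):
            net = load_network(df)
        assert len(net.ppi_edges) == 1
        assert len(net.regulatory_edges) == 1

    def test_duplicate_edges_keep_max_probability(self):
        df = pd.DataFrame(
            [
                ("A", "B", 0.4, "ppi"),
                ("B", "A", 0.7, "ppi"),
            ],
            columns=["node_a", "node_b", "probability", "edge_type"],
        )
        net = load_network(df)
        assert net.ppi_edges == {("A", "B"): 0.7}

    @pytest.mark.parametrize(
        "bad_row, match",
        [
            (("A", "B", 1.5, "ppi"), "probability"),
            (("A", "B", 0.0, "ppi"), "probability"),
            (("A", "B", 0.5, "banana"), "edge_type"),
        ],
    )
    def test_invalid_rows_rejected(self, bad_row, match):
        df = pd.DataFrame(
            [bad_row], columns=["node_a", "node_b", "probability", "edge_type"]
        )
        with pytest.raises(NetworkValidationError, match=match):
            load_network(df)

    def test_round_trip_preserves_network(self, tmp_path):
        rng = np.random.default_rng(5)
        net = InteractionNetwork()
        nodes = [f"n{i}" for i in range(50)]
        n_edges = 0
        while n_edges < 100:
            a, b = rng.choice(nodes, size=2, replace=False)
            net.add_ppi_edge(str(a), str(b), float(rng.uniform(0.1, 1.0)))
            n_edges += 1
        for i in range(20):
            net.add_regulatory_edge(
                f"n{i}", f"n{49 - i}", float(rng.uniform(0.1, 1.0))
            )
        out = tmp_path / "net.tsv"
        write_network(net, out)
        again = load_network(out)
        assert again == net


class TestPathWeight:
    def test_product_of_edge_probabilities(self, chain_network):
        assert path_weight(["S", "A", "B", "T"], chain_network) == pytest.approx(
            0.9 * 0.8 * 0.9
        )

    def test_single_certain_edge_is_identity(self):
        net = InteractionNetwork()
        net.add_regulatory_edge("F", "T", 1.0)
        assert path_weight(["F", "T"], net) == 1.0

    def test_missing_edge_is_an_error(self, chain_network):
        with pytest.raises(NetworkValidationError, match="no edge"):
            path_weight(["S", "T"], chain_network)

    def test_extension_never_increases_weight(self, small_instance):
        net = small_instance.network
        for cond in small_instance.conditions[:1]:
            for paths in cond.candidate_paths.values():
                for p in paths:
                    for cut in range(2, len(p.nodes)):
                        prefix_w = path_weight(p.nodes[:cut] , net) if cut >= 2 else 1.0
                        assert p.weight <= prefix_w + 1e-12


class TestEnumerateCandidatePaths:
    def test_unique_chain_path(self):
        df = pd.DataFrame(
            [("S", "A", 0.9, "ppi"), ("A", "T", 0.9, "regulatory")],
            columns=["node_a", "node_b", "probability", "edge_type"],
        )
        net = load_network(df)
        out = enumerate_candidate_paths(net, {"S"}, {"T"})
        assert [p.nodes for p in out["T"]] == [("S", "A", "T")]
        assert out["T"][0].weight == pytest.approx(0.81)

    def test_length_bound_excludes_long_paths(self):
        df = pd.DataFrame(
            [("S", "A", 0.9, "ppi"), ("A", "T", 0.9, "regulatory")],
            columns=["node_a", "node_b", "probability", "edge_type"],
        )
        net = load_network(df)
        out = enumerate_candidate_paths(
            net, {"S"}, {"T"}, PathEnumerationConfig(max_path_edges=1)
        )
        assert out["T"] == ()

    def test_unreachable_target_yields_empty_set(self, chain_network):
        out = enumerate_candidate_paths(chain_network, {"T"}, {"S"})
        assert out["S"] == ()

    def test_matches_networkx_bounded_enumeration(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i:02d}" for i in range(40)]
        rows = []
        for _ in range(70):
            a, b = rng.choice(nodes, size=2, replace=False)
            rows.append((str(a), str(b), float(rng.uniform(0.2, 1.0)), "ppi"))
        for i in range(12):
            rows.append(
                (f"n{i:02d}", f"n{39 - i:02d}", float(rng.uniform(0.2, 1.0)), "regulatory")
            )
        df = pd.DataFrame(
            rows, columns=["node_a", "node_b", "probability", "edge_type"]
        )
        net = load_network(df)
        sources = {"n00", "n01"}
        targets = {"n40", "n39", "n38", "n30"} & net.nodes
        cfg = PathEnumerationConfig(max_path_edges=4, paths_per_pair=100)
        mine = enumerate_candidate_paths(net, sources, targets, cfg)
        oracle = nx_bounded_paths(df, sources, targets, 4)
        for t in targets:
            got = {p.nodes: p.weight for p in mine[t]}
            want = oracle[t]
            assert set(got) == set(want)
            for nodes_seq, w in want.items():
                assert got[nodes_seq] == pytest.approx(w, abs=1e-12)

    def test_top_m_truncation_matches_oracle_ranking(self):
        rng = np.random.default_rng(13)
        nodes = [f"n{i:02d}" for i in range(25)]
        rows = []
        for _ in range(60):
            a, b = rng.choice(nodes, size=2, replace=False)
            rows.append((str(a), str(b), float(rng.uniform(0.2, 1.0)), "ppi"))
        for i in range(8):
            rows.append((f"n{i:02d}", "n24", float(rng.uniform(0.2, 1.0)), "regulatory"))
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "probability", "edge_type"])
        net = load_network(df)
        cfg = PathEnumerationConfig(max_path_edges=4, paths_per_pair=5)
        mine = enumerate_candidate_paths(net, {"n10"}, {"n24"}, cfg)
        oracle = nx_bounded_paths(df, {"n10"}, {"n24"}, 4)["n24"]
        want_top = sorted(oracle.values(), reverse=True)[:5]
        got = sorted((p.weight for p in mine["n24"]), reverse=True)
        assert got == pytest.approx(want_top, abs=1e-12)

    def test_invariant_to_edge_row_permutation(self, rng):
        inst = generate_instance(SynthConfig(seed=3))
        import mtpaths.network as mn

        df_rows = []
        for (a, b), p in inst.network.ppi_edges.items():
            df_rows.append((a, b, p, "ppi"))
        for (a, b), p in inst.network.regulatory_edges.items():
            df_rows.append((a, b, p, "regulatory"))
        df = pd.DataFrame(df_rows, columns=["node_a", "node_b", "probability", "edge_type"])
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        cond = inst.conditions[0]
        a = mn.enumerate_candidate_paths(load_network(df), cond.sources, cond.targets)
        b = mn.enumerate_candidate_paths(load_network(shuffled), cond.sources, cond.targets)
        assert a == b

    def test_every_path_satisfies_structural_invariants(self, small_instance):
        net = small_instance.network
        for cond in small_instance.conditions:
            for t, paths in cond.candidate_paths.items():
                for p in paths:
                    assert p.nodes[0] in cond.sources
                    assert p.nodes[-1] == t
                    assert len(set(p.nodes)) == len(p.nodes)
                    assert net.is_regulatory(p.nodes[-2], p.nodes[-1])
                    assert p.weight == pytest.approx(
                        path_weight(p.nodes[:-1], net)
                        * net.regulatory_edges[(p.nodes[-2], p.nodes[-1])],
                        abs=1e-12,
                    )


class TestPathType:
    @pytest.mark.parametrize(
        "nodes, weight",
        [(("A",), 0.5), (("A", "B", "A"), 0.5), (("A", "B"), 0.0), (("A", "B"), 1.5)],
    )
    def test_invalid_paths_rejected(self, nodes, weight):
        with pytest.raises(NetworkValidationError):
            Path(nodes, weight)
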