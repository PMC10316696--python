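"""Edge merging, normalization, cycle repair, and the end-to-end pipeline."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from knockdag.edges import new_edge_list, normalize_effects
from knockdag.graph import (
    CausalDagModel,
    CausalGraph,
    PipelineConfig,
    break_cycles,
    merge_edges,
    run_pipeline,
)
from knockdag.knocknet import NetConfig
from knockdag.simulate import SimConfig, simulate_dataset

FAST_NET = NetConfig(step_budget=4000, ensemble=1)


def _edges(records):
    return new_edge_list(records)


class TestMerge:
    def test_disjoint_lists_concatenate(self):
        lin = _edges([{"var_a": "a", "var_b": "b", "kind": "linear", "effect_size": 0.5}])
        non = _edges([{"var_a": "c", "var_b": "d", "kind": "nonlinear", "effect_size": 2.0}])
        merged = merge_edges(lin, non)
        assert len(merged) == 2
        assert set(merged["kind"]) == {"linear", "nonlinear"}

    def test_pair_in_both_stages_labeled_linear_with_audit(self):
        lin = _edges([{"var_a": "a", "var_b": "b", "kind": "linear", "effect_size": 0.5}])
        non = _edges([{"var_a": "b", "var_b": "a", "kind": "nonlinear", "effect_size": 2.0}])
        merged = merge_edges(lin, non)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert row.kind == "linear"
        assert row.effect_linear == 0.5 and row.effect_nonlinear == 2.0

    def test_min_max_normalization_within_kind(self):
        lin = _edges([
            {"var_a": "a", "var_b": "b", "kind": "linear", "effect_size": 0.1},
            {"var_a": "a", "var_b": "c", "kind": "linear", "effect_size": 0.9},
            {"var_a": "b", "var_b": "c", "kind": "linear", "effect_size": 0.5},
        ])
        non = _edges([{"var_a": "c", "var_b": "d", "kind": "nonlinear", "effect_size": 7.0}])
        merged = merge_edges(lin, non).set_index(["var_a", "var_b"])
        assert merged.loc[("a", "c"), "normalized_effect"] == 1.0
        assert merged.loc[("a", "b"), "normalized_effect"] == 0.0
        assert merged.loc[("a", "c"), "normalized_effect"] > merged.loc[("b", "c"), "normalized_effect"]
        # a single-edge kind normalizes to 1
        assert merged.loc[("c", "d"), "normalized_effect"] == 1.0

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _edges([
                {"var_a": "a", "var_b": "b", "effect_size": 1.0},
                {"var_a": "b", "var_b": "a", "effect_size": 2.0},
            ])

    def test_normalize_all_equal_effects_map_to_one(self):
        e = _edges([
            {"var_a": "a", "var_b": "b", "effect_size": 0.4},
            {"var_a": "a", "var_b": "c", "effect_size": 0.4},
        ])
        out = normalize_effects(e)
        assert (out["normalized_effect"] == 1.0).all()


def _graph(records, nodes=None):
    df = new_edge_list(records)
    nodes = nodes or sorted(set(df["var_a"]) | set(df["var_b"]))
    return CausalGraph(nodes, df)


class TestBreakCycles:
    def test_acyclic_graph_is_fixed_point(self):
        g = _graph([
            {"var_a": "a", "var_b": "b", "direction": "a_to_b", "normalized_effect": 0.5, "effect_size": 1},
            {"var_a": "b", "var_b": "c", "direction": "a_to_b", "normalized_effect": 0.5, "effect_size": 1},
        ])
        out = break_cycles(g)
        assert len(out.edges) == 2 and out.removed_edges == []

    def test_three_cycle_drops_weakest_edge(self):
        g = _graph([
            {"var_a": "a", "var_b": "b", "direction": "a_to_b", "normalized_effect": 0.9, "effect_size": 1},
            {"var_a": "b", "var_b": "c", "direction": "a_to_b", "normalized_effect": 0.5, "effect_size": 1},
            {"var_a": "a", "var_b": "c", "direction": "b_to_a", "normalized_effect": 0.2, "effect_size": 1},
        ])
        out = break_cycles(g)
        assert out.is_acyclic()
        assert len(out.removed_edges) == 1
        gone = out.removed_edges[0]
        assert (gone["var_a"], gone["var_b"]) == ("a", "c")
        assert gone["reason"] == "cycle_repair"

    def test_undirected_edges_never_participate(self):
        g = _graph([
            {"var_a": "a", "var_b": "b", "direction": "a_to_b", "normalized_effect": 0.9, "effect_size": 1},
            {"var_a": "b", "var_b": "c", "direction": "undirected", "normalized_effect": 0.1, "effect_size": 1},
        ])
        out = break_cycles(g)
        assert len(out.edges) == 2

    def test_random_tournament_becomes_acyclic(self, rng):
        nodes = [f"n{k}" for k in range(6)]
        records = []
        for i in range(6):
            for j in range(i + 1, 6):
                records.append({
                    "var_a": nodes[i], "var_b": nodes[j],
                    "direction": "a_to_b" if rng.random() < 0.5 else "b_to_a",
                    "normalized_effect": float(rng.random()), "effect_size": 1.0,
                })
        out = break_cycles(_graph(records, nodes))
        # independent oracle: rebuild the digraph and re-check with networkx
        dig = nx.DiGraph()
        for _, r in out.directed_edges().iterrows():
            u, v = (r.var_a, r.var_b) if r.direction == "a_to_b" else (r.var_b, r.var_a)
            dig.add_edge(u, v)
        assert nx.is_directed_acyclic_graph(dig)
        assert len(out.edges) + len(out.removed_edges) == 15
        # every removal must have been justified: restoring any removed edge
        # alone to the final graph creates a cycle or it was part of one earlier
        for gone in out.removed_edges:
            assert gone["reason"] == "cycle_repair"


class TestPipeline:
    def test_pipeline_deterministic_and_acyclic(self):
        sim = simulate_dataset(SimConfig(3, 2, 300, seed=6))
        cfg = PipelineConfig(net=FAST_NET)
        a = run_pipeline(sim.dataset, cfg, seed=2)
        b = run_pipeline(sim.dataset, cfg, seed=2)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        assert a.is_acyclic()

    def test_null_data_yields_near_empty_graph(self):
        # independent Gaussians: the linear stage should select ~nothing and
        # the knockoff+ filter nothing at all
        total = 0
        for seed in (0, 1, 2):
            g = np.random.default_rng(500 + seed)
            from knockdag.dataset import Dataset

            d = Dataset.from_dataframe(pd.DataFrame(g.standard_normal((1000, 3)), columns=list("abc")))
            out = run_pipeline(d, PipelineConfig(net=FAST_NET, plus=True), seed=seed)
            total += len(out.edges)
        assert total <= 1

    def test_removing_outcome_removes_its_edges(self):
        sim = simulate_dataset(SimConfig(3, 2, 300, seed=6))
        cfg = PipelineConfig(net=FAST_NET)
        full = run_pipeline(sim.dataset, cfg, seed=2)
        assert (full.edges[["var_a", "var_b"]] == "Y").any().any()
        reduced = run_pipeline(sim.dataset.drop("Y"), cfg, seed=2)
        assert not (reduced.edges[["var_a", "var_b"]] == "Y").any().any()

    def test_user_dropped_edge_is_audited(self):
        sim = simulate_dataset(SimConfig(3, 2, 300, seed=6))
        cfg = PipelineConfig(net=FAST_NET)
        full = run_pipeline(sim.dataset, cfg, seed=2)
        first = tuple(full.edges.iloc[0][["var_a", "var_b"]])
        dropped = run_pipeline(sim.dataset, PipelineConfig(net=FAST_NET, drop_edges=(first,)), seed=2)
        pairs = set(zip(dropped.edges["var_a"], dropped.edges["var_b"]))
        assert first not in pairs
        assert any(r["reason"] == "user_removed" for r in dropped.removed_edges)

    def test_model_results_surface(self):
        sim = simulate_dataset(SimConfig(2, 2, 250, seed=9))
        res = CausalDagModel(sim.dataset, PipelineConfig(net=FAST_NET)).fit(seed=1)
        text = res.summary()
        assert "acyclic: True" in text
        assert isinstance(res.edges, pd.DataFrame)
        dot = res.graph.to_dot()
        assert dot.startswith("digraph") and "Y" in dot

    def test_screen_restricts_edges_to_admissible_pairs(self):
        sim = simulate_dataset(SimConfig(3, 2, 400, seed=12))
        out = run_pipeline(sim.dataset, PipelineConfig(net=FAST_NET, screen=True, screen_tol=1e-4), seed=1)
        from knockdag.dataset import precision_screen

        admissible = precision_screen(sim.dataset, tol=1e-4)
        for _, r in out.edges.iterrows():
            assert tuple(sorted((r.var_a, r.var_b))) in {tuple(sorted(p)) for p in admissible}
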