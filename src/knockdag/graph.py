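"""Edge merging, orientation, cycle repair, and the end-to-end pipeline.

The final artifact is a causal graph whose directed subgraph is acyclic.
Linear (MGM) and nonlinear (knockoff-filter) edges are merged by unordered
pair - a pair found by both stages keeps the simpler linear label, with both
raw effects retained for audit - effect sizes are min-max normalized within
each kind, every edge is oriented by the degenerate-Gaussian likelihood
ratio, and any directed cycle is broken by repeatedly dropping the cycle
edge with the smallest normalized effect.  Ties stay undirected and are
excluded from cycle tests; every removal is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import Dataset, precision_screen, standardize
from .dg import DgConfig, orient_pair
from .edges import EDGE_COLUMNS, new_edge_list, normalize_effects, write_edges
from .knocknet import NetConfig, select_nonlinear
from .mgm import MgmPenalties, fit_mgm, extract_linear_edges


@dataclass
class CausalGraph:
    """Final graph plus its audit trail.

    ``edges`` follows the edge-list schema; ``removed_edges`` records every
    edge dropped after orientation together with the reason
    ("cycle_repair" or "user_removed").
    """

    nodes: list[str]
    edges: pd.DataFrame
    removed_edges: list[dict] = field(default_factory=list)

    def directed_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["direction"] != "undirected"]

    def undirected_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["direction"] == "undirected"]

    def to_networkx(self) -> nx.DiGraph:
        """Directed subgraph only (ties carried separately)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, r in self.directed_edges().iterrows():
            u, v = (r.var_a, r.var_b) if r.direction == "a_to_b" else (r.var_b, r.var_a)
            g.add_edge(u, v, kind=r.kind, effect=r.normalized_effect)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def to_dot(self) -> str:
        lines = ["digraph causal {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for _, r in self.edges.iterrows():
            style = "solid" if r.kind == "linear" else "dashed"
            if r.direction == "undirected":
                lines.append(f'  "{r.var_a}" -> "{r.var_b}" [dir=none, style={style}];')
            else:
                u, v = (r.var_a, r.var_b) if r.direction == "a_to_b" else (r.var_b, r.var_a)
                lines.append(f'  "{u}" -> "{v}" [style={style}, label="{r.normalized_effect:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


def merge_edges(linear: pd.DataFrame, nonlinear: pd.DataFrame) -> pd.DataFrame:
    """Union by unordered pair; both-stage pairs keep the linear label.

    Both raw effects are retained in audit columns (effect_linear /
    effect_nonlinear); normalized_effect is recomputed per kind.
    """
    records: dict[tuple[str, str], dict] = {}
    for _, r in linear.iterrows():
        key = (r.var_a, r.var_b)
        records[key] = {
            "var_a": r.var_a, "var_b": r.var_b, "kind": "linear",
            "effect_size": r.effect_size, "effect_linear": r.effect_size,
            "effect_nonlinear": np.nan,
        }
    for _, r in nonlinear.iterrows():
        key = (r.var_a, r.var_b)
        if key in records:
            records[key]["effect_nonlinear"] = r.effect_size
        else:
            records[key] = {
                "var_a": r.var_a, "var_b": r.var_b, "kind": "nonlinear",
                "effect_size": r.effect_size, "effect_linear": np.nan,
                "effect_nonlinear": r.effect_size,
            }
    merged = new_edge_list(list(records.values()))
    return normalize_effects(merged)


def orient_edges(edges: pd.DataFrame, d: Dataset, cfg: DgConfig | None = None) -> pd.DataFrame:
    """Fill direction/orientation_stat for every edge via the DG rule."""
    cfg = cfg or DgConfig()
    data = d
    if cfg.scale == "standardized":
        data, _ = standardize(d, which="all")
    out = edges.copy()
    for idx, r in out.iterrows():
        res = orient_pair(r.var_a, r.var_b, data, cfg)
        out.loc[idx, "orientation_stat"] = res.delta_ll
        out.loc[idx, "direction"] = {"i_to_j": "a_to_b", "j_to_i": "b_to_a", "undirected": "undirected"}[res.direction]
    return out


def break_cycles(g: CausalGraph) -> CausalGraph:
    """Remove directed cycles, dropping the weakest edge of each cycle.

    While a directed cycle exists, the cycle edge with the minimum
    normalized_effect is removed (ties broken lexicographically by endpoint
    names); removals are appended to the audit list.  Undirected edges never
    participate.
    """
    edges = g.edges.copy()
    removed = list(g.removed_edges)
    while True:
        digraph = CausalGraph(g.nodes, edges).to_networkx()
        try:
            cycle = nx.find_cycle(digraph)
        except nx.NetworkXNoCycle:
            break
        # locate edge rows of this cycle and drop the weakest
        candidates = []
        for u, v in cycle:
            a, b = sorted((u, v))
            mask = (edges["var_a"] == a) & (edges["var_b"] == b)
            row = edges[mask].iloc[0]
            candidates.append((float(row.normalized_effect), a, b, edges.index[mask][0]))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, a, b, drop_idx = candidates[0]
        removed.append({**edges.loc[drop_idx].to_dict(), "reason": "cycle_repair"})
        edges = edges.drop(index=drop_idx)
    out = CausalGraph(g.nodes, edges.reset_index(drop=True), removed)
    assert out.is_acyclic()
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; every stage default is overridable."""

    screen: bool = False
    screen_tol: float = 1e-4
    penalties: MgmPenalties = field(default_factory=MgmPenalties)
    mgm_max_iter: int = 500
    mgm_tol: float = 1e-7
    net: NetConfig = field(default_factory=NetConfig)
    q: float = 0.05
    plus: bool = False
    shrinkage: float | None = None
    targets: tuple[str, ...] | None = None
    dg: DgConfig = field(default_factory=DgConfig)
    drop_edges: tuple[tuple[str, str], ...] = ()
    run_linear: bool = True
    run_nonlinear: bool = True


def run_pipeline(d: Dataset, config: PipelineConfig | None = None, seed: int = 0) -> CausalGraph:
    """Full two-stage learner: associations -> orientation -> acyclic graph.

    Deterministic given (input, config, seed).  The optional inverse-
    covariance screen restricts both stages' output to admissible pairs.
    """
    config = config or PipelineConfig()
    admissible = precision_screen(d, tol=config.screen_tol) if config.screen else None

    linear = new_edge_list([])
    if config.run_linear:
        # continuous columns standardized; ordinal columns keep their codes so
        # the MGM fits multinomial conditionals for them
        std_cont, _ = standardize(d, which="continuous_only")
        fit = fit_mgm(std_cont, config.penalties, max_iter=config.mgm_max_iter, tol=config.mgm_tol)
        linear = extract_linear_edges(fit)

    nonlinear = new_edge_list([])
    if config.run_nonlinear:
        targets = list(config.targets) if config.targets is not None else None
        nonlinear = select_nonlinear(
            d, targets=targets, q=config.q, plus=config.plus,
            cfg=replace(config.net, seed=seed), shrinkage=config.shrinkage, seed=seed,
        )

    merged = merge_edges(linear, nonlinear)
    if admissible is not None and len(merged):
        keep = [tuple(sorted(p)) in {tuple(sorted(x)) for x in admissible} for p in zip(merged.var_a, merged.var_b)]
        merged = merged[keep].reset_index(drop=True)

    removed: list[dict] = []
    if config.drop_edges and len(merged):
        drop = {tuple(sorted(p)) for p in config.drop_edges}
        mask = [tuple(sorted(p)) in drop for p in zip(merged.var_a, merged.var_b)]
        for _, r in merged[mask].iterrows():
            removed.append({**r.to_dict(), "reason": "user_removed"})
        merged = merged[[not m for m in mask]].reset_index(drop=True)

    oriented = orient_edges(merged, d, config.dg)
    graph = CausalGraph(list(d.names), oriented, removed)
    return break_cycles(graph)


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class CausalDagModel:
    """Two-stage causal structure learner over a mixed-type dataset.

    Statsmodels-style entry point: build from a `Dataset` (or a numeric
    DataFrame) and call :meth:`fit` to obtain a results object carrying the
    oriented edge table, audit trail, and summary.
    """

    def __init__(self, dataset: Dataset, config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta=None, config: PipelineConfig | None = None) -> "CausalDagModel":
        return cls(Dataset.from_dataframe(df, meta), config)

    def fit(self, seed: int = 0) -> "CausalDagResults":
        graph = run_pipeline(self.dataset, self.config, seed=seed)
        return CausalDagResults(self, graph, seed)


class CausalDagResults:
    def __init__(self, model: CausalDagModel, graph: CausalGraph, seed: int):
        self.model = model
        self.graph = graph
        self.seed = seed

    @property
    def edges(self) -> pd.DataFrame:
        return self.graph.edges

    @property
    def removed_edges(self) -> list[dict]:
        return self.graph.removed_edges

    def to_tsv(self, path) -> None:
        write_edges(self.edges[EDGE_COLUMNS + [c for c in ("effect_linear", "effect_nonlinear") if c in self.edges]], path)

    def summary(self) -> str:
        e = self.edges
        n_lin = int((e["kind"] == "linear").sum())
        n_non = int((e["kind"] == "nonlinear").sum())
        n_undir = int((e["direction"] == "undirected").sum())
        lines = [
            "Causal DAG (two-stage: MGM linear + knockoff-filter nonlinear, DG-oriented)",
            f"  samples: {self.model.dataset.n_samples}, variables: {self.model.dataset.n_variables}, seed: {self.seed}",
            f"  edges: {len(e)} (linear {n_lin}, nonlinear {n_non}; undirected ties {n_undir})",
            f"  removed in cycle repair / by user: {len(self.removed_edges)}",
            f"  directed subgraph acyclic: {self.graph.is_acyclic()}",
        ]
        for _, r in e.iterrows():
            arrow = {"a_to_b": "->", "b_to_a": "<-", "undirected": "--"}[r.direction]
            lines.append(
                f"    {r.var_a} {arrow} {r.var_b}  [{r.kind}] effect {r.effect_size:.4f} "
                f"(norm {r.normalized_effect:.2f})"
            )
        return "\n".join(lines)
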