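"""Benchmark metrics on the single-index simulation.

Readouts mirror the simulation study the learner is designed around:

* ROC/AUC of the knockoff-statistic ranking of true vs null features
  (threshold-free: S_j is the method's native score, the FDR level q being
  its only selection dial);
* association power, the fraction of true features selected at level q;
* causal true/false positive counts after DG orientation;
* false discovery proportion among selected features.

All experiments are driven by explicit seed lists, one replicate dataset per
seed, and aggregate as mean +/- standard error across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dg import DgConfig, orient_pair
from .graph import CausalGraph
from .knocknet import NetConfig, select_for_response
from .simulate import SimConfig, SimDataset, simulate_dataset
from .knocknet import fit_response_model


def auc_from_scores(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` against boolean ``labels``.

    Fraction of (true, false) pairs with score_true > score_false, ties
    counted one half.  Accepts aligned arrays, or two dicts keyed by feature.
    """
    if isinstance(scores, dict):
        keys = list(scores)
        s = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([bool(labels[k]) for k in keys])
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=bool)
    n_true = int(y.sum())
    n_false = int((~y).sum())
    if n_true == 0 or n_false == 0:
        raise ValueError("need both classes to compute an AUC")
    # rank-sum formulation with midranks for ties
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_true = ranks[y].sum()
    return float((r_true - n_true * (n_true + 1) / 2.0) / (n_true * n_false))


def causal_confusion(g: CausalGraph, truth: SimDataset) -> tuple[int, int]:
    """(causal_tp, causal_fp) of a graph against simulation ground truth.

    A directed edge true-feature -> Y is a true positive.  Any Y -> feature
    edge, and any directed edge between two non-outcome features, is a false
    positive.  Undirected (tie) edges count neither; a null feature oriented
    into Y is a false association but not a false causality.
    """
    y = truth.OUTCOME
    true_set = set(truth.true_features)
    tp = fp = 0
    for _, r in g.directed_edges().iterrows():
        u, v = (r.var_a, r.var_b) if r.direction == "a_to_b" else (r.var_b, r.var_a)
        if v == y:
            if u in true_set:
                tp += 1
        elif u == y:
            fp += 1
        else:
            fp += 1
    return tp, fp


# ---------------------------------------------------------------------------
# replicate-level experiments
# ---------------------------------------------------------------------------

@dataclass
class BenchResult:
    """Per-replicate table plus mean +/- standard error aggregates."""

    per_replicate: pd.DataFrame
    seeds: list[int]

    @property
    def aggregate(self) -> pd.DataFrame:
        num = self.per_replicate.select_dtypes("number")
        agg = pd.DataFrame({"mean": num.mean(), "sem": num.sem(ddof=1)})
        agg["n_reps"] = len(self.per_replicate)
        return agg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def knockoff_statistics_for_outcome(sim: SimDataset, net_cfg: NetConfig) -> pd.Series:
    """S_j for every feature of a simulated dataset, response Y."""
    _, table = fit_response_model(sim.dataset, sim.OUTCOME, cfg=net_cfg)
    return table["S"]


def auc_replicate(sim: SimDataset, net_cfg: NetConfig) -> float:
    s = knockoff_statistics_for_outcome(sim, net_cfg)
    labels = [sim.labels[f] for f in s.index]
    return auc_from_scores(s.to_numpy(), labels)


def auc_benchmark(
    base: SimConfig,
    n_reps: int = 10,
    seed: int = 1,
    net_cfg: NetConfig | None = None,
) -> BenchResult:
    """Per-dataset AUC of the S-statistic ranking, averaged over replicates."""
    net_cfg = net_cfg or NetConfig()
    seeds = _spawn_seeds(seed, n_reps)
    rows = []
    for rep, s in enumerate(seeds):
        sim = simulate_dataset(replace(base, seed=s))
        auc = auc_replicate(sim, replace(net_cfg, seed=s))
        rows.append({"replicate": rep, "seed": s, "auc": auc})
    return BenchResult(pd.DataFrame(rows), seeds)


def power_causality_replicate(
    sim: SimDataset,
    q: float = 0.05,
    plus: bool = False,
    net_cfg: NetConfig | None = None,
    dg_cfg: DgConfig | None = None,
) -> dict:
    """Selection + orientation readouts for one replicate, response Y only.

    Power is the fraction of true features selected at level q; every
    selected association (feature, Y) is then oriented by the DG rule on the
    raw values, and directions are tallied into causal TP/FP per
    `causal_confusion`'s convention.
    """
    net_cfg = net_cfg or NetConfig()
    dg_cfg = dg_cfg or DgConfig()
    res = select_for_response(sim.dataset, sim.OUTCOME, q=q, plus=plus, cfg=net_cfg)
    true_set = set(sim.true_features)
    selected = set(res.selected)
    n_true_sel = len(selected & true_set)
    n_null_sel = len(selected - true_set)
    fdp = n_null_sel / max(len(selected), 1)

    to_y = from_y = undirected = 0
    true_to_y = 0
    for feat in sorted(selected):
        r = orient_pair(feat, sim.OUTCOME, sim.dataset, dg_cfg)
        if r.direction == "i_to_j":
            to_y += 1
            if feat in true_set:
                true_to_y += 1
        elif r.direction == "j_to_i":
            from_y += 1
        else:
            undirected += 1
    return {
        "n_selected": len(selected),
        "power": n_true_sel / len(true_set),
        "fdp": fdp,
        "causal_tp": true_to_y,
        "causal_fp": from_y,  # Y -> feature orientations; no feature-feature edges arise here
        "oriented_to_y": to_y,
        "oriented_from_y": from_y,
        "undirected": undirected,
        "frac_true_oriented_to_y": (true_to_y / n_true_sel) if n_true_sel else np.nan,
    }


def power_causality_benchmark(
    base: SimConfig,
    n_reps: int = 10,
    seed: int = 1,
    q: float = 0.05,
    plus: bool = False,
    net_cfg: NetConfig | None = None,
    dg_cfg: DgConfig | None = None,
) -> BenchResult:
    net_cfg = net_cfg or NetConfig()
    seeds = _spawn_seeds(seed, n_reps)
    rows = []
    for rep, s in enumerate(seeds):
        sim = simulate_dataset(replace(base, seed=s))
        out = power_causality_replicate(sim, q=q, plus=plus, net_cfg=replace(net_cfg, seed=s), dg_cfg=dg_cfg)
        rows.append({"replicate": rep, "seed": s, **out})
    return BenchResult(pd.DataFrame(rows), seeds)


def run_benchmark(
    scenarios: list[SimConfig],
    n_reps: int = 10,
    seed: int = 1,
    q: float = 0.05,
    plus: bool = False,
    net_cfg: NetConfig | None = None,
    metric: str = "power",
) -> pd.DataFrame:
    """Grid runner: one aggregate row per scenario cell.

    metric="power" runs selection+orientation; metric="auc" runs the
    ranking experiment.  Per-replicate failures are logged in the
    ``n_failed`` column and excluded from the averages.
    """
    rows = []
    for cell, cfg in enumerate(scenarios):
        try:
            if metric == "auc":
                res = auc_benchmark(cfg, n_reps=n_reps, seed=seed + cell, net_cfg=net_cfg)
            else:
                res = power_causality_benchmark(cfg, n_reps=n_reps, seed=seed + cell, q=q, plus=plus, net_cfg=net_cfg)
            agg = res.aggregate
            row = {
                "cell": cell,
                "n_true": cfg.n_true,
                "n_null": cfg.n_null,
                "n_samples": cfg.n_samples,
                "alpha_mix": cfg.alpha_mix,
                "n_reps": len(res.per_replicate),
                "n_failed": 0,
            }
            for name in agg.index:
                if name in ("replicate", "seed"):
                    continue
                row[f"{name}_mean"] = agg.loc[name, "mean"]
                row[f"{name}_sem"] = agg.loc[name, "sem"]
            rows.append(row)
        except Exception as exc:  # pragma: no cover - defensive per-cell guard
            rows.append({"cell": cell, "n_true": cfg.n_true, "n_null": cfg.n_null,
                         "n_samples": cfg.n_samples, "alpha_mix": cfg.alpha_mix,
                         "n_reps": 0, "n_failed": n_reps, "error": str(exc)})
    return pd.DataFrame(rows)
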