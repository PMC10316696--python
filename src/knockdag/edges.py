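"""Edge-list representation shared by all stages.

An edge list is a pandas DataFrame with one row per unordered variable pair:

    var_a, var_b          endpoint names, var_a < var_b lexicographically
    kind                  "linear" | "nonlinear"
    effect_size           raw, non-negative (|beta|, group norm, or knockoff S)
    normalized_effect     min-max scaled within each kind, in [0, 1]
    direction             "a_to_b" | "b_to_a" | "undirected"
    orientation_stat      signed log-likelihood difference from the orientation rule

Raw effect sizes from the two stages live on different scales, so cross-kind
comparisons (cycle repair in particular) use normalized_effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDGE_COLUMNS = [
    "var_a",
    "var_b",
    "kind",
    "effect_size",
    "normalized_effect",
    "direction",
    "orientation_stat",
]

KINDS = ("linear", "nonlinear")
DIRECTIONS = ("a_to_b", "b_to_a", "undirected")


def new_edge_list(records: list[dict] | None = None) -> pd.DataFrame:
    """Build a validated edge table from record dicts (missing fields defaulted)."""
    records = records or []
    rows = []
    for r in records:
        a, b = str(r["var_a"]), str(r["var_b"])
        if a == b:
            raise ValueError(f"self edge on {a!r}")
        if a > b:
            a, b = b, a
        kind = r.get("kind", "linear")
        if kind not in KINDS:
            raise ValueError(f"unknown edge kind {kind!r}")
        eff = float(r.get("effect_size", 0.0))
        if eff < 0:
            raise ValueError("effect_size must be >= 0")
        direction = r.get("direction", "undirected")
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        row = {
            "var_a": a,
            "var_b": b,
            "kind": kind,
            "effect_size": eff,
            "normalized_effect": float(r.get("normalized_effect", np.nan)),
            "direction": direction,
            "orientation_stat": float(r.get("orientation_stat", np.nan)),
        }
        for extra in ("effect_linear", "effect_nonlinear"):
            if extra in r:
                row[extra] = r[extra]
        rows.append(row)
    cols = EDGE_COLUMNS + [c for c in ("effect_linear", "effect_nonlinear") if any(c in r for r in rows)]
    df = pd.DataFrame(rows, columns=cols)
    pairs = list(zip(df["var_a"], df["var_b"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate unordered pairs in edge list")
    return df


def normalize_effects(edges: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale effect sizes within each kind (max -> 1, min -> 0).

    A kind whose effects are all equal (including a single edge) maps to 1.
    """
    out = edges.copy()
    for kind in KINDS:
        mask = out["kind"] == kind
        if not mask.any():
            continue
        eff = out.loc[mask, "effect_size"].to_numpy(dtype=float)
        span = eff.max() - eff.min()
        if span <= 0:
            out.loc[mask, "normalized_effect"] = 1.0
        else:
            out.loc[mask, "normalized_effect"] = (eff - eff.min()) / span
    return out


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
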