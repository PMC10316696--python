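"""Tabular containers and shared preprocessing for mixed-type data.

The whole package operates on a sample-by-variable matrix holding two kinds
of variables: continuous measurements and ordinal categoricals.  Ordinal
variables are stored as 0..L-1 integer codes in declared level order and are
treated as Gaussian-approximate downstream (knockoff construction and the
degenerate-Gaussian score both assume roughly Gaussian marginals).  Nominal
(unordered) categoricals are rejected by design.

Missing values are a hard error: the statistical machinery downstream has no
imputation model, so incomplete samples must be dropped before loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
ORDINAL = "ordinal"

_SAMPLE_ID_COL = "sample_id"


@dataclass(frozen=True)
class VariableMeta:
    """Declared type of a single variable.

    Parameters
    ----------
    name : str
        Column name, unique within a dataset.
    kind : {"continuous", "ordinal"}
    levels : tuple
        Ordered level codes for ordinal variables (at least two); must be
        empty for continuous variables.
    """

    name: str
    kind: str
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, ORDINAL):
            raise ValueError(
                f"variable {self.name!r}: kind must be 'continuous' or 'ordinal', "
                f"got {self.kind!r} (nominal categoricals are not supported)"
            )
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == ORDINAL and len(self.levels) < 2:
            raise ValueError(f"ordinal variable {self.name!r} needs >= 2 levels")
        if self.kind == CONTINUOUS and self.levels:
            raise ValueError(f"continuous variable {self.name!r} must not declare levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class Dataset:
    """Validated N x M value matrix with per-variable metadata.

    ``values`` is float64 throughout; ordinal columns hold integer codes
    0..L-1 in declared level order.
    """

    values: np.ndarray
    meta: list[VariableMeta]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 samples and 2 variables, got {n} x {m}")
        if len(self.meta) != m:
            raise ValueError(f"meta declares {len(self.meta)} variables for {m} columns")
        names = [v.name for v in self.meta]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite values are not allowed; drop incomplete samples upstream")
        for j, v in enumerate(self.meta):
            if v.kind == ORDINAL:
                col = self.values[:, j]
                codes = np.round(col)
                if not np.array_equal(codes, col) or col.min() < 0 or col.max() >= v.n_levels:
                    raise ValueError(f"ordinal column {v.name!r} contains values outside its 0..{v.n_levels - 1} codes")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.meta]

    @property
    def continuous_names(self) -> list[str]:
        return [v.name for v in self.meta if v.kind == CONTINUOUS]

    @property
    def ordinal_names(self) -> list[str]:
        return [v.name for v in self.meta if v.kind == ORDINAL]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def var_meta(self, name: str) -> VariableMeta:
        return self.meta[self.index_of(name)]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index_of(name)]

    def drop(self, name: str) -> "Dataset":
        j = self.index_of(name)
        keep = [k for k in range(self.n_variables) if k != j]
        return Dataset(self.values[:, keep], [self.meta[k] for k in keep], list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=pd.Index(self.sample_ids, name=_SAMPLE_ID_COL))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: Sequence[VariableMeta] | None = None) -> "Dataset":
        """Build a dataset from a numeric frame; columns default to continuous."""
        if meta is None:
            meta = [VariableMeta(str(c), CONTINUOUS) for c in df.columns]
        return cls(df.to_numpy(dtype=float), list(meta), [str(i) for i in df.index])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_meta(meta_path: str | Path) -> list[dict]:
    text = Path(meta_path).read_text()
    if str(meta_path).endswith(".json"):
        entries = json.loads(text)
    else:
        entries = yaml.safe_load(text)
    if not isinstance(entries, list):
        raise ValueError("metadata sidecar must be a list of {name, kind, levels} entries")
    return entries


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def load_dataset(table_path: str | Path, meta_path: str | Path) -> Dataset:
    """Load a delimited table plus its metadata sidecar into a `Dataset`.

    Ordinal columns are mapped to 0..L-1 integer codes preserving the declared
    level order.  Any undeclared column, unknown level code, non-numeric cell
    in a continuous column, or missing value is a hard error.
    """
    df = pd.read_csv(table_path, sep=_sep_for(table_path))
    if df.columns[0] == _SAMPLE_ID_COL:
        sample_ids = [str(s) for s in df[_SAMPLE_ID_COL]]
        df = df.drop(columns=[_SAMPLE_ID_COL])
    else:
        sample_ids = [f"s{i}" for i in range(len(df))]

    entries = _read_meta(meta_path)
    meta_by_name = {}
    for e in entries:
        vm = VariableMeta(str(e["name"]), e["kind"], tuple(e.get("levels") or ()))
        meta_by_name[vm.name] = vm
    for col in df.columns:
        if str(col) not in meta_by_name:
            raise ValueError(f"column {col!r} missing from metadata sidecar")

    meta: list[VariableMeta] = []
    columns = []
    for col in df.columns:
        vm = meta_by_name[str(col)]
        meta.append(vm)
        raw = df[col]
        if raw.isna().any():
            raise ValueError(f"column {col!r} has missing values; drop incomplete samples before loading")
        if vm.kind == CONTINUOUS:
            try:
                columns.append(raw.astype(float).to_numpy())
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric cell in continuous column {col!r}") from exc
        else:
            columns.append(_encode_ordinal(raw, vm))
    values = np.column_stack(columns)
    return Dataset(values, meta, sample_ids)


def _encode_ordinal(series: pd.Series, vm: VariableMeta) -> np.ndarray:
    """Map raw level codes to 0..L-1 in declared order; unknown code -> error."""
    numeric_levels = all(_is_number(lv) for lv in vm.levels)
    if numeric_levels:
        mapping = {float(lv): i for i, lv in enumerate(vm.levels)}
        keys = series.astype(float)
    else:
        mapping = {str(lv): i for i, lv in enumerate(vm.levels)}
        keys = series.astype(str)
    codes = np.empty(len(series), dtype=float)
    for i, k in enumerate(keys):
        if k not in mapping:
            raise ValueError(f"unknown level code {k!r} in ordinal column {vm.name!r} (declared levels: {list(vm.levels)})")
        codes[i] = mapping[k]
    return codes


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_dataset(d: Dataset, table_path: str | Path, meta_path: str | Path) -> None:
    """Write the table + sidecar so that `load_dataset` round-trips losslessly.

    Ordinal codes are decoded back to their declared level labels.
    """
    df = d.to_dataframe().reset_index()
    for v in d.meta:
        if v.kind == ORDINAL:
            df[v.name] = [v.levels[int(c)] for c in df[v.name]]
    df.to_csv(table_path, sep=_sep_for(table_path), index=False, float_format="%.17g")
    entries = [
        {"name": v.name, "kind": v.kind, "levels": list(v.levels)}
        for v in d.meta
    ]
    text = yaml.safe_dump(entries, sort_keys=False)
    Path(meta_path).write_text(text)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizeParams:
    """Per-column (mean, sd) of a standardization, for inversion."""

    names: tuple
    means: np.ndarray
    sds: np.ndarray

    def inverse(self, d: Dataset) -> Dataset:
        values = d.values.copy()
        for name, mu, sd in zip(self.names, self.means, self.sds):
            j = d.index_of(name)
            values[:, j] = values[:, j] * sd + mu
        meta = list(d.meta)
        return Dataset(values, meta, list(d.sample_ids))


def standardize(d: Dataset, which: str = "continuous_only") -> tuple[Dataset, StandardizeParams]:
    """Center/scale columns to sample mean 0 and sample sd 1 (ddof=1).

    ``which`` is ``"continuous_only"`` or ``"all"``; with ``"all"`` ordinal
    code columns are scaled too (they are treated as Gaussian-approximate
    downstream).  A constant column is an error.
    """
    if which not in ("continuous_only", "all"):
        raise ValueError("which must be 'continuous_only' or 'all'")
    values = d.values.copy()
    names, means, sds = [], [], []
    for j, v in enumerate(d.meta):
        if which == "continuous_only" and v.kind != CONTINUOUS:
            continue
        col = values[:, j]
        mu = col.mean()
        sd = col.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"cannot standardize constant column {v.name!r}")
        values[:, j] = (col - mu) / sd
        names.append(v.name)
        means.append(mu)
        sds.append(sd)
    # standardized ordinal codes are no longer integer codes, relabel continuous
    meta = []
    for v in d.meta:
        if v.kind == ORDINAL and which == "all":
            meta.append(VariableMeta(v.name, CONTINUOUS))
        else:
            meta.append(v)
    out = Dataset(values, meta, list(d.sample_ids))
    params = StandardizeParams(tuple(names), np.asarray(means), np.asarray(sds))
    return out, params


# ---------------------------------------------------------------------------
# Inverse-covariance candidate screen
# ---------------------------------------------------------------------------

def precision_screen(d: Dataset, tol: float = 1e-4, ridge: float | str = "auto") -> set[tuple[str, str]]:
    """Admissible unordered pairs by thresholding the inverse covariance.

    A pair (i, j) passes when ``|Omega_ij| >= tol`` with ``Omega`` the inverse
    of the sample covariance of the (numerically coded) matrix.  This is a
    coarse optional pre-filter for conditional independence; it is OFF by
    default in the pipeline.

    ``ridge="auto"`` adds ``1e-6 * trace/M`` to the diagonal when the
    covariance is singular (always when N <= M); ``ridge=0`` disables the
    regularization and raises on singularity.
    """
    cov = np.cov(d.values, rowvar=False, ddof=1)
    m = cov.shape[0]
    eps = 0.0
    if ridge == "auto":
        if d.n_samples <= m or np.linalg.matrix_rank(cov) < m:
            eps = 1e-6 * np.trace(cov) / m
    else:
        eps = float(ridge)
    if eps == 0.0 and (d.n_samples <= m or np.linalg.matrix_rank(cov) < m):
        raise np.linalg.LinAlgError(
            "sample covariance is singular (N <= M?); pass ridge='auto' or a positive ridge, "
            "or collect more samples than variables"
        )
    omega = np.linalg.inv(cov + eps * np.eye(m))
    names = d.names
    pairs = set()
    for i in range(m):
        for j in range(i + 1, m):
            if abs(omega[i, j]) >= tol:
                pairs.add((names[i], names[j]))
    return pairs
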