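"""Pairwise-coupled knockoff filter network: nonlinear association selection.

One response model is fitted per target variable.  Each input feature x_j is
paired with its knockoff x~_j in a filter layer with two scalar weights
(ri_j, ri~_j); the p filter outputs are scaled elementwise by a vector w0 and
passed through two dense ReLU hidden layers and a linear output:

    z_j  = ri_j x_j + ri~_j x~_j
    h0   = w0 * z
    yhat = ReLU(ReLU(h0 W1 + b1) W2 + b2) w3 + b3

Training is minibatch Adam on the mean-squared error with an L1 penalty on
all weight matrices (not biases), Glorot-normal initial weights.  After
training, the dense path collapses to a per-feature vector
w = w0 * (W1 W2 w3) and the importances are RI_j = ri_j w_j and
RI~_j = ri~_j w_j.  The knockoff statistic S_j = |RI_j| - |RI~_j| is
sign-symmetric for null features, so the data-dependent threshold of the
knockoff filter controls the FDR of the selected set; S_j of a selected
feature doubles as its (unsigned) nonlinear effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import Dataset, standardize
from .knockoffs import KnockoffModel, fit_knockoff_model, sample_knockoffs

try:  # JIT-compiled trainer; pure-NumPy fallback keeps the package importable
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not args or not callable(args[0]) else args[0]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training settings for one response model.

    hidden_units=None means p (one unit per input feature, the design the
    hyperparameter experiments in the source framework favour);
    l1_lambda=None means sqrt(2 log p / n); epochs=None sets the epoch count
    from a fixed optimizer-step budget (`step_budget` Adam updates in total,
    clipped to 30..1000 epochs) so that small-sample fits are trained as
    long as large-sample ones; ensemble is the number of independently
    seeded (knockoff draw, initialization) fits whose statistics are
    averaged - a multiple-restart derandomization that stabilizes S against
    both the knockoff sampling noise and the nonconvex fit.
    """

    hidden_layers: int = 2
    hidden_units: int | None = None
    activation: str = "relu"
    init: str = "glorot_normal"
    l1_lambda: float | None = None
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 10
    loss: str = "mse"
    epochs: int | None = None
    step_budget: int = 30_000
    ensemble: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers != 2:
            raise ValueError("the pairwise filter architecture has exactly 2 dense hidden layers")
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.init != "glorot_normal":
            raise ValueError("only glorot_normal init is supported")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")
        if self.epochs is not None and self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.step_budget < 1:
            raise ValueError("step_budget must be >= 1")
        if self.ensemble < 1:
            raise ValueError("ensemble must be >= 1")

    def resolve(self, p: int, n: int) -> "NetConfig":
        """Fill the data-dependent defaults for p features and n samples."""
        h = self.hidden_units if self.hidden_units is not None else p
        lam = self.l1_lambda if self.l1_lambda is not None else float(np.sqrt(2.0 * np.log(p) / n))
        if self.epochs is None:
            steps_per_epoch = -(-n // self.batch_size)
            epochs = max(30, min(1000, -(-self.step_budget // steps_per_epoch)))
        else:
            epochs = self.epochs
        return replace(self, hidden_units=h, l1_lambda=lam, epochs=epochs)


@_njit(cache=True)
def _train_kernel(x, xt, y, ri, ri_t, w0, W1, b1, W2, b2, w3, b3a,
                  epochs, batch, lr, lam, seed):
    """Minibatch Adam on MSE with L1 subgradient; updates parameters in place.

    The shuffling RNG is seeded here so the whole trajectory is a pure
    function of (data, initial weights, hyperparameters, seed).
    """
    n, p = x.shape
    b1m, b2m, eps = 0.9, 0.999, 1e-8

    m_ri = np.zeros(p); v_ri = np.zeros(p)
    m_rit = np.zeros(p); v_rit = np.zeros(p)
    m_w0 = np.zeros(p); v_w0 = np.zeros(p)
    m_W1 = np.zeros_like(W1); v_W1 = np.zeros_like(W1)
    m_b1 = np.zeros_like(b1); v_b1 = np.zeros_like(b1)
    m_W2 = np.zeros_like(W2); v_W2 = np.zeros_like(W2)
    m_b2 = np.zeros_like(b2); v_b2 = np.zeros_like(b2)
    m_w3 = np.zeros_like(w3); v_w3 = np.zeros_like(w3)
    m_b3 = 0.0; v_b3 = 0.0

    np.random.seed(seed)
    order = np.arange(n)
    t = 0
    for _ep in range(epochs):
        for i in range(n - 1, 0, -1):  # Fisher-Yates shuffle
            j = np.random.randint(0, i + 1)
            tmp = order[i]; order[i] = order[j]; order[j] = tmp
        for start in range(0, n, batch):
            end = min(start + batch, n)
            bsz = end - start
            xb = np.empty((bsz, p)); xtb = np.empty((bsz, p)); yb = np.empty(bsz)
            for r in range(bsz):
                k = order[start + r]
                for c in range(p):
                    xb[r, c] = x[k, c]
                    xtb[r, c] = xt[k, c]
                yb[r] = y[k]

            # forward
            z = xb * ri + xtb * ri_t
            h0 = z * w0
            pre1 = h0 @ W1 + b1
            a1 = np.maximum(pre1, 0.0)
            pre2 = a1 @ W2 + b2
            a2 = np.maximum(pre2, 0.0)
            yhat = a2 @ w3 + b3a[0]

            # backward
            e = (2.0 / bsz) * (yhat - yb)
            g_w3 = a2.T @ e
            g_b3 = e.sum()
            d2 = e.reshape(-1, 1) * w3.reshape(1, -1)
            d2 = np.where(pre2 > 0.0, d2, 0.0)
            g_W2 = a1.T @ d2
            g_b2 = d2.sum(axis=0)
            d1 = d2 @ W2.T
            d1 = np.where(pre1 > 0.0, d1, 0.0)
            g_W1 = h0.T @ d1
            g_b1 = d1.sum(axis=0)
            dh0 = d1 @ W1.T
            g_w0 = (dh0 * z).sum(axis=0)
            dz = dh0 * w0
            g_ri = (dz * xb).sum(axis=0)
            g_rit = (dz * xtb).sum(axis=0)

            # L1 subgradient on weights (not biases)
            g_ri = g_ri + lam * np.sign(ri)
            g_rit = g_rit + lam * np.sign(ri_t)
            g_w0 = g_w0 + lam * np.sign(w0)
            g_W1 = g_W1 + lam * np.sign(W1)
            g_W2 = g_W2 + lam * np.sign(W2)
            g_w3 = g_w3 + lam * np.sign(w3)

            t += 1
            c1 = 1.0 - b1m ** t
            c2 = 1.0 - b2m ** t

            m_ri = b1m * m_ri + (1 - b1m) * g_ri; v_ri = b2m * v_ri + (1 - b2m) * g_ri * g_ri
            ri -= lr * (m_ri / c1) / (np.sqrt(v_ri / c2) + eps)
            m_rit = b1m * m_rit + (1 - b1m) * g_rit; v_rit = b2m * v_rit + (1 - b2m) * g_rit * g_rit
            ri_t -= lr * (m_rit / c1) / (np.sqrt(v_rit / c2) + eps)
            m_w0 = b1m * m_w0 + (1 - b1m) * g_w0; v_w0 = b2m * v_w0 + (1 - b2m) * g_w0 * g_w0
            w0 -= lr * (m_w0 / c1) / (np.sqrt(v_w0 / c2) + eps)
            m_W1 = b1m * m_W1 + (1 - b1m) * g_W1; v_W1 = b2m * v_W1 + (1 - b2m) * g_W1 * g_W1
            W1 -= lr * (m_W1 / c1) / (np.sqrt(v_W1 / c2) + eps)
            m_b1 = b1m * m_b1 + (1 - b1m) * g_b1; v_b1 = b2m * v_b1 + (1 - b2m) * g_b1 * g_b1
            b1 -= lr * (m_b1 / c1) / (np.sqrt(v_b1 / c2) + eps)
            m_W2 = b1m * m_W2 + (1 - b1m) * g_W2; v_W2 = b2m * v_W2 + (1 - b2m) * g_W2 * g_W2
            W2 -= lr * (m_W2 / c1) / (np.sqrt(v_W2 / c2) + eps)
            m_b2 = b1m * m_b2 + (1 - b1m) * g_b2; v_b2 = b2m * v_b2 + (1 - b2m) * g_b2 * g_b2
            b2 -= lr * (m_b2 / c1) / (np.sqrt(v_b2 / c2) + eps)
            m_w3 = b1m * m_w3 + (1 - b1m) * g_w3; v_w3 = b2m * v_w3 + (1 - b2m) * g_w3 * g_w3
            w3 -= lr * (m_w3 / c1) / (np.sqrt(v_w3 / c2) + eps)
            m_b3 = b1m * m_b3 + (1 - b1m) * g_b3; v_b3 = b2m * v_b3 + (1 - b2m) * g_b3 * g_b3
            b3a[0] -= lr * (m_b3 / c1) / (np.sqrt(v_b3 / c2) + eps)


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) spawned from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


class PairwiseKnockoffNet:
    """NumPy implementation of the filter network for a single response."""

    def __init__(self, p: int, cfg: NetConfig):
        self.p = p
        self.h = cfg.hidden_units if cfg.hidden_units is not None else p
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._init_params(rng)

    def _glorot(self, rng, fan_in, fan_out, shape):
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)

    def _init_params(self, rng):
        p, h = self.p, self.h
        # filter pair (x_j, x~_j) -> one unit: a (2 -> 1) layer per feature
        self.ri = self._glorot(rng, 2, 1, p)
        self.ri_t = self._glorot(rng, 2, 1, p)
        self.w0 = self._glorot(rng, 1, 1, p)
        self.W1 = self._glorot(rng, p, h, (p, h))
        self.b1 = np.zeros(h)
        self.W2 = self._glorot(rng, h, h, (h, h))
        self.b2 = np.zeros(h)
        self.w3 = self._glorot(rng, h, 1, h)
        self.b3 = 0.0

    # -- forward ---------------------------------------------------------
    def predict(self, x: np.ndarray, x_tilde: np.ndarray) -> np.ndarray:
        z = x * self.ri + x_tilde * self.ri_t
        h0 = z * self.w0
        a1 = np.maximum(h0 @ self.W1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        return a2 @ self.w3 + self.b3

    def loss(self, x, x_tilde, y) -> float:
        """Penalized training loss (MSE + L1 on weights)."""
        mse = float(np.mean((self.predict(x, x_tilde) - y) ** 2))
        lam = self.cfg.l1_lambda or 0.0
        l1 = sum(np.abs(w).sum() for w in (self.ri, self.ri_t, self.w0, self.W1, self.W2, self.w3))
        return mse + lam * l1

    # -- training --------------------------------------------------------
    def fit(self, x: np.ndarray, x_tilde: np.ndarray, y: np.ndarray) -> "PairwiseKnockoffNet":
        """Minibatch Adam on MSE; deterministic given cfg.seed."""
        x = np.ascontiguousarray(x, float)
        x_tilde = np.ascontiguousarray(x_tilde, float)
        y = np.ascontiguousarray(np.asarray(y, float).ravel())
        n, p = x.shape
        if p != self.p:
            raise ValueError(f"model built for {self.p} features, got {p}")
        if len(y) != n or x_tilde.shape != x.shape:
            raise ValueError("x, x_tilde, y must have matching shapes")
        cfg = self.cfg.resolve(p, n)
        self.cfg = cfg
        if cfg.epochs == 0:
            return self
        b3a = np.array([self.b3])
        _train_kernel(
            x, x_tilde, y,
            self.ri, self.ri_t, self.w0, self.W1, self.b1, self.W2, self.b2, self.w3, b3a,
            cfg.epochs, cfg.batch_size, cfg.learning_rate, cfg.l1_lambda,
            int(cfg.seed) % (2**31),
        )
        self.b3 = float(b3a[0])
        for name in ("ri", "ri_t", "w0", "W1", "W2", "w3"):
            if not np.isfinite(getattr(self, name)).all():
                raise FloatingPointError(
                    f"non-finite weights after training (learning rate {cfg.learning_rate}); "
                    "lower the learning rate or rescale the response"
                )
        return self


def importance_from_weights(model: PairwiseKnockoffNet) -> pd.DataFrame:
    """Per-feature importances from the trained weights.

    The dense path collapses to w = w0 * (W1 W2 w3); RI_j = ri_j w_j and
    RI~_j = ri~_j w_j (the pair shares the single downstream path through its
    filter unit).  Returns one row per feature with the statistic
    S = |RI| - |RI~|.
    """
    if model.W1.shape != (model.p, model.h) or model.W2.shape != (model.h, model.h):
        raise ValueError("architecture mismatch: dense weights do not match (p, h)")
    path = model.W1 @ (model.W2 @ model.w3)
    w = model.w0 * path
    ri, ri_t = model.ri, model.ri_t
    out = pd.DataFrame(
        {
            "ri": ri,
            "ri_tilde": ri_t,
            "RI": ri * w,
            "RI_tilde": ri_t * w,
        }
    )
    out["S"] = np.abs(out["RI"]) - np.abs(out["RI_tilde"])
    if not np.isfinite(out["S"]).all():
        raise ValueError("non-finite importance; training diverged")
    return out


def knockoff_threshold(s: np.ndarray, q: float = 0.05, plus: bool = True) -> float:
    """Data-dependent selection threshold of the knockoff filter.

    Scans the candidate set {|S_j| : S_j != 0} and returns the smallest t with

        #{j : S_j <= -t} / #{j : S_j >= t} <= q          (plus=False, T)
        (1 + #{j : S_j <= -t}) / max(1, #{j : S_j >= t}) <= q   (plus=True, T+)

    or +inf when no t qualifies (then nothing is selected).  The selected set
    is {j : S_j >= threshold}.  T+ guarantees FDR <= q; plain T controls a
    modified FDR and is the variant with usable power when fewer than 1/q
    features are truly active.
    """
    s = np.asarray(s, dtype=float)
    if s.size and not np.isfinite(s).all():
        raise ValueError("statistics must be finite")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    candidates = np.unique(np.abs(s[s != 0.0]))
    for t in candidates:
        neg = int(np.sum(s <= -t))
        pos = int(np.sum(s >= t))
        if plus:
            ratio = (1 + neg) / max(1, pos)
        else:
            if pos == 0:
                ratio = 0.0 if neg == 0 else np.inf
            else:
                ratio = neg / pos
        if ratio <= q:
            return float(t)
    return float("inf")


@dataclass
class SelectionResult:
    """Outcome of the knockoff filter for one response variable."""

    response: str
    selected: list[str]
    threshold: float
    q: float
    statistics: pd.Series      # S_j for every candidate feature
    effect_sizes: pd.Series    # S_j restricted to the selected features

    @property
    def n_selected(self) -> int:
        return len(self.selected)


class KnockoffFilterEnsemble:
    """A bag of independently seeded filter-network fits for one response."""

    def __init__(self, members: list[PairwiseKnockoffNet]):
        if not members:
            raise ValueError("empty ensemble")
        self.members = members

    @property
    def p(self) -> int:
        return self.members[0].p


def fit_response_model(
    d: Dataset,
    response: str,
    cfg: NetConfig | None = None,
    knockoffs: np.ndarray | None = None,
    km: KnockoffModel | None = None,
    shrinkage: float | None = None,
) -> tuple[PairwiseKnockoffNet | KnockoffFilterEnsemble, pd.DataFrame]:
    """Fit the filter network(s) with ``response`` as outcome, rest as input.

    Input features are standardized internally and the response is centered
    but kept on its observed scale: the L1 strength sqrt(2 log p / n) is an
    absolute quantity, so rescaling the response would change how aggressive
    the penalty is relative to the signal.  With cfg.ensemble > 1, that many
    independently seeded fits are run - each with its own knockoff draw
    unless an explicit knockoff matrix is supplied - and the returned
    importance table is the member average (the returned model is the
    ensemble).  Seeds for knockoff noise and training are spawned from
    cfg.seed so a seed shared with an upstream data generator cannot
    correlate the streams.
    """
    cfg = cfg or NetConfig()
    y = d.column(response)
    if y.std(ddof=1) == 0:
        raise ValueError(f"constant response {response!r}")
    y = y - y.mean()
    feats, _ = standardize(d.drop(response), which="all")
    x = feats.values
    names = feats.names
    n, p = x.shape

    if km is None and knockoffs is None:
        km = fit_knockoff_model(x, shrinkage=shrinkage)
    seeds = _derived_seeds(cfg.seed, 2 * cfg.ensemble)
    members: list[PairwiseKnockoffNet] = []
    tables: list[pd.DataFrame] = []
    for k in range(cfg.ensemble):
        noise_seed, net_seed = seeds[2 * k], seeds[2 * k + 1]
        xt = knockoffs if knockoffs is not None else sample_knockoffs(x, km, seed=noise_seed)
        member = PairwiseKnockoffNet(p, replace(cfg.resolve(p, n), seed=net_seed, ensemble=1))
        member.fit(x, xt, y)
        tables.append(importance_from_weights(member))
        members.append(member)

    table = sum(tables[1:], tables[0].copy()) / len(tables)
    table.index = pd.Index(names, name="feature")
    model = members[0] if cfg.ensemble == 1 else KnockoffFilterEnsemble(members)
    return model, table


def select_for_response(
    d: Dataset,
    response: str,
    q: float = 0.05,
    plus: bool = False,
    cfg: NetConfig | None = None,
    shrinkage: float | None = None,
) -> SelectionResult:
    """Knockoff-filter feature selection against one response at FDR level q."""
    _, table = fit_response_model(d, response, cfg=cfg, shrinkage=shrinkage)
    s = table["S"]
    thr = knockoff_threshold(s.to_numpy(), q=q, plus=plus)
    selected = [str(f) for f in s.index[s >= thr]]
    return SelectionResult(response, selected, thr, q, s, s.loc[selected])


class KnockoffFilterModel:
    """Nonlinear variable-selection model for one response (Model/Results surface).

    Wraps knockoff construction + the pairwise filter network; ``fit``
    returns a results object carrying the importance table, the selection at
    the requested FDR level, and a text summary.
    """

    def __init__(self, dataset: Dataset, response: str, cfg: NetConfig | None = None,
                 shrinkage: float | None = None):
        if response not in dataset.names:
            raise KeyError(f"unknown response {response!r}")
        self.dataset = dataset
        self.response = response
        self.cfg = cfg or NetConfig()
        self.shrinkage = shrinkage

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, meta=None, **kwargs) -> "KnockoffFilterModel":
        return cls(Dataset.from_dataframe(df, meta), response, **kwargs)

    def fit(self, q: float = 0.05, plus: bool = False, seed: int | None = None) -> "KnockoffFilterResults":
        cfg = self.cfg if seed is None else replace(self.cfg, seed=seed)
        model, table = fit_response_model(self.dataset, self.response, cfg=cfg, shrinkage=self.shrinkage)
        s = table["S"]
        thr = knockoff_threshold(s.to_numpy(), q=q, plus=plus)
        selected = [str(f) for f in s.index[s >= thr]]
        sel = SelectionResult(self.response, selected, thr, q, s, s.loc[selected])
        return KnockoffFilterResults(self, model, table, sel, plus)


class KnockoffFilterResults:
    def __init__(self, model_spec: KnockoffFilterModel, network, importances: pd.DataFrame,
                 selection: SelectionResult, plus: bool):
        self.model_spec = model_spec
        self.network = network
        self.importances = importances
        self.selection = selection
        self.plus = plus

    @property
    def effect_sizes(self) -> pd.Series:
        return self.selection.effect_sizes

    def summary(self) -> str:
        sel = self.selection
        kind = "knockoff+" if self.plus else "knockoff"
        lines = [
            f"Knockoff-filter network, response {sel.response!r}",
            f"  candidates: {len(sel.statistics)}, {kind} threshold at q={sel.q}: {sel.threshold}",
            f"  selected: {sel.n_selected}",
        ]
        for feat, eff in sel.effect_sizes.sort_values(ascending=False).items():
            lines.append(f"    {feat}  S = {eff:.4f}")
        return "\n".join(lines)


def select_nonlinear(
    d: Dataset,
    targets: list[str] | None = None,
    q: float = 0.05,
    plus: bool = False,
    cfg: NetConfig | None = None,
    shrinkage: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nonlinear association edges over a set of response variables.

    For each target, fits knockoffs + a filter network and selects features
    at FDR level q; each selected (feature, target) pair becomes a nonlinear
    edge with effect size S_j.  Duplicate unordered pairs from different
    targets are merged keeping the larger effect.  Returns an edge table
    (columns var_a, var_b, kind, effect_size).
    """
    from .edges import new_edge_list  # local import to avoid a cycle

    cfg = cfg or NetConfig()
    targets = list(targets) if targets is not None else list(d.names)
    ss = np.random.SeedSequence(seed)
    records = {}
    for target, child_seed in zip(targets, ss.spawn(len(targets))):
        t_seed = int(child_seed.generate_state(1)[0] % (2**31))
        res = select_for_response(
            d, target, q=q, plus=plus, cfg=replace(cfg, seed=t_seed), shrinkage=shrinkage
        )
        for feat in res.selected:
            key = tuple(sorted((feat, res.response)))
            eff = float(res.effect_sizes[feat])
            if key not in records or eff > records[key]:
                records[key] = eff
    rows = [
        {"var_a": a, "var_b": b, "kind": "nonlinear", "effect_size": eff}
        for (a, b), eff in sorted(records.items())
    ]
    return new_edge_list(rows)
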