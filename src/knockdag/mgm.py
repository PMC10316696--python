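"""Penalized mixed-graphical-model pseudo-likelihood: linear association stage.

The Lee-Hastie pairwise model couples C continuous and D ordinal variables
through shared interaction blocks: beta (C x C, continuous-continuous),
nu (per continuous-ordinal pair, one weight per level) and Phi (per
ordinal-ordinal pair, a level-by-level matrix).  The partition function is
never computed; instead the node-conditional pseudo-likelihood is used:
each continuous node contributes a Gaussian least-squares conditional and
each ordinal node a multinomial-logistic conditional, both parameterized by
the shared blocks.  The negative pseudo-likelihood here is averaged over
samples, which puts the default sparsity penalties (0.3) on the scale of
correlations.

Sparsity comes from a group-lasso penalty,

    lambda_cc sum |beta_ij| + lambda_cd sum ||nu_ij||_2 + lambda_dd sum ||Phi_ij||_F,

minimized by proximal gradient with backtracking line search (soft threshold
on beta entries, group soft threshold on nu vectors and Phi blocks).  A pair
whose block survives the penalty is a selected linear association; its
effect size is the block magnitude.  There is no secondary significance
test: the penalty is the selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .dataset import CONTINUOUS, ORDINAL, Dataset
from .edges import new_edge_list


@dataclass(frozen=True)
class MgmPenalties:
    """Sparsity penalties per interaction type (continuous-continuous,
    continuous-discrete, discrete-discrete)."""

    lambda_cc: float = 0.3
    lambda_cd: float = 0.3
    lambda_dd: float = 0.3

    def __post_init__(self):
        if min(self.lambda_cc, self.lambda_cd, self.lambda_dd) < 0:
            raise ValueError("penalties must be >= 0")


class _MgmData:
    """Pre-split design: continuous block, ordinal codes and one-hots."""

    def __init__(self, d: Dataset):
        self.cont_idx = [j for j, v in enumerate(d.meta) if v.kind == CONTINUOUS]
        self.disc_idx = [j for j, v in enumerate(d.meta) if v.kind == ORDINAL]
        self.cont_names = [d.meta[j].name for j in self.cont_idx]
        self.disc_names = [d.meta[j].name for j in self.disc_idx]
        self.x = d.values[:, self.cont_idx]
        self.n = d.n_samples
        self.levels = [d.meta[j].n_levels for j in self.disc_idx]
        self.onehot = []
        for j, L in zip(self.disc_idx, self.levels):
            codes = d.values[:, j].astype(int)
            oh = np.zeros((self.n, L))
            oh[np.arange(self.n), codes] = 1.0
            self.onehot.append(oh)

    @property
    def c(self) -> int:
        return len(self.cont_idx)

    @property
    def d_count(self) -> int:
        return len(self.disc_idx)


@dataclass
class MgmFit:
    """Fitted parameter blocks of the pairwise model.

    beta is symmetric with zero diagonal; nu[e] stacks, for ordinal variable
    e, one weight row per continuous variable (C x L_e); phi[(e, f)] holds
    the level-by-level interactions for e < f.  alpha_pot / disc_pot are the
    nuisance node potentials (intercepts).
    """

    cont_names: list[str]
    disc_names: list[str]
    levels: list[int]
    beta: np.ndarray
    alpha_pot: np.ndarray
    nu: list[np.ndarray]
    phi: dict[tuple[int, int], np.ndarray]
    disc_pot: list[np.ndarray]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @classmethod
    def zeros(cls, data: _MgmData) -> "MgmFit":
        c, dd = data.c, data.d_count
        return cls(
            cont_names=list(data.cont_names),
            disc_names=list(data.disc_names),
            levels=list(data.levels),
            beta=np.zeros((c, c)),
            alpha_pot=np.zeros(c),
            nu=[np.zeros((c, L)) for L in data.levels],
            phi={(e, f): np.zeros((data.levels[e], data.levels[f])) for e in range(dd) for f in range(e + 1, dd)},
            disc_pot=[np.zeros(L) for L in data.levels],
        )

    def copy_params(self) -> "MgmFit":
        return MgmFit(
            self.cont_names,
            self.disc_names,
            self.levels,
            self.beta.copy(),
            self.alpha_pot.copy(),
            [v.copy() for v in self.nu],
            {k: v.copy() for k, v in self.phi.items()},
            [v.copy() for v in self.disc_pot],
            list(self.objective_trace),
            self.converged,
        )


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------

def _cont_means(data: _MgmData, fit: MgmFit) -> np.ndarray:
    """Conditional mean of every continuous node given the rest (N x C)."""
    mean = data.x @ fit.beta + fit.alpha_pot
    for e in range(data.d_count):
        mean = mean + data.onehot[e] @ fit.nu[e].T
    return mean


def _disc_logits(data: _MgmData, fit: MgmFit, e: int) -> np.ndarray:
    """Multinomial logits of ordinal node e over its levels (N x L_e)."""
    eta = np.broadcast_to(fit.disc_pot[e], (data.n, data.levels[e])).copy()
    eta += data.x @ fit.nu[e]
    for f in range(data.d_count):
        if f == e:
            continue
        lo, hi = min(e, f), max(e, f)
        block = fit.phi[(lo, hi)]
        if e == lo:
            eta += data.onehot[f] @ block.T
        else:
            eta += data.onehot[f] @ block
    return eta


def _smooth_objective(data: _MgmData, fit: MgmFit) -> float:
    n = data.n
    obj = 0.0
    if data.c:
        resid = _cont_means(data, fit) - data.x
        obj += 0.5 * float(np.sum(resid**2)) / n
    for e in range(data.d_count):
        eta = _disc_logits(data, fit, e)
        obj += float(np.sum(logsumexp(eta, axis=1) - np.sum(eta * data.onehot[e], axis=1))) / n
    return obj


def _smooth_gradient(data: _MgmData, fit: MgmFit) -> MgmFit:
    """Exact gradient of the smooth part w.r.t. the shared blocks."""
    n = data.n
    g = MgmFit.zeros(data)
    if data.c:
        resid = (_cont_means(data, fit) - data.x) / n  # N x C
        g.alpha_pot = resid.sum(axis=0)
        gb = data.x.T @ resid
        g.beta = gb + gb.T       # shared symmetric beta appears in both conditionals
        np.fill_diagonal(g.beta, 0.0)
    probs = []
    for e in range(data.d_count):
        pr = softmax(_disc_logits(data, fit, e), axis=1)
        probs.append(pr)
        delta = (pr - data.onehot[e]) / n  # N x L_e
        g.disc_pot[e] = delta.sum(axis=0)
        if data.c:
            g.nu[e] = data.x.T @ delta + (data.onehot[e].T @ resid).T
    for e in range(data.d_count):
        for f in range(e + 1, data.d_count):
            delta_e = (probs[e] - data.onehot[e]) / n
            delta_f = (probs[f] - data.onehot[f]) / n
            g.phi[(e, f)] = delta_e.T @ data.onehot[f] + (delta_f.T @ data.onehot[e]).T
    return g


def _penalty_value(fit: MgmFit, pen: MgmPenalties) -> float:
    val = pen.lambda_cc * float(np.abs(np.triu(fit.beta, 1)).sum())
    for e in range(len(fit.disc_names)):
        val += pen.lambda_cd * float(np.linalg.norm(fit.nu[e], axis=1).sum())
    for block in fit.phi.values():
        val += pen.lambda_dd * float(np.linalg.norm(block))
    return val


def _prox(fit: MgmFit, pen: MgmPenalties, step: float) -> MgmFit:
    out = fit.copy_params()
    # soft threshold beta entries (keep symmetry, zero diagonal)
    thr = step * pen.lambda_cc
    b = out.beta
    out.beta = np.sign(b) * np.maximum(np.abs(b) - thr, 0.0)
    np.fill_diagonal(out.beta, 0.0)
    # group soft threshold each nu row (one continuous-ordinal pair)
    for e in range(len(out.nu)):
        norms = np.linalg.norm(out.nu[e], axis=1)
        scale = np.zeros_like(norms)
        nz = norms > 0
        scale[nz] = np.maximum(1.0 - step * pen.lambda_cd / norms[nz], 0.0)
        out.nu[e] = out.nu[e] * scale[:, None]
    # group soft threshold each Phi block (Frobenius)
    for key, block in out.phi.items():
        nrm = np.linalg.norm(block)
        out.phi[key] = block * max(1.0 - step * pen.lambda_dd / nrm, 0.0) if nrm > 0 else block
    return out


def _axpy(base: MgmFit, direction: MgmFit, t: float) -> MgmFit:
    out = base.copy_params()
    out.beta = base.beta - t * direction.beta
    out.alpha_pot = base.alpha_pot - t * direction.alpha_pot
    out.nu = [b - t * g for b, g in zip(base.nu, direction.nu)]
    out.phi = {k: base.phi[k] - t * direction.phi[k] for k in base.phi}
    out.disc_pot = [b - t * g for b, g in zip(base.disc_pot, direction.disc_pot)]
    return out


def _param_dot(a: MgmFit, b: MgmFit) -> float:
    # beta_st (s < t) is one shared parameter; its full derivative already
    # sums both node conditionals, so the inner product runs over the
    # upper triangle once
    total = float(np.sum(np.triu(a.beta, 1) * np.triu(b.beta, 1)))
    total += float(a.alpha_pot @ b.alpha_pot)
    for u, v in zip(a.nu, b.nu):
        total += float(np.sum(u * v))
    for k in a.phi:
        total += float(np.sum(a.phi[k] * b.phi[k]))
    for u, v in zip(a.disc_pot, b.disc_pot):
        total += float(u @ v)
    return total


def _axpy_diff(a: MgmFit, b: MgmFit) -> MgmFit:
    out = a.copy_params()
    out.beta = a.beta - b.beta
    out.alpha_pot = a.alpha_pot - b.alpha_pot
    out.nu = [u - v for u, v in zip(a.nu, b.nu)]
    out.phi = {k: a.phi[k] - b.phi[k] for k in a.phi}
    out.disc_pot = [u - v for u, v in zip(a.disc_pot, b.disc_pot)]
    return out


def neg_pseudolikelihood(d: Dataset, params: MgmFit) -> float:
    """Negative node-conditional pseudo-likelihood, averaged over samples.

    Sum over continuous nodes of Gaussian least-squares conditionals plus sum
    over ordinal nodes of multinomial-logistic conditionals, all sharing the
    blocks in ``params``.
    """
    _check_finite(params)
    return _smooth_objective(_MgmData(d), params)


def _check_finite(fit: MgmFit) -> None:
    arrays = [fit.beta, fit.alpha_pot, *fit.nu, *fit.phi.values(), *fit.disc_pot]
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("non-finite parameter in MGM fit")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_mgm(
    d: Dataset,
    pen: MgmPenalties | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> MgmFit:
    """Proximal-gradient minimizer of the penalized pseudo-likelihood.

    Continuous columns should be standardized beforehand.  The recorded
    ``objective_trace`` (penalized objective per iteration) is non-increasing
    by construction of the backtracking line search; non-convergence at
    max_iter raises a warning and returns the best iterate.
    """
    pen = pen or MgmPenalties()
    if d.n_samples <= 10:
        raise ValueError("need more than 10 samples to fit the MGM")
    data = _MgmData(d)
    fit = MgmFit.zeros(data)

    # Lipschitz estimate from the largest eigenvalue of the embedded design
    # covariance (the smooth part is quadratic/logistic in that design)
    design = [data.x] if data.c else []
    design += data.onehot
    z = np.hstack(design)
    lmax = float(np.linalg.eigvalsh(z.T @ z / data.n)[-1])
    step = 1.0 / max(2.0 * lmax, 1e-8)

    obj = _smooth_objective(data, fit) + _penalty_value(fit, pen)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        grad = _smooth_gradient(data, fit)
        smooth0 = obj - _penalty_value(fit, pen)
        t = step
        for _bt in range(60):
            cand = _prox(_axpy(fit, grad, t), pen, t)
            diff = _axpy_diff(cand, fit)
            smooth_cand = _smooth_objective(data, cand)
            quad = smooth0 + _param_dot(grad, diff) + _param_dot(diff, diff) / (2.0 * t)
            if smooth_cand <= quad + 1e-12:
                break
            t *= 0.5
        new_obj = smooth_cand + _penalty_value(cand, pen)
        if new_obj > obj + 1e-12:
            break  # cannot decrease further at numerical precision
        fit = cand
        rel = abs(obj - new_obj) / max(abs(obj), 1.0)
        obj = new_obj
        trace.append(obj)
        step = min(t * 1.5, 1.0 / max(lmax, 1e-8))
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MGM proximal gradient did not converge; returning best iterate", RuntimeWarning)
    fit.objective_trace = trace
    fit.converged = converged
    return fit


def extract_linear_edges(fit: MgmFit) -> pd.DataFrame:
    """One linear edge per surviving interaction block.

    Effect sizes: |beta_ij| (cont-cont), ||nu_ij||_2 (cont-ordinal),
    ||Phi_ij||_F (ordinal-ordinal).
    """
    rows = []
    c = len(fit.cont_names)
    for i in range(c):
        for j in range(i + 1, c):
            if fit.beta[i, j] != 0.0:
                rows.append(
                    {"var_a": fit.cont_names[i], "var_b": fit.cont_names[j], "kind": "linear",
                     "effect_size": abs(float(fit.beta[i, j]))}
                )
    for e, name_e in enumerate(fit.disc_names):
        norms = np.linalg.norm(fit.nu[e], axis=1)
        for i in range(c):
            if norms[i] > 0.0:
                rows.append(
                    {"var_a": fit.cont_names[i], "var_b": name_e, "kind": "linear",
                     "effect_size": float(norms[i])}
                )
    for (e, f), block in fit.phi.items():
        nrm = float(np.linalg.norm(block))
        if nrm > 0.0:
            rows.append(
                {"var_a": fit.disc_names[e], "var_b": fit.disc_names[f], "kind": "linear",
                 "effect_size": nrm}
            )
    return new_edge_list(rows)


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class MgmModel:
    """Linear-association model over a dataset (statsmodels-style surface)."""

    def __init__(self, dataset: Dataset, penalties: MgmPenalties | None = None):
        self.dataset = dataset
        self.penalties = penalties or MgmPenalties()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta=None, penalties: MgmPenalties | None = None) -> "MgmModel":
        return cls(Dataset.from_dataframe(df, meta), penalties)

    def fit(self, max_iter: int = 500, tol: float = 1e-7) -> "MgmResults":
        fit = fit_mgm(self.dataset, self.penalties, max_iter=max_iter, tol=tol)
        return MgmResults(self, fit)


class MgmResults:
    def __init__(self, model: MgmModel, params: MgmFit):
        self.model = model
        self.params = params
        self.edges = extract_linear_edges(params)

    @property
    def objective_trace(self) -> list[float]:
        return self.params.objective_trace

    def summary(self) -> str:
        pen = self.model.penalties
        lines = [
            "Mixed graphical model (penalized pseudo-likelihood)",
            f"  samples: {self.model.dataset.n_samples}, variables: {self.model.dataset.n_variables}",
            f"  penalties: cc={pen.lambda_cc} cd={pen.lambda_cd} dd={pen.lambda_dd}",
            f"  iterations: {len(self.objective_trace) - 1} (converged: {self.params.converged})",
            f"  final objective: {self.objective_trace[-1]:.6f}",
            f"  selected linear edges: {len(self.edges)}",
        ]
        for _, r in self.edges.iterrows():
            lines.append(f"    {r.var_a} -- {r.var_b}  effect {r.effect_size:.4f}")
        return "\n".join(lines)
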