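"""Gaussian model-X knockoff construction.

A knockoff copy X~ of the feature matrix X preserves the feature covariance
(cov(X~) = Sigma, cov(X, X~) = Sigma - diag{s}) while being conditionally
independent of any response given X.  Selection statistics contrasting a
feature with its knockoff are therefore sign-symmetric for null features,
which is what gives the downstream filter its FDR control.

Knockoffs are sampled from the exact Gaussian conditional

    x~ | x  ~  N( x - diag{s} Sigma^-1 x,  2 diag{s} - diag{s} Sigma^-1 diag{s} ),

with x centered.  The diagonal s uses the equicorrelated rule on the
correlation scale, s_j = min(2 lambda_min(R), 1), rescaled to covariance
units and shrunk back geometrically if the conditional covariance loses
positive semidefiniteness numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KnockoffModel:
    """Estimated Gaussian feature model plus the knockoff diagonal."""

    mu: np.ndarray
    Sigma: np.ndarray
    s_diag: np.ndarray
    seed: int = 0
    # cached sampling operators
    _coef: np.ndarray | None = None       # Sigma^-1 diag{s}, applied row-wise
    _cond_sqrt: np.ndarray | None = None  # symmetric square root of the conditional covariance

    @property
    def n_features(self) -> int:
        return len(self.mu)

    def conditional_covariance(self) -> np.ndarray:
        d = np.diag(self.s_diag)
        return 2.0 * d - d @ np.linalg.solve(self.Sigma, d)

    def _prepare(self) -> None:
        if self._coef is not None:
            return
        self._coef = np.linalg.solve(self.Sigma, np.diag(self.s_diag))
        cond = self.conditional_covariance()
        w, v = np.linalg.eigh((cond + cond.T) / 2.0)
        w = np.clip(w, 0.0, None)
        self._cond_sqrt = (v * np.sqrt(w)) @ v.T


def fit_knockoff_model(x: np.ndarray, shrinkage: float | None = None, seed: int = 0) -> KnockoffModel:
    """Estimate mean/covariance of X and choose the knockoff diagonal s.

    shrinkage=None picks 0.1 when N < 2M (Sigma must be well conditioned for
    the conditional above) and 0 otherwise; an explicit value in [0, 1] blends
    the sample covariance with its diagonal: (1-g) S + g diag(S).
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    if shrinkage is None:
        shrinkage = 0.1 if n < 2 * m else 0.0
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    mu = x.mean(axis=0)
    s_emp = np.cov(x, rowvar=False, ddof=1)
    s_emp = np.atleast_2d(s_emp)
    sigma = (1.0 - shrinkage) * s_emp + shrinkage * np.diag(np.diag(s_emp))
    sigma = (sigma + sigma.T) / 2.0

    sd = np.sqrt(np.diag(sigma))
    if np.any(sd <= 0):
        raise ValueError("zero-variance feature; remove constant columns first")
    corr = sigma / np.outer(sd, sd)
    lam_min = np.linalg.eigvalsh(corr)[0]
    if lam_min <= 0:
        raise ValueError(
            "estimated covariance is not positive definite; increase the shrinkage "
            "(e.g. fit_knockoff_model(x, shrinkage=0.2))"
        )
    # equicorrelated rule on the correlation scale, then back to covariance units
    s_corr = min(2.0 * lam_min, 1.0)
    s = s_corr * np.diag(sigma)

    km = KnockoffModel(mu, sigma, s, seed=seed)
    # shrink back until 2 diag{s} - diag{s} Sigma^-1 diag{s} is numerically PSD
    scale = max(np.trace(sigma) / m, 1e-12)
    for _ in range(200):
        w_min = np.linalg.eigvalsh(km.conditional_covariance())[0]
        if w_min >= -1e-10 * scale:
            break
        km.s_diag = km.s_diag * 0.95
    else:
        raise ValueError("could not find a valid knockoff diagonal; increase the shrinkage")
    return km


def sample_knockoffs(x: np.ndarray, km: KnockoffModel, seed: int | None = None) -> np.ndarray:
    """Draw the knockoff matrix X~, same shape as X; deterministic given seed."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != km.n_features:
        raise ValueError("feature count does not match the knockoff model")
    km._prepare()
    rng = np.random.default_rng(km.seed if seed is None else seed)
    xc = x - km.mu
    mean = xc - xc @ km._coef
    noise = rng.standard_normal(x.shape) @ km._cond_sqrt
    return km.mu + mean + noise
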