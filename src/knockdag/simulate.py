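"""Single-index benchmark simulator with controlled nonlinearity.

Generates datasets of p outcome-driving features, q null features, and a
continuous outcome

    Y = alpha * g(x' beta) + (1 - alpha) * x' gamma + eps,

with g the cube link, eps ~ N(0, sigma^2), and all p+q feature columns drawn
jointly Gaussian with an AR-structured dependence (parameter rho).  The
mixing weight alpha interpolates between a completely nonlinear outcome
(alpha = 1) and a half-nonlinear / half-linear one (alpha = 0.5); only the p
true features ever enter the outcome, so every feature carries an exact
true/null label and a known causal direction feature -> Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CONTINUOUS, Dataset, VariableMeta

# How the AR parameter enters the feature law.  The default follows the
# single-index benchmark convention this generator emulates: (rho^|j-k|) is
# the feature *covariance* ("covariance_ar", the standard AR(1) design).
# The alternative reading, where (rho^|j-k|) is the precision and the
# covariance is its (tridiagonal) inverse, is available as "precision_ar".
COV_CONVENTIONS = ("covariance_ar", "precision_ar")


@dataclass(frozen=True)
class SimConfig:
    """Scenario description for a single synthetic dataset.

    amplitude=None means the default 1.5/sqrt(n_true), which keeps the scale
    of x' beta stable as the number of true features grows.
    """

    n_true: int
    n_null: int
    n_samples: int
    alpha_mix: float = 1.0
    rho: float = 0.5
    sigma: float = 1.0
    link: str = "cube"
    amplitude: float | None = None
    cov_convention: str = "covariance_ar"
    seed: int = 0

    def __post_init__(self):
        if self.n_true < 1:
            raise ValueError("need at least one true feature")
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in [0, 1]")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.link != "cube":
            raise ValueError("only the cube link is supported")
        if self.cov_convention not in COV_CONVENTIONS:
            raise ValueError(f"cov_convention must be one of {COV_CONVENTIONS}")
        if self.amplitude is not None and self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def effective_amplitude(self) -> float:
        return self.amplitude if self.amplitude is not None else 1.5 / np.sqrt(self.n_true)


@dataclass
class SimDataset:
    """A simulated dataset plus its ground truth.

    ``truth`` maps each feature name to "true_assoc" or "null"; the causal
    direction for every true feature is feature -> Y.
    """

    dataset: Dataset
    truth: dict[str, str]
    beta: np.ndarray
    gamma: np.ndarray
    config: SimConfig

    OUTCOME = "Y"

    @property
    def feature_names(self) -> list[str]:
        return [n for n in self.dataset.names if n != self.OUTCOME]

    @property
    def true_features(self) -> list[str]:
        return [n for n, lab in self.truth.items() if lab == "true_assoc"]

    @property
    def null_features(self) -> list[str]:
        return [n for n, lab in self.truth.items() if lab == "null"]

    @property
    def labels(self) -> dict[str, bool]:
        """feature -> True iff truly outcome-associated."""
        return {n: lab == "true_assoc" for n, lab in self.truth.items()}


def make_feature_covariance(p_plus_q: int, rho: float, convention: str = "covariance_ar") -> np.ndarray:
    """Feature covariance Sigma implied by the AR matrix (rho^|j-k|).

    convention="covariance_ar" (default): the AR matrix is the covariance
    itself.  convention="precision_ar": (rho^|j-k|) is the precision and
    Sigma is its inverse (a tridiagonal covariance).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if convention not in COV_CONVENTIONS:
        raise ValueError(f"convention must be one of {COV_CONVENTIONS}")
    idx = np.arange(p_plus_q)
    ar = rho ** np.abs(idx[:, None] - idx[None, :])
    if convention == "covariance_ar":
        sigma = ar
    else:
        sigma = np.linalg.inv(ar)
        sigma = (sigma + sigma.T) / 2.0
    # AR matrices with |rho| < 1 are positive definite, hence so is the inverse
    assert np.linalg.eigvalsh(sigma)[0] > 0
    return sigma


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one dataset from the single-index model; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    p, q, n = cfg.n_true, cfg.n_null, cfg.n_samples
    m = p + q
    sigma_feat = make_feature_covariance(m, cfg.rho, cfg.cov_convention)
    chol = np.linalg.cholesky(sigma_feat)

    amp = cfg.effective_amplitude
    beta = rng.choice([-1.0, 1.0], size=p) * amp
    gamma = rng.choice([-1.0, 1.0], size=p) * amp
    x = rng.standard_normal((n, m)) @ chol.T
    eps = rng.normal(0.0, cfg.sigma, size=n) if cfg.sigma > 0 else np.zeros(n)

    u = x[:, :p] @ beta
    y = cfg.alpha_mix * u**3 + (1.0 - cfg.alpha_mix) * (x[:, :p] @ gamma) + eps

    width = max(2, len(str(m)))
    names = [f"X{j + 1:0{width}d}" for j in range(p)] + [f"Z{j + 1:0{width}d}" for j in range(q)]
    truth = {nm: ("true_assoc" if j < p else "null") for j, nm in enumerate(names)}
    meta = [VariableMeta(nm, CONTINUOUS) for nm in names] + [VariableMeta(SimDataset.OUTCOME, CONTINUOUS)]
    values = np.column_stack([x, y])
    ds = Dataset(values, meta)
    return SimDataset(ds, truth, beta, gamma, cfg)
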