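"""Category probabilities and log-likelihood for the generalized ordered logit.

The latent severity propensity of crash i is η_i = β·x_i + φ_{m(i)} with a
standard-logistic residual; the lower threshold is fixed at 0 and the upper
threshold is μ2_i = exp(α·z_i), so

    p1 = logistic(−η),   p3 = logistic(η − μ2),   p2 = 1 − p1 − p3.

Setting φ = 0 recovers the non-spatial model exactly.  Linear predictors are
clipped at ±30 before exponentiation: the probabilities are saturated to
machine precision well inside that range, and the clip prevents overflow in
the exp(exp(·)) composition of the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_model import CrashDataset, CrashRecord

__all__ = [
    "LINPRED_CLIP",
    "PROB_FLOOR",
    "CoefficientSet",
    "CategoryProbabilities",
    "upper_threshold",
    "category_probs",
    "category_prob_matrix",
    "log_likelihood",
    "deviance",
]

logger = logging.getLogger(__name__)

LINPRED_CLIP = 30.0
PROB_FLOOR = 1e-300

# warn once per process: clipping/flooring is routine during burn-in
# exploration and would otherwise flood the log
_warned: set[str] = set()


def _warn_once(key: str, msg: str, *args) -> None:
    if key not in _warned:
        _warned.add(key)
        logger.warning(msg, *args)


@dataclass
class CoefficientSet:
    """β (propensity), α (threshold), φ (segment effects), and τφ.

    ``phi`` is all-zero for the non-spatial model; the logistic residual is
    never stored — it is integrated out analytically by the link.
    """

    beta: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tau_phi: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probabilities of the three severity levels for one crash."""

    p1: float
    p2: float
    p3: float

    @property
    def cumulative(self) -> tuple[float, float, float]:
        return (self.p1, self.p1 + self.p2, 1.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])


def _clip(lin: np.ndarray | float) -> np.ndarray | float:
    lin = np.asarray(lin, dtype=float)
    if np.any(np.abs(lin) > LINPRED_CLIP):
        _warn_once("clip", "linear predictor clipped at ±%.0f", LINPRED_CLIP)
        lin = np.clip(lin, -LINPRED_CLIP, LINPRED_CLIP)
    return lin


def upper_threshold(alpha: np.ndarray, z: np.ndarray) -> float | np.ndarray:
    """Upper threshold μ2 = exp(α·z); the lower threshold is identically 0."""
    lin = np.dot(np.asarray(z, dtype=float), np.asarray(alpha, dtype=float))
    return np.exp(_clip(lin))


def _probs_from_predictors(
    eta: np.ndarray, mu2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p1, p2, p3) from the clipped propensity η and threshold μ2."""
    p1 = expit(-eta)
    p3 = expit(eta - mu2)
    # complement form is algebraically identical to the product expression for
    # p2 but avoids exp(exp(.)) blow-up; clip shields the rare cancellation.
    p2 = np.clip(1.0 - p1 - p3, 0.0, 1.0)
    return p1, p2, p3


def _eta_for(coef: CoefficientSet, segment_1based: np.ndarray | int, xdot: np.ndarray):
    if coef.phi.size:
        return xdot + coef.phi[np.asarray(segment_1based) - 1]
    return xdot


def category_probs(coef: CoefficientSet, record: CrashRecord) -> CategoryProbabilities:
    """Severity-level probabilities for one crash under ``coef``."""
    x = np.asarray(record.x, dtype=float)
    z = np.asarray(record.z, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(z).all()):
        raise ValueError("non-finite covariates")
    eta = _clip(_eta_for(coef, record.segment, float(coef.beta @ x)))
    mu2 = upper_threshold(coef.alpha, z)
    p1, p2, p3 = _probs_from_predictors(np.asarray(eta), np.asarray(mu2))
    return CategoryProbabilities(p1=float(p1), p2=float(p2), p3=float(p3))


def category_prob_matrix(coef: CoefficientSet, data: CrashDataset) -> np.ndarray:
    """(n, 3) matrix of severity-level probabilities for a whole dataset."""
    eta = _clip(_eta_for(coef, data.segments, data.X @ coef.beta))
    mu2 = np.exp(_clip(data.Z @ coef.alpha))
    p1, p2, p3 = _probs_from_predictors(np.asarray(eta), mu2)
    return np.column_stack([p1, p2, p3])


def pointwise_log_prob(
    eta: np.ndarray, mu2: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """log p_{i, y_i} for pre-computed predictors; the sampler's hot path.

    ``eta`` must already be clipped; ``y`` holds levels in {1,2,3}.
    """
    p1, p2, p3 = _probs_from_predictors(eta, mu2)
    p_obs = np.where(y == 1, p1, np.where(y == 2, p2, p3))
    tiny = p_obs < PROB_FLOOR
    if np.any(tiny):
        _warn_once("floor", "probability underflow floored at %g", PROB_FLOOR)
        p_obs = np.maximum(p_obs, PROB_FLOOR)
    return np.log(p_obs)


def log_likelihood(coef: CoefficientSet, data: CrashDataset) -> float:
    """Σ_i log p_{i, y_i} over the dataset."""
    eta = _clip(_eta_for(coef, data.segments, data.X @ coef.beta))
    mu2 = np.exp(_clip(data.Z @ coef.alpha))
    return float(pointwise_log_prob(np.asarray(eta), mu2, data.y).sum())


def deviance(coef: CoefficientSet, data: CrashDataset) -> float:
    """−2 × log-likelihood."""
    return -2.0 * log_likelihood(coef, data)
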