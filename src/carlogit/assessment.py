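"""Model assessment: DIC, classification accuracy, and comparison.

DIC = D̄ + pD, where D̄ is the posterior mean deviance and pD = D̄ − D(θ̄)
is the effective number of parameters evaluated at the posterior means of
all sampled quantities (including the segment field).  Differences above 10
are treated as decisive evidence against the higher-DIC model; smaller gaps
are indeterminate.

Classification accuracy is the fraction of crashes whose modal
posterior-mean category probability matches the observed level, with ties
broken toward the less severe level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .data_model import CrashDataset
from .likelihood import LINPRED_CLIP, CoefficientSet, deviance as plugin_deviance
from .mcmc import PosteriorChain

__all__ = [
    "FitReport",
    "dic",
    "posterior_mean_probs",
    "predicted_levels",
    "classification_accuracy",
    "assess",
    "compare",
    "DECISIVE_DIC_GAP",
]

DECISIVE_DIC_GAP = 10.0


def data_fingerprint(data: CrashDataset) -> str:
    h = hashlib.sha1()
    h.update(data.y.tobytes())
    h.update(data.segments.tobytes())
    h.update(np.ascontiguousarray(data.X).tobytes())
    h.update(np.ascontiguousarray(data.Z).tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class FitReport:
    """Assessment summary for one fitted model on one dataset."""

    model: str
    d_bar: float
    p_d: float
    dic: float
    classification_accuracy: float
    predicted: np.ndarray
    fingerprint: str

    def __post_init__(self) -> None:
        if not np.isclose(self.dic, self.d_bar + self.p_d):
            raise ValueError("DIC must equal d_bar + p_d")
        if not 0.0 <= self.classification_accuracy <= 1.0:
            raise ValueError("classification accuracy must be in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "d_bar": self.d_bar,
            "p_d": self.p_d,
            "dic": self.dic,
            "classification_accuracy": self.classification_accuracy,
            "classification_accuracy_pct": round(100 * self.classification_accuracy),
            "fingerprint": self.fingerprint,
        }


def dic(chain: PosteriorChain, data: CrashDataset) -> tuple[float, float, float]:
    """(D̄, pD, DIC) with the plug-in deviance at posterior means."""
    d_bar = float(chain.deviance.mean())
    d_hat = plugin_deviance(chain.posterior_mean_coefficients(), data)
    p_d = d_bar - d_hat
    return d_bar, p_d, d_bar + p_d


def posterior_mean_probs(
    chain: PosteriorChain, data: CrashDataset, *, block: int = 512
) -> np.ndarray:
    """(n, 3) posterior means of the category probabilities.

    Averages the probabilities over retained draws in blocks to bound the
    transient memory at block × n floats.
    """
    from scipy.special import expit

    n = data.n_crashes
    acc = np.zeros((n, 3))
    S = chain.n_draws
    seg0 = data.segments - 1
    for start in range(0, S, block):
        b = slice(start, min(start + block, S))
        eta = chain.beta[b] @ data.X.T
        if chain.phi is not None:
            eta = eta + chain.phi[b][:, seg0]
        eta = np.clip(eta, -LINPRED_CLIP, LINPRED_CLIP)
        mu2 = np.exp(np.clip(chain.alpha[b] @ data.Z.T, -LINPRED_CLIP, LINPRED_CLIP))
        p1 = expit(-eta)
        p3 = expit(eta - mu2)
        acc[:, 0] += p1.sum(axis=0)
        acc[:, 2] += p3.sum(axis=0)
    acc[:, 0] /= S
    acc[:, 2] /= S
    acc[:, 1] = np.clip(1.0 - acc[:, 0] - acc[:, 2], 0.0, 1.0)
    return acc


def predicted_levels(probs: np.ndarray) -> np.ndarray:
    """Modal severity level per crash; ties resolve to the less severe level."""
    return np.argmax(probs, axis=1) + 1  # argmax returns the first maximum


def classification_accuracy(chain: PosteriorChain, data: CrashDataset) -> float:
    """Fraction of crashes whose predicted level equals the observed one."""
    probs = posterior_mean_probs(chain, data)
    pred = predicted_levels(probs)
    return float((pred == data.y).mean())


def assess(chain: PosteriorChain, data: CrashDataset) -> FitReport:
    """Full fit report: DIC decomposition plus classification accuracy."""
    d_bar, p_d, dic_val = dic(chain, data)
    probs = posterior_mean_probs(chain, data)
    pred = predicted_levels(probs)
    return FitReport(
        model=chain.model,
        d_bar=d_bar,
        p_d=p_d,
        dic=dic_val,
        classification_accuracy=float((pred == data.y).mean()),
        predicted=pred,
        fingerprint=data_fingerprint(data),
    )


def compare(fit_a: FitReport, fit_b: FitReport) -> dict:
    """ΔDIC/ΔCA verdict; decisive only when |ΔDIC| strictly exceeds 10."""
    if fit_a.fingerprint != fit_b.fingerprint:
        raise ValueError("fit reports come from different datasets")
    delta_dic = fit_a.dic - fit_b.dic
    decisive = abs(delta_dic) > DECISIVE_DIC_GAP
    if decisive:
        preferred = fit_a.model if delta_dic < 0 else fit_b.model
    else:
        preferred = None
    return {
        "delta_dic": delta_dic,
        "delta_ca": fit_a.classification_accuracy - fit_b.classification_accuracy,
        "verdict": "decisive" if decisive else "indeterminate",
        "preferred": preferred,
        "models": [fit_a.model, fit_b.model],
    }
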