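"""Average marginal effects of covariates on the severity-level probabilities.

For a continuous variable x with propensity coefficient βx and threshold
coefficient αx (zero when the variable is absent from that side), at a crash
with probabilities (p1, p2, p3) and upper threshold μ2:

    ∂p1/∂x = βx · p1(p1 − 1)
    ∂p3/∂x = (βx − αx·μ2) · p3(1 − p3)
    ∂p2/∂x = −∂p1/∂x − ∂p3/∂x        (probability conservation)

For an indicator, the effect is the difference in category probabilities with
the indicator switched 0 → 1, holding everything else fixed; for mutually
exclusive indicator sets the sibling indicators are held at zero in both
counterfactuals, so the contrast is "this level vs the reference level" and
no impossible covariate row is evaluated.

A variable entering only the threshold (βx = 0) cannot move p1: the light
category's boundary is pinned at zero, so its probability depends on the
propensity alone — such variables shift probability purely between the
medium and severe levels.

Per-crash effects are evaluated at plug-in coefficient values (typically
posterior means) and averaged over all crashes; summaries report percentage
points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import CrashDataset, CrashRecord
from .likelihood import LINPRED_CLIP, CoefficientSet

__all__ = [
    "MarginalEffectTriplet",
    "continuous_me",
    "binary_me",
    "average_me",
    "average_me_draws",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarginalEffectTriplet:
    """Effect of one variable on (p1, p2, p3); sums to zero by construction."""

    variable: str
    kind: Literal["continuous", "indicator"]
    scope: Literal["per-crash", "dataset-average"]
    d_p1: float
    d_p2: float
    d_p3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_p1, self.d_p2, self.d_p3])

    def as_percent(self) -> np.ndarray:
        return 100.0 * self.as_array()


def _side_indices(
    x_names: Sequence[str], z_names: Sequence[str], var: str
) -> tuple[int | None, int | None]:
    ix = list(x_names).index(var) if var in x_names else None
    iz = list(z_names).index(var) if var in z_names else None
    if ix is None and iz is None:
        raise ValueError(f"variable {var!r} is in neither covariate function")
    return ix, iz


def _predictors(
    coef: CoefficientSet, X: np.ndarray, Z: np.ndarray, seg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    eta = X @ coef.beta
    if coef.phi.size:
        eta = eta + coef.phi[seg - 1]
    eta = np.clip(eta, -LINPRED_CLIP, LINPRED_CLIP)
    mu2 = np.exp(np.clip(Z @ coef.alpha, -LINPRED_CLIP, LINPRED_CLIP))
    return eta, mu2


def _continuous_arrays(
    coef: CoefficientSet,
    X: np.ndarray,
    Z: np.ndarray,
    seg: np.ndarray,
    x_names: Sequence[str],
    z_names: Sequence[str],
    var: str,
) -> np.ndarray:
    ix, iz = _side_indices(x_names, z_names, var)
    bx = float(coef.beta[ix]) if ix is not None else 0.0
    ax = float(coef.alpha[iz]) if iz is not None else 0.0
    eta, mu2 = _predictors(coef, X, Z, seg)
    p1 = expit(-eta)
    p3 = expit(eta - mu2)
    d1 = bx * p1 * (p1 - 1.0)
    d3 = (bx - ax * mu2) * p3 * (1.0 - p3)
    return np.column_stack([d1, -d1 - d3, d3])


def _binary_arrays(
    coef: CoefficientSet,
    X: np.ndarray,
    Z: np.ndarray,
    seg: np.ndarray,
    x_names: Sequence[str],
    z_names: Sequence[str],
    var: str,
    siblings: Sequence[str] = (),
) -> np.ndarray:
    _side_indices(x_names, z_names, var)  # existence check
    def switched(value: float) -> tuple[np.ndarray, np.ndarray]:
        # siblings are zeroed in BOTH scenarios: the contrast is "this level
        # vs the reference level", so neither counterfactual row is an
        # impossible combination of exclusive indicators
        Xs, Zs = X.copy(), Z.copy()
        for side_names, mat in ((x_names, Xs), (z_names, Zs)):
            names = list(side_names)
            if var in names:
                mat[:, names.index(var)] = value
            for sib in siblings:
                if sib in names:
                    mat[:, names.index(sib)] = 0.0
        return Xs, Zs

    def probs(Xs: np.ndarray, Zs: np.ndarray) -> np.ndarray:
        eta, mu2 = _predictors(coef, Xs, Zs, seg)
        p1 = expit(-eta)
        p3 = expit(eta - mu2)
        return np.column_stack([p1, 1.0 - p1 - p3, p3])

    return probs(*switched(1.0)) - probs(*switched(0.0))


def continuous_me(
    coef: CoefficientSet,
    record: CrashRecord,
    var: str,
    *,
    x_names: Sequence[str],
    z_names: Sequence[str],
) -> MarginalEffectTriplet:
    """First-derivative effect of a continuous variable at one crash."""
    tri = _continuous_arrays(
        coef,
        record.x[None, :],
        record.z[None, :],
        np.array([record.segment]),
        x_names,
        z_names,
        var,
    )[0]
    return MarginalEffectTriplet(
        variable=var, kind="continuous", scope="per-crash",
        d_p1=float(tri[0]), d_p2=float(tri[1]), d_p3=float(tri[2]),
    )


def binary_me(
    coef: CoefficientSet,
    record: CrashRecord,
    var: str,
    *,
    x_names: Sequence[str],
    z_names: Sequence[str],
    siblings: Sequence[str] = (),
) -> MarginalEffectTriplet:
    """0 → 1 switch effect of an indicator at one crash.

    ``siblings`` lists mutually exclusive indicators zeroed in the
    switched-on counterfactual.
    """
    vals = []
    for names, vec in ((x_names, record.x), (z_names, record.z)):
        if var in names:
            vals.append(float(vec[list(names).index(var)]))
    if vals and any(v not in (0.0, 1.0) for v in vals):
        logger.warning(
            "variable %r is not binary at this crash; computed as a unit change", var
        )
    tri = _binary_arrays(
        coef,
        record.x[None, :],
        record.z[None, :],
        np.array([record.segment]),
        x_names,
        z_names,
        var,
        siblings,
    )[0]
    return MarginalEffectTriplet(
        variable=var, kind="indicator", scope="per-crash",
        d_p1=float(tri[0]), d_p2=float(tri[1]), d_p3=float(tri[2]),
    )


def average_me(
    coef: CoefficientSet,
    data: CrashDataset,
    variables: Mapping[str, Literal["continuous", "indicator"]],
    *,
    exclusive_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Dataset-average marginal effects, in percentage points.

    One row per variable with columns ``light``, ``medium``, ``severe``
    (the effect on p1, p2, p3 × 100), shaped like the conventional
    marginal-effect table of this literature.
    """
    exclusive_groups = exclusive_groups or {}
    sibling_map: dict[str, tuple[str, ...]] = {}
    for members in exclusive_groups.values():
        for v in members:
            sibling_map[v] = tuple(m for m in members if m != v)

    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            tri = _continuous_arrays(
                coef, data.X, data.Z, data.segments, data.x_names, data.z_names, var
            )
        elif kind == "indicator":
            tri = _binary_arrays(
                coef, data.X, data.Z, data.segments, data.x_names, data.z_names,
                var, sibling_map.get(var, ()),
            )
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        mean = 100.0 * tri.mean(axis=0)
        rows.append(
            {"variable": var, "kind": kind,
             "light": mean[0], "medium": mean[1], "severe": mean[2]}
        )
    return pd.DataFrame(rows).set_index("variable")


def average_me_draws(
    chain,
    data: CrashDataset,
    variables: Mapping[str, Literal["continuous", "indicator"]],
    *,
    exclusive_groups: Mapping[str, Sequence[str]] | None = None,
    max_draws: int = 500,
) -> pd.DataFrame:
    """Posterior-uncertainty version of :func:`average_me`.

    Evaluates the dataset-average triplet at (up to ``max_draws`` evenly
    thinned) posterior draws instead of the plug-in means, and reports the
    posterior mean and equal-tailed 95% interval of each effect, in
    percentage points.
    """
    S = chain.n_draws
    idx = np.linspace(0, S - 1, min(max_draws, S)).astype(int)
    stacks: dict[str, list[np.ndarray]] = {v: [] for v in variables}
    for s in idx:
        coef = CoefficientSet(
            beta=chain.beta[s],
            alpha=chain.alpha[s],
            phi=chain.phi[s] if chain.phi is not None else np.zeros(0),
        )
        table = average_me(coef, data, variables, exclusive_groups=exclusive_groups)
        for v in variables:
            stacks[v].append(table.loc[v, ["light", "medium", "severe"]].to_numpy(float))
    rows = []
    for v, kind in variables.items():
        draws = np.asarray(stacks[v])
        lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
        m = draws.mean(axis=0)
        rows.append(
            {"variable": v, "kind": kind,
             "light": m[0], "light_q2.5": lo[0], "light_q97.5": hi[0],
             "medium": m[1], "medium_q2.5": lo[1], "medium_q97.5": hi[1],
             "severe": m[2], "severe_q2.5": lo[2], "severe_q97.5": hi[2]}
        )
    return pd.DataFrame(rows).set_index("variable")
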