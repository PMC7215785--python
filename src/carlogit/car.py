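"""Intrinsic conditional autoregressive (CAR) prior over segment effects.

Each segment effect φ_m, conditional on the rest, is Gaussian with mean the
average of its neighbours' effects and precision τφ times the neighbour
count.  Jointly (up to an additive constant) the improper density is

    log p(φ | τφ) = (df/2)·log τφ − (τφ/2)·Σ_{edges (m,n)} (φ_m − φ_n)²

with df = Σ_components (size − 1): the field is flat along the per-component
constant direction, so identification pins each component's mean at zero
(and in the sampler the regression intercept absorbs the global level).
Degree-0 segments ("islands") have no defined conditional; their effect is
fixed at 0 and they contribute nothing to df.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import SegmentGraph

__all__ = ["IslandSegmentError", "CarField", "full_conditional", "log_density", "recenter"]


class IslandSegmentError(ValueError):
    """Raised when a conditional is requested for a degree-0 segment.

    The intrinsic CAR conditional is undefined without neighbours; island
    effects are pinned at 0 by policy (see module docstring).
    """


@dataclass(frozen=True)
class CarField:
    """A realisation φ of the segment field with its graph and precision."""

    phi: np.ndarray
    graph: SegmentGraph
    tau_phi: float

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (self.graph.n_segments,):
            raise ValueError("phi length must equal the number of segments")
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")
        object.__setattr__(self, "phi", phi)

    def pairwise_sum(self) -> float:
        """Σ over edges of (φ_m − φ_n)²."""
        e = self.graph.edge_array()
        if not e.size:
            return 0.0
        d = self.phi[e[:, 0]] - self.phi[e[:, 1]]
        return float(d @ d)


def full_conditional(field: CarField, m: int) -> tuple[float, float]:
    """Conditional mean and precision of φ_m given the rest (1-based ``m``).

    mean = neighbour average, precision = τφ × neighbour count.
    """
    nbrs = field.graph.neighbors(m)
    if not nbrs:
        raise IslandSegmentError(
            f"segment {m} has no neighbours; island effects are fixed at 0"
        )
    vals = field.phi[np.asarray(nbrs, dtype=np.intp) - 1]
    return float(vals.mean()), float(field.tau_phi * len(nbrs))


def log_density(field: CarField) -> float:
    """Joint log-density of φ up to an additive constant.

    (df/2)·log τφ − (τφ/2)·Σ_edges (φ_m − φ_n)²; df accounts for the rank
    deficiency of the intrinsic precision matrix τφ(D − W).
    """
    df = field.graph.df_prior
    return 0.5 * df * np.log(field.tau_phi) - 0.5 * field.tau_phi * field.pairwise_sum()


def recenter(field: CarField) -> CarField:
    """Subtract the per-component mean from φ; islands are reset to 0.

    Idempotent; when the intercept absorbs the removed level the data
    likelihood is unchanged.
    """
    phi = field.phi.copy()
    for comp in field.graph.components():
        phi[comp] -= phi[comp].mean()
    phi[field.graph.islands()] = 0.0
    return replace(field, phi=phi)
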