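"""Scikit-learn-style estimators for the generalized ordered logit models.

:class:`GeneralizedOrderedLogit` fits the non-spatial model;
:class:`SpatialGeneralizedOrderedLogit` adds intrinsic-CAR segment effects.
Both follow the sklearn estimator contract — constructor parameters mirror
attributes, ``fit(X, y)`` accepts a DataFrame of covariates and an ordinal
severity vector, fitted state lives in trailing-underscore attributes, and
``predict`` / ``predict_proba`` / ``score`` behave like any classifier over
the ordered levels {1, 2, 3} — so the models compose with sklearn pipelines
and model selection.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import assessment, mcmc
from .data_model import CrashDataset, SegmentGraph, chain_graph
from .likelihood import CoefficientSet
from .marginal_effects import average_me

__all__ = ["GeneralizedOrderedLogit", "SpatialGeneralizedOrderedLogit"]


class GeneralizedOrderedLogit(BaseEstimator, ClassifierMixin):
    """Bayesian generalized ordered logit with covariate-dependent threshold.

    The latent severity propensity is β·x with a standard-logistic residual;
    the lower category boundary is fixed at 0 and the upper boundary is
    exp(α·z), so covariates may widen or narrow the medium band.  Estimation
    is by adaptive Metropolis-within-Gibbs under diffuse priors.

    Parameters
    ----------
    propensity_cols, threshold_cols
        Column names of ``X`` entering the propensity (β) and threshold (α)
        functions.  A column may appear in both.  ``None`` uses every
        non-reserved column on both sides.
    n_iter, burn_in, thin, seed
        Chain protocol; the retained draws number (n_iter − burn_in)/thin.
    prior_coef_variance, prior_tau_shape, prior_tau_rate
        Diffuse-prior settings (the τ parameters are used by the spatial
        subclass only).
    adapt_window, target_accept
        Burn-in step-size adaptation.

    Attributes
    ----------
    chain_ : PosteriorChain
        Retained posterior draws with acceptance bookkeeping.
    summary_ : DataFrame
        Posterior means, SDs, MC errors and 90/95% credible intervals.
    coef_ : CoefficientSet
        Posterior-mean coefficients (plug-in values).
    classes_ : ndarray
        The ordered severity levels [1, 2, 3].
    """

    _model = "nonspatial"
    _reserved = ("severity", "segment")

    def __init__(
        self,
        propensity_cols: Sequence[str] | None = None,
        threshold_cols: Sequence[str] | None = None,
        *,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 1,
        seed: int = 0,
        prior_coef_variance: float = 1e4,
        prior_tau_shape: float = 0.01,
        prior_tau_rate: float = 0.01,
        adapt_window: int = 50,
        target_accept: float = 0.44,
    ) -> None:
        self.propensity_cols = propensity_cols
        self.threshold_cols = threshold_cols
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_coef_variance = prior_coef_variance
        self.prior_tau_shape = prior_tau_shape
        self.prior_tau_rate = prior_tau_rate
        self.adapt_window = adapt_window
        self.target_accept = target_accept

    # -- dataset assembly -------------------------------------------------
    def _graph_for(self, X: pd.DataFrame) -> SegmentGraph:
        # the non-spatial model carries a trivial single-segment graph
        return chain_graph(1)

    def _segments_for(self, X: pd.DataFrame) -> np.ndarray:
        return np.ones(len(X), dtype=np.intp)

    def _build_dataset(self, X: pd.DataFrame, y: np.ndarray | None) -> CrashDataset:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of named covariates")
        cols = [c for c in X.columns if c not in self._reserved]
        xcols = list(self.propensity_cols) if self.propensity_cols is not None else cols
        zcols = list(self.threshold_cols) if self.threshold_cols is not None else cols
        n = len(X)
        design_x = np.column_stack(
            [np.ones(n)] + [X[c].to_numpy(dtype=float) for c in xcols]
        )
        design_z = np.column_stack(
            [np.ones(n)] + [X[c].to_numpy(dtype=float) for c in zcols]
        )
        return CrashDataset(
            y=np.ones(n, dtype=np.intp) if y is None else np.asarray(y, dtype=np.intp),
            X=design_x,
            Z=design_z,
            segments=self._segments_for(X),
            x_names=("constant", *xcols),
            z_names=("constant", *zcols),
            graph=self._graph_for(X),
        )

    def _mcmc_config(self) -> mcmc.McmcConfig:
        return mcmc.McmcConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            prior_coef_variance=self.prior_coef_variance,
            prior_tau_shape=self.prior_tau_shape,
            prior_tau_rate=self.prior_tau_rate,
            adapt_window=self.adapt_window,
            target_accept=self.target_accept,
        )

    # -- sklearn surface --------------------------------------------------
    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "GeneralizedOrderedLogit":
        """Run the MCMC chain on (X, y) and store posterior state."""
        dataset = self._build_dataset(X, np.asarray(y))
        self.dataset_ = dataset
        self.chain_ = mcmc.fit(self._model, dataset, self._mcmc_config())
        self.summary_ = self.chain_.summary()
        self.coef_ = self.chain_.posterior_mean_coefficients()
        self.classes_ = np.array([1, 2, 3])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean category probabilities, shape (n, 3)."""
        check_is_fitted(self, "chain_")
        dataset = self._build_dataset(X, None)
        return assessment.posterior_mean_probs(self.chain_, dataset)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Modal severity level; ties resolve toward the less severe level."""
        return assessment.predicted_levels(self.predict_proba(X))

    def assess(self) -> assessment.FitReport:
        """DIC decomposition and classification accuracy on the fit data."""
        check_is_fitted(self, "chain_")
        return assessment.assess(self.chain_, self.dataset_)

    def marginal_effects(
        self,
        variables: Mapping[str, str],
        *,
        exclusive_groups: Mapping[str, Sequence[str]] | None = None,
    ) -> pd.DataFrame:
        """Dataset-average marginal effects at posterior-mean coefficients."""
        check_is_fitted(self, "chain_")
        return average_me(
            self.coef_, self.dataset_, variables, exclusive_groups=exclusive_groups
        )


class SpatialGeneralizedOrderedLogit(GeneralizedOrderedLogit):
    """Generalized ordered logit with intrinsic-CAR segment effects.

    Adds a segment-level random effect φ to the latent propensity, with the
    conditional-autoregressive prior over the supplied adjacency: each φ_m,
    given the rest, is Gaussian around the neighbour average with precision
    τφ × neighbour count.  ``X`` must carry a segment-index column.

    Parameters (beyond the base class)
    ----------------------------------
    graph
        A :class:`SegmentGraph`, or ``None`` to use a chain graph over
        ``1..max(segment)`` — the linear-corridor default.
    segment_col
        Name of the 1-based segment-index column in ``X``.

    Attributes
    ----------
    phi_ : ndarray
        Posterior-mean segment effects.
    sd_phi_ : float
        Posterior mean of the per-draw field SD, the spatial-correlation
        strength summary.
    """

    _model = "spatial"

    def __init__(
        self,
        propensity_cols: Sequence[str] | None = None,
        threshold_cols: Sequence[str] | None = None,
        *,
        graph: SegmentGraph | None = None,
        segment_col: str = "segment",
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 1,
        seed: int = 0,
        prior_coef_variance: float = 1e4,
        prior_tau_shape: float = 0.01,
        prior_tau_rate: float = 0.01,
        adapt_window: int = 50,
        target_accept: float = 0.44,
    ) -> None:
        super().__init__(
            propensity_cols,
            threshold_cols,
            n_iter=n_iter,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            prior_coef_variance=prior_coef_variance,
            prior_tau_shape=prior_tau_shape,
            prior_tau_rate=prior_tau_rate,
            adapt_window=adapt_window,
            target_accept=target_accept,
        )
        self.graph = graph
        self.segment_col = segment_col

    @property
    def _reserved(self) -> tuple[str, ...]:  # type: ignore[override]
        return ("severity", self.segment_col)

    def _graph_for(self, X: pd.DataFrame) -> SegmentGraph:
        if self.graph is not None:
            return self.graph
        if self.segment_col not in X.columns:
            raise ValueError(f"X lacks the segment column {self.segment_col!r}")
        return chain_graph(int(X[self.segment_col].max()))

    def _segments_for(self, X: pd.DataFrame) -> np.ndarray:
        if self.segment_col not in X.columns:
            raise ValueError(f"X lacks the segment column {self.segment_col!r}")
        return X[self.segment_col].to_numpy(dtype=np.intp)

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "SpatialGeneralizedOrderedLogit":
        super().fit(X, y)
        self.phi_ = self.chain_.phi.mean(axis=0)
        self.tau_phi_ = float(self.chain_.tau_phi.mean())
        self.sd_phi_ = float(self.chain_.sd_phi().mean())
        return self
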