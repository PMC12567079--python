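"""scikit-learn style front-ends over the tracking, RQA and model layers.

These wrappers expose the pipeline's fit/transform-shaped pieces with the
estimator protocol (``get_params``/``set_params``, trailing-underscore
fitted attributes), so they compose with sklearn pipelines and model
selection. They are thin: the science lives in :mod:`cartwheel.tracker`,
:mod:`cartwheel.rqa` and :mod:`cartwheel.glmm`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import rqa as _rqa
from .glmm import fit_gamma_glmm_arrays
from .tracker import TrackerConfig, track_frames

__all__ = ["ColorQuadrantTracker", "RecurrenceAnalysis", "GammaGLMM"]


class ColorQuadrantTracker(BaseEstimator, TransformerMixin):
    """Transformer: RGB frame stack -> edge-male vertical-position series."""

    def __init__(
        self,
        color_lo=(150, 0, 0),
        color_hi=(255, 100, 100),
        coverage_threshold=0.40,
        grid=None,
        target_fps=15.0,
        dance_direction="left",
        female_column=None,
        max_gap=3,
        fps=30.0,
    ):
        self.color_lo = color_lo
        self.color_hi = color_hi
        self.coverage_threshold = coverage_threshold
        self.grid = grid
        self.target_fps = target_fps
        self.dance_direction = dance_direction
        self.female_column = female_column
        self.max_gap = max_gap
        self.fps = fps

    def _config(self) -> TrackerConfig:
        return TrackerConfig(
            color_lo=tuple(self.color_lo),
            color_hi=tuple(self.color_hi),
            coverage_threshold=self.coverage_threshold,
            grid=self.grid,
            target_fps=self.target_fps,
            dance_direction=self.dance_direction,
            female_column=self.female_column,
            max_gap=self.max_gap,
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        """Track a (T, H, W, 3) frame stack; returns the y series (px)."""
        series = track_frames(X, self._config(), fps=self.fps)
        self.series_ = series
        return series.y


class RecurrenceAnalysis(BaseEstimator, TransformerMixin):
    """Transformer: 1-D series -> the five consistency metrics.

    ``fit`` selects the entropy-maximizing radius (``radius_``,
    ``entropy_curve_``); ``transform`` returns
    ``[rr, det, lam, mcentr, radius]`` for the series.
    """

    def __init__(self, radius=None, q=2, n_samples=10_000, seed=0):
        self.radius = radius
        self.q = q
        self.n_samples = n_samples
        self.seed = seed

    def fit(self, X, y=None):
        yv = np.asarray(X, dtype=float).ravel()
        if self.radius is None:
            self.radius_, self.entropy_curve_ = _rqa.select_radius(
                yv, q=self.q, n_samples=self.n_samples, rng=self.seed
            )
        else:
            self.radius_ = float(self.radius)
            self.entropy_curve_ = None
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "radius_"):
            raise RuntimeError("call fit before transform")
        yv = np.asarray(X, dtype=float).ravel()
        m = _rqa.rqa_summary(
            yv, radius=self.radius_, q=self.q, n_samples=self.n_samples, seed=self.seed
        )
        self.metrics_ = m
        return np.array([m.rr, m.det, m.lam, m.mcentr, m.radius])


class GammaGLMM(BaseEstimator, RegressorMixin):
    """Regressor: Gamma log-link mixed model with a random intercept.

    ``fit(X, y, groups=...)`` exposes ``coef_``, ``intercept_``, ``se_``,
    ``wald_chi2_``, ``pvalues_``, ``ranef_var_`` and ``converged_``;
    ``predict`` returns the population-level mean response.
    """

    def __init__(self, standardize=False):
        self.standardize = standardize

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if groups is None:
            groups = np.zeros(y.size, dtype=int)
        if self.standardize:
            self._mean = X.mean(axis=0)
            self._sd = X.std(axis=0, ddof=0)
            if np.any(self._sd == 0):
                raise ValueError("cannot standardize a constant predictor")
            X = (X - self._mean) / self._sd
        else:
            self._mean = np.zeros(X.shape[1])
            self._sd = np.ones(X.shape[1])
        design = np.column_stack([np.ones(len(X)), X])
        fit = fit_gamma_glmm_arrays(y, design, np.asarray(groups))
        self.result_ = fit
        self.intercept_ = float(fit.coef[0])
        self.coef_ = fit.coef[1:]
        self.se_ = fit.se[1:]
        self.wald_chi2_ = fit.wald_chi2[1:]
        self.pvalues_ = fit.pvalues[1:]
        self.ranef_var_ = fit.ranef_var
        self.shape_ = fit.shape
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("call fit before predict")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = (X - self._mean) / self._sd
        return np.exp(self.intercept_ + Xs @ self.coef_)
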