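"""Scikit-learn-style estimator facade over counting and training.

`CryptCounter` packages the per-day crypt classifier as a fit/predict
estimator: `predict` counts crypts on boundaries with the current
parameters, and `fit` re-trains those parameters against manual reference
counts by simulated annealing. It plays by the scikit-learn rules
(`get_params`/`set_params`, fitted attributes with a trailing underscore,
clone-compatible constructor), so it composes with model-selection helpers
even though its "X" is a list of boundary polygons rather than a matrix.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .boundary_io import BoundaryPolygon
from .crypt_counting import CountResult, CryptParameters, count_crypts
from .training import (
    AnnealingSchedule,
    OptimizationResult,
    ParameterBounds,
    TrainingExample,
    evaluate_objective,
    train_parameters,
)

__all__ = ["CryptCounter"]


class CryptCounter(BaseEstimator):
    """Count crypt-like buds on closed organoid boundaries.

    Parameters
    ----------
    harmonics : float
        Elliptic-Fourier harmonic count (rounded when applied). More
        harmonics keep smaller boundary features.
    min_area_norm, max_area_norm : float
        Accepted window for candidate area / total organoid area.
    min_arclen_norm : float
        Minimum candidate arc length / total boundary length.
    kappa_tol : float
        Concavity threshold; samples with curvature < -kappa_tol count as
        concave. 0 by default (Fourier truncation already removes noise).
    n_iter, random_state, bounds_* : annealing controls used by :meth:`fit`.

    Attributes (after :meth:`fit`)
    ------------------------------
    harmonics_, min_area_norm_, max_area_norm_, min_arclen_norm_ : float
        Trained parameter values.
    objective_ : float
        Mean percentage error of the trained parameters on the fit data.
    result_ : OptimizationResult
        Full annealing outcome including the iteration trace.

    Examples
    --------
    >>> from cryptmorph import CryptCounter, make_lobed_boundary, LobedShapeSpec
    >>> poly, k = make_lobed_boundary(LobedShapeSpec(k=4))
    >>> CryptCounter(harmonics=12, min_area_norm=0.05, max_area_norm=0.6,
    ...              min_arclen_norm=0.02).predict([poly])
    array([4])
    """

    def __init__(
        self,
        harmonics: float = 15.0,
        min_area_norm: float = 0.01,
        max_area_norm: float = 0.3,
        min_arclen_norm: float = 0.03,
        kappa_tol: float = 0.0,
        n_iter: int = 300,
        random_state: int = 0,
        bounds_harmonics: tuple[float, float] = (3.0, 40.0),
        bounds_area: tuple[float, float] = (0.001, 0.6),
        bounds_arclen: tuple[float, float] = (0.0, 0.3),
    ) -> None:
        self.harmonics = harmonics
        self.min_area_norm = min_area_norm
        self.max_area_norm = max_area_norm
        self.min_arclen_norm = min_arclen_norm
        self.kappa_tol = kappa_tol
        self.n_iter = n_iter
        self.random_state = random_state
        self.bounds_harmonics = bounds_harmonics
        self.bounds_area = bounds_area
        self.bounds_arclen = bounds_arclen

    # ------------------------------------------------------------------
    def _current_parameters(self) -> CryptParameters:
        """Trained parameters if fitted, else the constructor values."""
        if hasattr(self, "harmonics_"):
            return CryptParameters(
                harmonics=self.harmonics_,
                min_area_norm=self.min_area_norm_,
                max_area_norm=self.max_area_norm_,
                min_arclen_norm=self.min_arclen_norm_,
            )
        return CryptParameters(
            harmonics=self.harmonics,
            min_area_norm=self.min_area_norm,
            max_area_norm=self.max_area_norm,
            min_arclen_norm=self.min_arclen_norm,
        )

    @classmethod
    def from_parameters(cls, params: CryptParameters, **kwargs) -> "CryptCounter":
        return cls(
            harmonics=params.harmonics,
            min_area_norm=params.min_area_norm,
            max_area_norm=params.max_area_norm,
            min_arclen_norm=params.min_arclen_norm,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        X: Sequence[BoundaryPolygon],
        y: Sequence[int],
        day_label: str = "",
        schedule: AnnealingSchedule | None = None,
    ) -> "CryptCounter":
        """Train the classifier thresholds against manual counts ``y``."""
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        examples = [
            TrainingExample(boundary=b, hand_count=int(c), day_label=day_label)
            for b, c in zip(X, y)
        ]
        result: OptimizationResult = train_parameters(
            examples,
            bounds=ParameterBounds(
                harmonics=self.bounds_harmonics,
                area=self.bounds_area,
                arclen=self.bounds_arclen,
            ),
            seed=self.random_state,
            schedule=schedule or AnnealingSchedule(n_iter=self.n_iter),
            initial=CryptParameters(
                harmonics=self.harmonics,
                min_area_norm=self.min_area_norm,
                max_area_norm=self.max_area_norm,
                min_arclen_norm=self.min_arclen_norm,
            ),
        )
        self.harmonics_ = result.params.harmonics
        self.min_area_norm_ = result.params.min_area_norm
        self.max_area_norm_ = result.params.max_area_norm
        self.min_arclen_norm_ = result.params.min_arclen_norm
        self.objective_ = result.mean_error_pct
        self.result_ = result
        return self

    def predict(self, X: Sequence[BoundaryPolygon]) -> np.ndarray:
        """Crypt counts for each boundary in ``X``."""
        params = self._current_parameters()
        return np.array(
            [
                count_crypts(b, params, kappa_tol=self.kappa_tol).crypt_count
                for b in X
            ],
            dtype=int,
        )

    def count(self, X: Sequence[BoundaryPolygon], ids: Sequence[str] | None = None
              ) -> list[CountResult]:
        """Full :class:`CountResult` per boundary (counts + candidates)."""
        params = self._current_parameters()
        ids = ids if ids is not None else [f"organoid_{i}" for i in range(len(X))]
        return [
            count_crypts(b, params, organoid_id=i, kappa_tol=self.kappa_tol)
            for b, i in zip(X, ids)
        ]

    def score(self, X: Sequence[BoundaryPolygon], y: Sequence[int]) -> float:
        """Negative mean percentage error (greater is better)."""
        examples = [
            TrainingExample(boundary=b, hand_count=int(c)) for b, c in zip(X, y)
        ]
        return -evaluate_objective(self._current_parameters(), examples)
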