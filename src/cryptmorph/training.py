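"""Classifier training: percentage-error objective + simulated annealing.

The crypt classifier has four parameters (harmonics, area window, arc-length
floor). They are fitted per culture day against manual reference counts by
minimising the mean percentage error

    %error = |hand_count - code_count| / hand_count * 100

averaged over the training organoids. The objective is piecewise constant
(counts are integers) with many flat plateaus and local minima, which rules
out gradient methods; a simulated-annealing search with bounded Gaussian
proposals explores globally and keeps the best parameters ever visited.

The harmonic count is treated as a continuous variable during the search
and rounded to the nearest integer inside every evaluation — averaging
optimisation runs can therefore report fractional harmonics even though
each evaluation uses an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary_io import BoundaryPolygon
from .crypt_counting import CryptParameters, count_crypts

__all__ = [
    "TrainingExample",
    "OptimizationResult",
    "ParameterBounds",
    "AnnealingSchedule",
    "percent_error",
    "evaluate_objective",
    "train_parameters",
]


@dataclass(frozen=True)
class TrainingExample:
    """One boundary with a manual reference crypt count."""

    boundary: BoundaryPolygon
    hand_count: int
    day_label: str = ""

    def __post_init__(self) -> None:
        if self.hand_count < 1:
            raise ValueError(
                "hand_count must be >= 1 (the percentage error divides by it)"
            )


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter search ranges for the annealer.

    The defaults loosely bracket the regimes that day-wise training visits:
    a broad harmonic band, normalised areas up to 0.6, arc-length floors up
    to 0.3.
    """

    harmonics: tuple[float, float] = (3.0, 40.0)
    area: tuple[float, float] = (0.001, 0.6)
    arclen: tuple[float, float] = (0.0, 0.3)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("harmonics", self.harmonics),
            ("area", self.area),
            ("arclen", self.arclen),
        ):
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
                raise ValueError(f"infeasible {name} bounds: ({lo}, {hi})")

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.harmonics[0], self.area[0], self.area[0], self.arclen[0]])

    @property
    def highs(self) -> np.ndarray:
        return np.array([self.harmonics[1], self.area[1], self.area[1], self.arclen[1]])


@dataclass(frozen=True)
class AnnealingSchedule:
    """Annealing controls.

    ``n_iter`` proposal steps with geometric cooling from an initial
    temperature set to the objective spread over ``initial_probes`` random
    probes, down to ``final_temp_frac`` of it after ``cooling_horizon``
    steps; Gaussian proposals with standard deviation ``step_frac`` of each
    parameter's bound range, clipped to the bounds. The per-step cooling
    factor depends on the horizon, not on ``n_iter``, so a longer budget
    extends the shorter run's trajectory and can never end on a worse
    best-seen objective.
    """

    n_iter: int = 300
    initial_probes: int = 20
    final_temp_frac: float = 1e-3
    cooling_horizon: int = 300
    step_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.initial_probes < 2 or self.cooling_horizon < 1:
            raise ValueError(
                "need n_iter >= 1, initial_probes >= 2 and cooling_horizon >= 1"
            )


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one annealing run."""

    params: CryptParameters
    mean_error_pct: float
    trace: list[tuple[CryptParameters, float]]
    seed: int

    def trace_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": i,
                "harmonics": p.harmonics,
                "min_area_norm": p.min_area_norm,
                "max_area_norm": p.max_area_norm,
                "min_arclen_norm": p.min_arclen_norm,
                "objective": obj,
            }
            for i, (p, obj) in enumerate(self.trace)
        ]
        return pd.DataFrame(rows)


def percent_error(hand: int, code: int) -> float:
    """Percentage deviation of a code count from a manual reference count."""
    if hand < 1:
        raise ValueError("percentage error undefined for hand count < 1")
    return abs(hand - code) / hand * 100.0


def evaluate_objective(
    params: CryptParameters, training_set: list[TrainingExample]
) -> float:
    """Mean percentage error of ``params`` over a (single-day) training set."""
    if not training_set:
        raise ValueError("empty training set")
    days = {ex.day_label for ex in training_set}
    if len(days) > 1:
        raise ValueError(f"training set mixes day labels: {sorted(days)}")
    errs = [
        percent_error(ex.hand_count, count_crypts(ex.boundary, params).crypt_count)
        for ex in training_set
    ]
    return float(np.mean(errs))


def _vector_to_params(x: np.ndarray, day_label: str) -> CryptParameters | None:
    """Decode a search vector; None when the area ordering is violated."""
    h, amin, amax, smin = x
    if amin >= amax:
        return None
    try:
        return CryptParameters(
            harmonics=float(h),
            min_area_norm=float(amin),
            max_area_norm=float(amax),
            min_arclen_norm=float(smin),
            day_label=day_label,
        )
    except ValueError:
        return None


def train_parameters(
    training_set: list[TrainingExample],
    bounds: ParameterBounds | None = None,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
    initial: CryptParameters | None = None,
) -> OptimizationResult:
    """Fit crypt-classifier parameters by simulated annealing.

    The search walks the 4-vector (harmonics, min_area, max_area,
    min_arclen) inside ``bounds``: Gaussian proposals scaled to 10% of each
    bound range (clipped), Metropolis acceptance at a geometrically cooled
    temperature, and the best-seen parameters returned — so the result is
    never worse than the initial point. Fully deterministic for a given
    seed, schedule and training set.
    """
    if not training_set:
        raise ValueError("empty training set")
    bounds = bounds or ParameterBounds()
    schedule = schedule or AnnealingSchedule()
    day = training_set[0].day_label
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lows, bounds.highs
    span = hi - lo

    def objective(x: np.ndarray) -> float:
        p = _vector_to_params(x, day)
        if p is None:
            return float("inf")
        return evaluate_objective(p, training_set)

    if initial is not None:
        x0 = np.array(
            [
                initial.harmonics,
                initial.min_area_norm,
                initial.max_area_norm,
                initial.min_arclen_norm,
            ]
        )
        x0 = np.clip(x0, lo, hi)
    else:
        x0 = lo + span * np.array([0.5, 0.15, 0.7, 0.25])

    # initial temperature: objective spread over random probes of the box
    probe_vals = []
    for _ in range(schedule.initial_probes):
        xp = lo + span * rng.random(4)
        v = objective(xp)
        if math.isfinite(v):
            probe_vals.append(v)
    t0 = max(float(np.std(probe_vals)) if probe_vals else 1.0, 1.0)
    alpha = schedule.final_temp_frac ** (1.0 / schedule.cooling_horizon)

    x_cur = x0.copy()
    f_cur = objective(x_cur)
    x_best, f_best = x_cur.copy(), f_cur
    trace: list[tuple[CryptParameters, float]] = []
    p_cur = _vector_to_params(x_cur, day)
    if p_cur is not None:
        trace.append((p_cur, f_cur))

    temp = t0
    for _ in range(schedule.n_iter):
        x_new = np.clip(x_cur + rng.normal(0.0, schedule.step_frac * span), lo, hi)
        f_new = objective(x_new)
        delta = f_new - f_cur
        if delta <= 0 or (
            math.isfinite(f_new) and rng.random() < math.exp(-delta / temp)
        ):
            x_cur, f_cur = x_new, f_new
        if f_cur < f_best:
            x_best, f_best = x_cur.copy(), f_cur
        p_iter = _vector_to_params(x_cur, day)
        if p_iter is not None:
            trace.append((p_iter, f_cur))
        temp *= alpha
        if f_best == 0.0:
            break

    best = _vector_to_params(x_best, day)
    if best is None:  # initial point infeasible and nothing better found
        raise ValueError("annealing found no feasible parameter vector")
    return OptimizationResult(
        params=best, mean_error_pct=float(f_best), trace=trace, seed=seed
    )
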