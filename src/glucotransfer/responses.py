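"""Deterministic forward model for postprandial glucose.

Each treatment (a meal of ``x`` grams carbohydrate, an exercise bout of
``z`` kcal) produces a bell-shaped glucose response

    h * exp(-0.5 * (delta - 3*alpha)**2 / alpha**2),   delta = t - tau >= 0,

with amplitude ``h = beta * dose`` and peak at ``delta = 3*alpha``, so
``alpha`` sets the response speed and ``beta`` the strength per unit dose.
Responses are causal (zero before the event) and superpose across events.
Three predictors are built from these responses on top of a constant
baseline (the median of the preprandial history):

* ``single``       y = y_base + R_d
* ``additive``     y = y_base + R_d + R_e
* ``synergistic``  y = y_base + R_d + R_e + C * (R_d ∘ R_e)

where ``∘`` is the elementwise product and ``C`` weights the diet-exercise
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .segments import Segment

MODEL_KINDS = ("single", "additive", "synergistic")


@dataclass
class PersonParams:
    """Person-specific response parameters.

    alpha_d : dietary response speed, minutes (> 0); peak at 3*alpha_d.
    beta_d  : dietary strength, mmol/L per gram carbohydrate.
    alpha_e : exercise response speed, minutes (> 0); None for single model.
    beta_e  : exercise strength, mmol/L per kcal (posterior expected <= 0).
    c_syn   : synergy weight C (dimensionless); None below synergistic.
    sigma   : observation noise SD, mmol/L.
    """

    alpha_d: float
    beta_d: float
    alpha_e: Optional[float] = None
    beta_e: Optional[float] = None
    c_syn: Optional[float] = None
    sigma: float = 0.4

    def __post_init__(self):
        if self.alpha_d <= 0:
            raise ValueError("alpha_d must be positive")
        if self.alpha_e is not None and self.alpha_e <= 0:
            raise ValueError("alpha_e must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class PredictedTrajectory:
    """Noise-free predicted glucose with its additive decomposition."""

    times: np.ndarray
    y_hat: np.ndarray
    y_base: float
    r_d: np.ndarray
    r_e: np.ndarray
    synergy: np.ndarray
    model_kind: str = "synergistic"

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "y_hat": self.y_hat.tolist(),
            "y_base": self.y_base,
            "r_d": self.r_d.tolist(),
            "r_e": self.r_e.tolist(),
            "synergy": self.synergy.tolist(),
            "model_kind": self.model_kind,
        }


def baseline_glucose(segment: Segment) -> float:
    """Median of the preprandial glucose history (held constant over the window)."""
    if segment.pre_glucose.size == 0:
        raise ValueError("segment has no preprandial samples")
    return float(np.median(segment.pre_glucose))


def bell_response(alpha: float,
                  amplitudes: Sequence[float],
                  event_times: Sequence[float],
                  grid: np.ndarray) -> np.ndarray:
    """Superposed causal bell responses evaluated on ``grid``.

    Each event i contributes ``amplitudes[i] * exp(-0.5*(d-3a)^2/a^2)`` for
    ``d = t - event_times[i] >= 0`` and nothing before its onset.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    amplitudes = np.asarray(amplitudes, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    if amplitudes.shape != event_times.shape:
        raise ValueError("amplitudes and event_times must have equal length")
    grid = np.asarray(grid, dtype=float)
    if amplitudes.size == 0:
        return np.zeros_like(grid)
    delta = grid[None, :] - event_times[:, None]
    bell = np.exp(-0.5 * ((delta - 3.0 * alpha) / alpha) ** 2)
    bell[delta < 0] = 0.0
    return amplitudes @ bell


def dietary_response(params: PersonParams, segment: Segment,
                     grid: np.ndarray | None = None) -> np.ndarray:
    """R_d over the postprandial grid: amplitude beta_d * carbs per meal in window."""
    if grid is None:
        grid = segment.post_times
    meals = segment.meals_in_window
    return bell_response(params.alpha_d,
                         [params.beta_d * m.carbs for m in meals],
                         [m.time for m in meals], grid)


def exercise_response(params: PersonParams, segment: Segment,
                      grid: np.ndarray | None = None) -> np.ndarray:
    """R_e over the postprandial grid: amplitude beta_e * kcal per bout in window."""
    if grid is None:
        grid = segment.post_times
    if params.alpha_e is None or params.beta_e is None:
        raise ValueError("exercise response requires alpha_e and beta_e")
    ex = segment.exercises_in_window
    return bell_response(params.alpha_e,
                         [params.beta_e * e.ee for e in ex],
                         [e.time for e in ex], grid)


def predict(model_kind: str, params: PersonParams, segment: Segment,
            grid: np.ndarray | None = None) -> PredictedTrajectory:
    """Noise-free mean glucose trajectory for one segment.

    The grid defaults to the segment's 18 postprandial CGM timestamps; a
    dense grid may be supplied for plotting and diagnostics.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    if grid is None:
        grid = segment.post_times
    grid = np.asarray(grid)
    y_base = baseline_glucose(segment)
    r_d = dietary_response(params, segment, grid)
    r_e = np.zeros_like(r_d)
    synergy = np.zeros_like(r_d)
    if model_kind in ("additive", "synergistic"):
        r_e = exercise_response(params, segment, grid)
    if model_kind == "synergistic":
        if params.c_syn is None:
            raise ValueError("synergistic model requires c_syn")
        synergy = params.c_syn * r_d * r_e
    y_hat = y_base + r_d + r_e + synergy
    return PredictedTrajectory(times=grid, y_hat=y_hat, y_base=y_base,
                               r_d=r_d, r_e=r_e, synergy=synergy,
                               model_kind=model_kind)
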