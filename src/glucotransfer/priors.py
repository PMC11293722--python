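"""Prior specifications for the hierarchical model.

The diet block is the same in every configuration: wide proper uniform
hyperpriors on the group means and *fixed* person-level SDs (10 min for
alpha_d, 0.1 mmol/L/g for beta_d).  The exercise block — group means of
(alpha_e, beta_e[, C]) — is where transfer learning acts, so its prior has
three modes:

* ``flat``      wide proper uniforms (source task / no transfer),
* ``gaussian``  independent normals, typically the moment-matched source
                posterior (normal transfer, eta = lambda = 1),
* ``extended``  the gaussian prior with latent shift eta and shrink lambda:
                Theta_e ~ N(eta ∘ mu_S, lambda * Sigma_S) with Gaussian
                hyperpriors on eta (mean 0.5 for the beta_e component, 1
                elsewhere) and lambda (mean 0.1, truncated positive).

Person-level SDs of the exercise block are learned with half-normal(1)
hyperpriors in every mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# exercise-block component order used throughout
EXERCISE_COMPONENTS = ("alpha_e", "beta_e", "c_syn")

# wide proper uniform bounds (engineering choices, overridable)
DIET_ALPHA_BOUNDS = (0.5, 60.0)     # peak between 1.5 and 180 min
DIET_BETA_BOUNDS = (0.0, 1.0)       # mmol/L per gram
FLAT_EXERCISE_BOUNDS = ((0.5, 60.0), (-1.0, 1.0), (-5.0, 5.0))

# fixed person-level SDs for the diet block
DIET_PERSON_SD = (10.0, 0.1)

# default hyperprior locations/scales for the extension parameters
ETA_MEANS = {"alpha_e": 1.0, "beta_e": 0.5, "c_syn": 1.0}
ETA_SD = 0.25
LAMBDA_MEAN = 0.1
LAMBDA_SD = 0.05


def exercise_block_size(model_kind: str) -> int:
    return {"single": 0, "additive": 2, "synergistic": 3}[model_kind]


@dataclass
class ExerciseBlockPrior:
    """Prior over the exercise-block group means (alpha_e, beta_e[, C])."""

    mode: str = "flat"                       # flat | gaussian | extended
    mu: Optional[np.ndarray] = None          # gaussian/extended location
    var: Optional[np.ndarray] = None         # gaussian/extended variances
    bounds: tuple = FLAT_EXERCISE_BOUNDS     # flat-mode bounds
    eta_mean: Optional[np.ndarray] = None    # extended-mode shift hyperprior
    eta_sd: float = ETA_SD
    lam_mean: float = LAMBDA_MEAN
    lam_sd: float = LAMBDA_SD

    def __post_init__(self):
        if self.mode not in ("flat", "gaussian", "extended"):
            raise ValueError(f"unknown exercise prior mode {self.mode!r}")
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=float)
        if self.var is not None:
            self.var = np.asarray(self.var, dtype=float)
            if np.any(self.var <= 0):
                raise ValueError("prior variances must be positive")
        if self.eta_mean is not None:
            self.eta_mean = np.asarray(self.eta_mean, dtype=float)
        if self.mode in ("gaussian", "extended"):
            if self.mu is None or self.var is None:
                raise ValueError(f"{self.mode} prior requires mu and var")
            if self.mu.shape != self.var.shape:
                raise ValueError("mu and var must have matching shapes")
        if self.mode == "extended" and self.eta_mean is None:
            k = len(self.mu)
            self.eta_mean = np.array(
                [ETA_MEANS[c] for c in EXERCISE_COMPONENTS[:k]])

    @property
    def n_components(self) -> Optional[int]:
        if self.mu is not None:
            return len(self.mu)
        return None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mu": None if self.mu is None else self.mu.tolist(),
            "var": None if self.var is None else self.var.tolist(),
            "bounds": [list(b) for b in self.bounds],
            "eta_mean": None if self.eta_mean is None else self.eta_mean.tolist(),
            "eta_sd": self.eta_sd,
            "lam_mean": self.lam_mean,
            "lam_sd": self.lam_sd,
        }


@dataclass
class PriorSpec:
    """Complete prior specification for one hierarchical fit."""

    exercise: ExerciseBlockPrior = field(default_factory=ExerciseBlockPrior)
    diet_alpha_bounds: tuple = DIET_ALPHA_BOUNDS
    diet_beta_bounds: tuple = DIET_BETA_BOUNDS
    diet_person_sd: tuple = DIET_PERSON_SD
    exercise_sd_scale: float = 1.0   # half-normal scale of learned person SDs
    sigma_scale: float = 2.0         # half-normal scale of the noise SD

    @classmethod
    def flat(cls) -> "PriorSpec":
        """Uninformative configuration: source task, or target without transfer."""
        return cls()

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise.to_dict(),
            "diet_alpha_bounds": list(self.diet_alpha_bounds),
            "diet_beta_bounds": list(self.diet_beta_bounds),
            "diet_person_sd": list(self.diet_person_sd),
            "exercise_sd_scale": self.exercise_sd_scale,
            "sigma_scale": self.sigma_scale,
        }
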