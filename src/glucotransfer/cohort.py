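"""Seeded synthetic cohorts: a balanced healthy-group RCT and an imbalanced
free-living patient cohort.

The generator draws person-specific response parameters from group-level
Gaussians and simulates CGM traces on the 5-minute grid as a per-segment
baseline plus the model's bell-shaped responses plus i.i.d. Gaussian noise,
so every inference stage can be exercised and checked against known truths
without any external data.

The RCT protocol: 4 healthy subjects, one 6-day session each, one target
meal per day with near-constant carbohydrate, and a randomized-order walk
condition — none (low), 100 steps/min (moderate) or 130 steps/min (high)
for 20 minutes starting 30 minutes after the meal.  Day pairs (1,4)/(2,5)/
(3,6) carry the low/moderate/high conditions.  Free-living patient
sessions run 3 days with several meals per day; postprandial exercise
occurs in only a small fraction of segments and is mostly of low energy
expenditure, reproducing the imbalance that motivates transfer learning.
The patient group's mean exercise strength defaults to half the healthy
group's, the physiological attenuation the transfer prior is built around.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .responses import PersonParams, MODEL_KINDS
from .segments import (Session, MealEvent, ExerciseEvent, GRID_MIN,
                       MINUTES_PER_DAY, PRE_WINDOW_MIN)

#: physiological attenuation of the exercise effect in the diabetic group
PATIENT_EXERCISE_ATTENUATION = 0.5

#: energy expenditure mapped onto the RCT walk conditions (kcal per 20-min walk)
RCT_EE = {"low": 0.0, "moderate": 80.0, "high": 130.0}
RCT_DAY_CONDITION = {1: "low", 2: "moderate", 3: "high",
                     4: "low", 5: "moderate", 6: "high"}
RCT_WALK_OFFSET_MIN = 30
RCT_WALK_DURATION_MIN = 20

# healthy-group true parameters: peaks of 2-4 mmol/L for 50-80 g meals,
# drops of 1.6-2.6 mmol/L for the 80-130 kcal RCT walks (stronger exercise
# effects push simulated glucose below zero)
HEALTHY_MEANS = {"alpha_d": 12.0, "beta_d": 0.04, "alpha_e": 10.0,
                 "beta_e": -0.02, "c_syn": 0.2}
BETWEEN_PERSON_SD = {"alpha_d": 2.0, "beta_d": 0.008, "alpha_e": 1.5,
                     "beta_e": 0.004, "c_syn": 0.05}


@dataclass
class RctCondition:
    """One randomized postprandial-exercise condition of the RCT."""

    label: str                      # low | moderate | high
    walk_pace: int                  # steps/min (0 for low)
    walk_duration: int = RCT_WALK_DURATION_MIN
    walk_offset: int = RCT_WALK_OFFSET_MIN
    ee_kcal: float = 0.0

    def __post_init__(self):
        if self.label == "low" and self.ee_kcal != 0.0:
            raise ValueError("low condition has no exercise")
        if self.label in ("moderate", "high") and self.ee_kcal <= 60.0:
            raise ValueError("moderate/high conditions must exceed the 60 kcal threshold")


RCT_CONDITIONS = {
    "low": RctCondition("low", walk_pace=0, ee_kcal=RCT_EE["low"]),
    "moderate": RctCondition("moderate", walk_pace=100, ee_kcal=RCT_EE["moderate"]),
    "high": RctCondition("high", walk_pace=130, ee_kcal=RCT_EE["high"]),
}


@dataclass
class CohortSpec:
    """Everything the generator needs, including the true parameters."""

    group: str = "healthy"
    n_persons: int = 4
    n_days: int = 6
    n_sessions: int = 1
    param_means: dict = field(default_factory=lambda: dict(HEALTHY_MEANS))
    param_sds: dict = field(default_factory=lambda: dict(BETWEEN_PERSON_SD))
    noise_sd: float = 0.4
    exercise_profile: str = "rct_balanced"   # or freeliving_imbalanced
    exercise_prob: float = 0.05              # fraction of segments with a bout
    high_ee_share: float = 0.3               # of bouts, fraction above 60 kcal
    meals_per_day: int = 3
    carb_mean: float = 45.0
    carb_sd: float = 15.0
    baseline_mean: float = 5.5
    baseline_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("need at least one person")
        if self.noise_sd < 0 or any(v < 0 for v in self.param_sds.values()):
            raise ValueError("SDs must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def rct_cohort_spec(n_persons: int = 4, seed: int = 0, **overrides) -> CohortSpec:
    """The balanced healthy-group RCT: 6 days, one target meal per day."""
    kw = dict(group="healthy", n_persons=n_persons, n_days=6, n_sessions=1,
              exercise_profile="rct_balanced", meals_per_day=1,
              carb_mean=60.0, carb_sd=8.0, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def freeliving_cohort_spec(n_persons: int = 68, n_sessions: int = 1,
                           exercise_prob: float = 0.05, seed: int = 0,
                           **overrides) -> CohortSpec:
    """The imbalanced free-living patient cohort: 3-day sessions, rare and
    mostly low-intensity postprandial exercise, exercise strength attenuated
    to half the healthy mean."""
    means = dict(HEALTHY_MEANS)
    means["beta_e"] = PATIENT_EXERCISE_ATTENUATION * means["beta_e"]
    kw = dict(group="patient", n_persons=n_persons, n_days=3,
              n_sessions=n_sessions, param_means=means,
              exercise_profile="freeliving_imbalanced",
              exercise_prob=exercise_prob, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def evaluation_cohort_spec(n_persons: int = 16, seed: int = 0,
                           **overrides) -> CohortSpec:
    """The standard imbalanced cohort for the transfer comparison: 16
    patients with two 3-day sessions each; a tenth of meals are followed by
    exercise and most bouts stay light, putting the above-60-kcal
    exercise-segment rate near the 4% observed in the emulated study while
    keeping the test-day stratum populated at this cohort size."""
    kw = dict(n_sessions=2, exercise_prob=0.10, high_ee_share=0.4)
    kw.update(overrides)
    return freeliving_cohort_spec(n_persons=n_persons, seed=seed, **kw)


def draw_person_params(spec: CohortSpec, rng: np.random.Generator) -> list[PersonParams]:
    """Person parameters from the group-level Gaussians, alphas truncated positive."""

    def trunc_pos(mean, sd):
        if sd == 0:
            return max(mean, 1e-6)
        for _ in range(100):
            x = rng.normal(mean, sd)
            if x > 0:
                return x
        return abs(x) + 1e-6

    m, s = spec.param_means, spec.param_sds
    out = []
    for _ in range(spec.n_persons):
        out.append(PersonParams(
            alpha_d=trunc_pos(m["alpha_d"], s["alpha_d"]),
            beta_d=rng.normal(m["beta_d"], s["beta_d"]),
            alpha_e=trunc_pos(m["alpha_e"], s["alpha_e"]),
            beta_e=rng.normal(m["beta_e"], s["beta_e"]),
            c_syn=rng.normal(m["c_syn"], s["c_syn"]),
            sigma=spec.noise_sd,
        ))
    return out


def _session_grid(n_days: int) -> np.ndarray:
    return np.arange(0, n_days * MINUTES_PER_DAY, GRID_MIN)


def _causal_bell(grid: np.ndarray, tau: float, alpha: float) -> np.ndarray:
    delta = grid - tau
    out = np.exp(-0.5 * ((delta - 3.0 * alpha) / alpha) ** 2)
    out[delta < 0] = 0.0
    return out


def simulate_glucose(params: PersonParams, session: Session, model_kind: str,
                     rng: np.random.Generator,
                     baseline_mean: float = 5.5,
                     baseline_sd: float = 0.4) -> Session:
    """Fill a session's glucose trace from its events under one model kind.

    The trace is a piecewise-constant baseline (one level drawn per meal,
    switching 15 minutes before each meal so the preprandial window sees the
    segment's own level) plus the summed causal responses of every meal and
    exercise bout, plus i.i.d. N(0, sigma) noise.  With ``sigma = 0`` the
    postprandial samples equal the noise-free model prediction exactly.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    grid = session.times.astype(float)
    meals = sorted(session.meals, key=lambda m: m.time)

    baseline = np.full(grid.shape, baseline_mean)
    for meal in meals:  # later boundaries overwrite earlier ones
        level = rng.normal(baseline_mean, baseline_sd)
        baseline[grid >= meal.time - PRE_WINDOW_MIN] = level

    r_d = np.zeros_like(grid)
    for meal in meals:
        r_d += params.beta_d * meal.carbs * _causal_bell(grid, meal.time, params.alpha_d)
    r_e = np.zeros_like(grid)
    if model_kind in ("additive", "synergistic"):
        for ex in session.exercises:
            r_e += params.beta_e * ex.ee * _causal_bell(grid, ex.time, params.alpha_e)
    total = baseline + r_d
    if model_kind in ("additive", "synergistic"):
        total = total + r_e
    if model_kind == "synergistic":
        total = total + params.c_syn * r_d * r_e

    # scale 0 draws exact zeros while consuming the same stream, so noisy and
    # noise-free runs of one seed stay event-aligned
    noise = rng.normal(0.0, params.sigma, size=grid.shape)
    glucose = np.maximum(total + noise, 0.1)  # CGM cannot read nonpositive
    session.glucose = glucose
    return session


def generate_rct_sessions(spec: CohortSpec, rng: np.random.Generator,
                          params: Optional[list[PersonParams]] = None,
                          model_kind: str = "synergistic") -> list[Session]:
    """Six-day balanced RCT sessions, one target meal per day at lunchtime.

    Carbohydrate is near-constant within person (fixed draw plus small daily
    jitter); moderate/high days insert one walk event 30 minutes after the
    meal with the condition-mapped energy expenditure, and nothing else
    within two hours of the meal.
    """
    if spec.group != "healthy" or spec.n_days != 6:
        raise ValueError("the RCT protocol is 6 days of healthy-group data")
    if params is None:
        params = draw_person_params(spec, rng)
    sessions = []
    for p, pp in enumerate(params):
        pid = f"H{p+1:02d}"
        carbs_person = max(rng.normal(spec.carb_mean, spec.carb_sd), 20.0)
        meals, exercises = [], []
        for day in range(1, spec.n_days + 1):
            tau = (day - 1) * MINUTES_PER_DAY + 750  # 12:30 target meal
            carbs = max(carbs_person + rng.normal(0.0, 2.0), 10.0)
            meals.append(MealEvent(tau, carbs))
            cond = RCT_CONDITIONS[RCT_DAY_CONDITION[day]]
            if cond.ee_kcal > 0:
                exercises.append(ExerciseEvent(tau + cond.walk_offset, cond.ee_kcal))
        grid = _session_grid(spec.n_days)
        session = Session(person_id=pid, group="healthy", session_id="rct",
                          n_days=spec.n_days, times=grid,
                          glucose=np.full(grid.shape, spec.baseline_mean),
                          meals=meals, exercises=exercises)
        simulate_glucose(pp, session, model_kind, rng,
                         baseline_mean=spec.baseline_mean,
                         baseline_sd=spec.baseline_sd)
        sessions.append(session)
    return sessions


def generate_freeliving_sessions(spec: CohortSpec, rng: np.random.Generator,
                                 params: Optional[list[PersonParams]] = None,
                                 model_kind: str = "synergistic") -> list[Session]:
    """Three-day free-living patient sessions with imbalanced exercise.

    Each day has ``meals_per_day`` meals around 8:00, 12:30 and 18:00
    (jittered on the grid, kept >= 3 h apart so responses do not bleed
    across segments); a postprandial walk follows a meal with probability
    ``exercise_prob``, and only ``high_ee_share`` of those walks exceed the
    60 kcal exercise-segment threshold.
    """
    if spec.group != "patient":
        raise ValueError("free-living generation is for the patient group")
    if params is None:
        params = draw_person_params(spec, rng)
    meal_anchors = [480, 750, 1080][:spec.meals_per_day]
    sessions = []
    for p, pp in enumerate(params):
        pid = f"P{p+1:02d}"
        for sess_idx in range(spec.n_sessions):
            meals, exercises = [], []
            for day in range(spec.n_days):
                for anchor in meal_anchors:
                    jitter = GRID_MIN * rng.integers(-6, 7)  # +/- 30 min on grid
                    tau = day * MINUTES_PER_DAY + anchor + jitter
                    carbs = max(rng.normal(spec.carb_mean, spec.carb_sd), 10.0)
                    meals.append(MealEvent(int(tau), carbs))
                    if rng.random() < spec.exercise_prob:
                        offset = GRID_MIN * rng.integers(4, 9)  # 20-40 min after
                        if rng.random() < spec.high_ee_share:
                            ee = rng.uniform(65.0, 140.0)
                        else:
                            ee = rng.uniform(10.0, 55.0)
                        exercises.append(ExerciseEvent(int(tau) + offset, ee))
            grid = _session_grid(spec.n_days)
            session = Session(person_id=pid, group="patient",
                              session_id=f"s{sess_idx+1}", n_days=spec.n_days,
                              times=grid,
                              glucose=np.full(grid.shape, spec.baseline_mean),
                              meals=meals, exercises=exercises)
            simulate_glucose(pp, session, model_kind, rng,
                             baseline_mean=spec.baseline_mean,
                             baseline_sd=spec.baseline_sd)
            sessions.append(session)
    return sessions


def generate_cohort(spec: CohortSpec, model_kind: str = "synergistic",
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[list[Session], list[PersonParams]]:
    """Generate sessions and the true person parameters for one cohort spec."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = draw_person_params(spec, rng)
    if spec.exercise_profile == "rct_balanced":
        sessions = generate_rct_sessions(spec, rng, params=params, model_kind=model_kind)
    elif spec.exercise_profile == "freeliving_imbalanced":
        sessions = generate_freeliving_sessions(spec, rng, params=params,
                                                model_kind=model_kind)
    else:
        raise ValueError(f"unknown exercise profile {spec.exercise_profile!r}")
    return sessions, params


def write_truth_json(path: str | Path, spec: CohortSpec,
                     params: list[PersonParams],
                     person_ids: Optional[list[str]] = None) -> None:
    """Record the cohort spec and every person's true parameters."""
    if person_ids is None:
        prefix = "H" if spec.group == "healthy" else "P"
        person_ids = [f"{prefix}{i+1:02d}" for i in range(len(params))]
    payload = {
        "spec": spec.to_dict(),
        "persons": {pid: asdict(pp) for pid, pp in zip(person_ids, params)},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
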