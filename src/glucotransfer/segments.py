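"""Sessions, events and meal-centered segments.

A *session* is one contiguous monitoring period for one person: a CGM trace
on a 5-minute grid together with meal events (carbohydrate grams) and
exercise events (energy expenditure, kcal).  Prediction operates on
*segments*: windows anchored at each meal start ``tau``, holding the
preprandial glucose history on ``[tau - 15, tau]`` and the postprandial
target on ``(tau, tau + 90]`` (18 samples at 5-minute spacing).  Segments
with any missing grid sample in either window are excluded rather than
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: minutes of preprandial history retained in each segment
PRE_WINDOW_MIN = 15
#: minutes of postprandial horizon (clinically relevant window)
POST_WINDOW_MIN = 90
#: CGM sampling interval in minutes
GRID_MIN = 5
#: number of postprandial samples in a complete segment
N_POST = POST_WINDOW_MIN // GRID_MIN

MINUTES_PER_DAY = 1440

GROUPS = ("healthy", "patient")


@dataclass(frozen=True)
class GlucoseSample:
    """One CGM reading: minutes since session start and mmol/L value."""

    time: int
    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"glucose must be positive, got {self.value}")


@dataclass(frozen=True)
class MealEvent:
    """A meal: start time (minutes since session start) and carbohydrate grams."""

    time: int
    carbs: float

    def __post_init__(self):
        if self.carbs < 0:
            raise ValueError(f"carbs must be nonnegative, got {self.carbs}")


@dataclass(frozen=True)
class ExerciseEvent:
    """An exercise bout: start time and total energy expenditure (kcal)."""

    time: int
    ee: float

    def __post_init__(self):
        if self.ee < 0:
            raise ValueError(f"energy expenditure must be nonnegative, got {self.ee}")


@dataclass
class Session:
    """One person-session: CGM trace plus meal and exercise event lists.

    ``times`` are integer minutes since session start, strictly increasing
    on the 5-minute grid; ``glucose`` are the matching mmol/L values.
    """

    person_id: str
    group: str
    session_id: str
    n_days: int
    times: np.ndarray
    glucose: np.ndarray
    meals: list[MealEvent] = field(default_factory=list)
    exercises: list[ExerciseEvent] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=int)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose values must be positive")

    @property
    def samples(self) -> list[GlucoseSample]:
        return [GlucoseSample(int(t), float(v)) for t, v in zip(self.times, self.glucose)]

    def day_of(self, time_min: int) -> int:
        """1-based day index of a time within the session."""
        return int(time_min) // MINUTES_PER_DAY + 1

    @property
    def day_index(self) -> np.ndarray:
        """1-based day index per glucose sample."""
        return self.times // MINUTES_PER_DAY + 1


@dataclass
class Segment:
    """A meal-centered window: preprandial history and postprandial target.

    The anchor meal (earliest in ``meals_in_window``) starts at
    ``meal_time``; successive meals within the 90-minute horizon and
    exercise bouts within ``[meal_time - 15, meal_time + 90]`` ride along so
    the forward model can superpose their responses.
    """

    person_id: str
    session_id: str
    group: str
    meal_time: int
    day: int
    pre_times: np.ndarray
    pre_glucose: np.ndarray
    post_times: np.ndarray
    post_glucose: np.ndarray
    meals_in_window: list[MealEvent]
    exercises_in_window: list[ExerciseEvent]
    role: str = "train"

    def __post_init__(self):
        self.pre_times = np.asarray(self.pre_times, dtype=int)
        self.pre_glucose = np.asarray(self.pre_glucose, dtype=float)
        self.post_times = np.asarray(self.post_times, dtype=int)
        self.post_glucose = np.asarray(self.post_glucose, dtype=float)
        if not self.meals_in_window:
            raise ValueError("segment must contain its anchor meal")
        anchor = min(m.time for m in self.meals_in_window)
        if anchor != self.meal_time:
            raise ValueError("anchor meal must be the earliest meal in the window")

    @property
    def anchor_meal(self) -> MealEvent:
        return min(self.meals_in_window, key=lambda m: m.time)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("pre_times", "pre_glucose", "post_times", "post_glucose"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Segment":
        d = dict(d)
        d["meals_in_window"] = [MealEvent(**m) for m in d["meals_in_window"]]
        d["exercises_in_window"] = [ExerciseEvent(**e) for e in d["exercises_in_window"]]
        return cls(**d)


@dataclass
class SegmentSet:
    """A collection of segments from one cohort group, with drop accounting."""

    segments: list[Segment]
    group: str
    n_dropped: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_persons(self) -> int:
        return len({s.person_id for s in self.segments})

    @property
    def person_ids(self) -> list[str]:
        return sorted({s.person_id for s in self.segments})

    def subset(self, role: str) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if s.role == role], self.group)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)


def _window_times(anchor: int, lo_offset: int, hi_offset: int, lattice_origin: int) -> np.ndarray:
    """Grid times within ``[anchor+lo_offset, anchor+hi_offset]`` on a session's 5-min lattice."""
    lo = anchor + lo_offset
    hi = anchor + hi_offset
    first = lo + (-(lo - lattice_origin)) % GRID_MIN
    return np.arange(first, hi + 1, GRID_MIN)


def segment_sessions(sessions: Sequence[Session]) -> SegmentSet:
    """Cut every session into meal-centered segments.

    One segment per meal event.  A segment is kept only when every 5-minute
    grid sample in both the pre window ``[tau-15, tau]`` and the post window
    ``(tau, tau+90]`` is present; incomplete segments are counted in
    ``n_dropped``.  Sessions without meals contribute zero segments.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions given")
    groups = {s.group for s in sessions}
    if len(groups) > 1:
        raise ValueError(f"sessions mix groups {sorted(groups)}; segment one group at a time")

    segments: list[Segment] = []
    n_dropped = 0
    for sess in sessions:
        if sess.times.size == 0:
            n_dropped += len(sess.meals)
            continue
        value_at = dict(zip(sess.times.tolist(), sess.glucose.tolist()))
        origin = int(sess.times[0])
        for meal in sorted(sess.meals, key=lambda m: m.time):
            tau = meal.time
            pre_t = _window_times(tau, -PRE_WINDOW_MIN, 0, origin)
            post_t = _window_times(tau, 1, POST_WINDOW_MIN, origin)
            if len(post_t) != N_POST or not all(t in value_at for t in pre_t) \
                    or not all(t in value_at for t in post_t) or len(pre_t) == 0:
                n_dropped += 1
                continue
            meals_in = [meal] + [m for m in sess.meals
                                 if tau < m.time <= tau + POST_WINDOW_MIN]
            ex_in = [e for e in sess.exercises
                     if tau - PRE_WINDOW_MIN <= e.time <= tau + POST_WINDOW_MIN]
            segments.append(Segment(
                person_id=sess.person_id,
                session_id=sess.session_id,
                group=sess.group,
                meal_time=tau,
                day=sess.day_of(tau),
                pre_times=pre_t,
                pre_glucose=np.array([value_at[t] for t in pre_t]),
                post_times=post_t,
                post_glucose=np.array([value_at[t] for t in post_t]),
                meals_in_window=meals_in,
                exercises_in_window=sorted(ex_in, key=lambda e: e.time),
            ))
    return SegmentSet(segments, group=sessions[0].group, n_dropped=n_dropped)


def split_train_test(segment_set: SegmentSet, session_length_days: int) -> SegmentSet:
    """Assign train/test roles by day within each session.

    3-day free-living sessions: days 1-2 train, day 3 test.  6-day RCT
    sessions are entirely training data (the source task has no test role).
    Other session lengths follow the free-living rule: the last day is the
    test day.  Splitting never crosses sessions.
    """
    for seg in segment_set.segments:
        if not 1 <= seg.day <= session_length_days:
            raise ValueError(
                f"segment day {seg.day} outside session length {session_length_days}")
        if session_length_days == 6:
            seg.role = "train"
        else:
            seg.role = "test" if seg.day == session_length_days else "train"
    return segment_set


def is_exercise_segment(segment: Segment) -> bool:
    """True iff postprandial energy expenditure exceeds 60 kcal.

    Only bouts strictly after the anchor meal count; 60 kcal exactly is not
    an exercise segment.
    """
    total = sum(e.ee for e in segment.exercises_in_window if e.time > segment.meal_time)
    return total > 60.0


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

GLUCOSE_COLUMNS = ["person_id", "session_id", "day", "time_min", "glucose_mmol_l"]
MEAL_COLUMNS = ["person_id", "session_id", "time_min", "carbs_g"]
EXERCISE_COLUMNS = ["person_id", "session_id", "time_min", "ee_kcal"]


def read_cohort_csv(directory: str | Path, group: str) -> list[Session]:
    """Load sessions from ``glucose.csv``, ``meals.csv``, ``exercise.csv``.

    Files are comma-separated UTF-8 with header rows; times are integer
    minutes since session start.
    """
    directory = Path(directory)
    kw = dict(float_precision="round_trip")
    glu = pd.read_csv(directory / "glucose.csv", **kw)
    meals = pd.read_csv(directory / "meals.csv", **kw)
    exercise = pd.read_csv(directory / "exercise.csv", **kw)
    for df, cols, name in ((glu, GLUCOSE_COLUMNS, "glucose.csv"),
                           (meals, MEAL_COLUMNS, "meals.csv"),
                           (exercise, EXERCISE_COLUMNS, "exercise.csv")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} is missing columns {sorted(missing)}")

    sessions = []
    for (pid, sid), g in glu.groupby(["person_id", "session_id"], sort=True):
        g = g.sort_values("time_min")
        m = meals[(meals.person_id == pid) & (meals.session_id == sid)]
        e = exercise[(exercise.person_id == pid) & (exercise.session_id == sid)]
        sessions.append(Session(
            person_id=str(pid),
            group=group,
            session_id=str(sid),
            n_days=int(g["day"].max()),
            times=g["time_min"].to_numpy(),
            glucose=g["glucose_mmol_l"].to_numpy(),
            meals=[MealEvent(int(t), float(c))
                   for t, c in zip(m["time_min"], m["carbs_g"])],
            exercises=[ExerciseEvent(int(t), float(k))
                       for t, k in zip(e["time_min"], e["ee_kcal"])],
        ))
    return sessions


def write_cohort_csv(sessions: Iterable[Session], directory: str | Path) -> None:
    """Write sessions to the three-file cohort format (deterministic ordering)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grows, mrows, erows = [], [], []
    for s in sorted(sessions, key=lambda s: (s.person_id, s.session_id)):
        days = s.day_index
        for t, d, v in zip(s.times, days, s.glucose):
            grows.append((s.person_id, s.session_id, int(d), int(t), float(v)))
        for m in sorted(s.meals, key=lambda m: m.time):
            mrows.append((s.person_id, s.session_id, m.time, m.carbs))
        for e in sorted(s.exercises, key=lambda e: e.time):
            erows.append((s.person_id, s.session_id, e.time, e.ee))
    kw = dict(index=False, float_format="%.17g")
    pd.DataFrame(grows, columns=GLUCOSE_COLUMNS).to_csv(directory / "glucose.csv", **kw)
    pd.DataFrame(mrows, columns=MEAL_COLUMNS).to_csv(directory / "meals.csv", **kw)
    pd.DataFrame(erows, columns=EXERCISE_COLUMNS).to_csv(directory / "exercise.csv", **kw)


def segments_to_jsonl(segment_set: SegmentSet, path: str | Path) -> None:
    """Serialize segments one-per-line; round-trippable with ``segments_from_jsonl``."""
    with open(path, "w", encoding="utf-8") as fh:
        for seg in segment_set.segments:
            fh.write(json.dumps(seg.to_dict()) + "\n")


def segments_from_jsonl(path: str | Path, group: str | None = None) -> SegmentSet:
    segments = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                segments.append(Segment.from_dict(json.loads(line)))
    if group is None:
        group = segments[0].group if segments else "patient"
    return SegmentSet(segments, group=group)
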