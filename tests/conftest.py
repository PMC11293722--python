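import numpy as np
import pytest

import glucotransfer as gt
from glucotransfer.segments import MealEvent, ExerciseEvent, Segment, Session


def make_segment(meal_time=750, carbs=60.0, exercises=(), pre=None, post=None,
                 person_id="P01", day=None):
    """A hand-built segment on the 5-minute grid."""
    pre_t = np.arange(meal_time - 15, meal_time + 1, 5)
    post_t = np.arange(meal_time + 5, meal_time + 91, 5)
    if pre is None:
        pre = np.full(pre_t.shape, 5.5)
    if post is None:
        post = np.full(post_t.shape, 6.0)
    return Segment(
        person_id=person_id, session_id="s1", group="patient",
        meal_time=meal_time, day=day if day is not None else meal_time // 1440 + 1,
        pre_times=pre_t, pre_glucose=np.asarray(pre, dtype=float),
        post_times=post_t, post_glucose=np.asarray(post, dtype=float),
        meals_in_window=[MealEvent(meal_time, carbs)],
        exercises_in_window=[ExerciseEvent(t, ee) for t, ee in exercises],
    )


def make_session(meal_times, carbs=60.0, exercises=(), n_days=3,
                 person_id="P01", group="patient", missing_times=()):
    """A constant-glucose session with the given events; optionally with
    grid samples removed to exercise the exclusion rule."""
    times = np.arange(0, n_days * 1440, 5)
    keep = ~np.isin(times, list(missing_times))
    return Session(
        person_id=person_id, group=group, session_id="s1", n_days=n_days,
        times=times[keep], glucose=np.full(keep.sum(), 5.5),
        meals=[MealEvent(int(t), carbs) for t in meal_times],
        exercises=[ExerciseEvent(int(t), float(ee)) for t, ee in exercises],
    )


@pytest.fixture
def segment():
    return make_segment()


@pytest.fixture
def params():
    return gt.PersonParams(alpha_d=12.0, beta_d=0.04, alpha_e=10.0,
                           beta_e=-0.02, c_syn=0.2, sigma=0.4)


@pytest.fixture(scope="session")
def rct_cohort():
    """The standard seeded synthetic RCT: 4 subjects x 6 days."""
    spec = gt.rct_cohort_spec(seed=11)
    sessions, truths = gt.generate_cohort(spec, model_kind="synergistic")
    segs = gt.split_train_test(gt.segment_sessions(sessions), 6)
    return spec, sessions, truths, segs


@pytest.fixture(scope="session")
def rct_source_fit(rct_cohort):
    """One reduced-draw source fit shared by the tests that only need a
    representative converged posterior."""
    _, _, _, segs = rct_cohort
    cfg = gt.SamplerConfig(n_chains=2, n_iter=1500, n_burnin=700, seed=42)
    return gt.fit_source_task(segs, "synergistic", config=cfg)
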