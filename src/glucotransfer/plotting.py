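"""Optional trajectory plotting (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .segments import Segment
from .responses import PersonParams, predict


def plot_segment_prediction(segment: Segment, params: PersonParams,
                            model_kind: str, path: str | Path) -> None:
    """Save a decomposition plot: observed samples, predicted mean, and the
    baseline/diet/exercise/synergy layers on a dense minute grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dense = np.arange(segment.meal_time, segment.meal_time + 91)
    traj = predict(model_kind, params, segment, grid=dense)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(segment.post_times, segment.post_glucose, "ko", ms=4, label="observed")
    ax.plot(segment.pre_times, segment.pre_glucose, "o", color="gray", ms=3)
    ax.plot(dense, traj.y_hat, color="crimson", label="predicted")
    ax.plot(dense, traj.y_base + traj.r_d, color="pink", label="baseline + diet")
    if model_kind != "single":
        ax.plot(dense, traj.y_base + traj.r_e, color="seagreen", ls="--",
                label="baseline + exercise")
    for ev in segment.exercises_in_window:
        ax.axvline(ev.time, color="green", alpha=0.4)
    ax.axvline(segment.meal_time, color="k", ls=":", alpha=0.6)
    ax.set_xlabel("minutes since session start")
    ax.set_ylabel("glucose (mmol/L)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
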