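#!/usr/bin/env python
"""Ray-cast validation: is "pursuit" assigned when gaze tracks moving disks?

Joins the classified segments with per-sample ray-cast object labels.  The
key contrast: smooth-pursuit labeling on dynamic-trial disks should exceed
the (spurious) rate on static objects, but dynamic *parafoveal* targets
move too slowly to clear the scaled low-gaze threshold — the classifier's
documented failure regime — so their rate collapses toward the static one.
Also computes the mean gaze speed in each trial's longest on-target
intersaccadic interval, the follow-up that exposes why.
"""

import json
from pathlib import Path

import pandas as pd

from vrgaze import classify as clf
from vrgaze import io, kinematics
from vrgaze.paradigm import WorldLayout
from vrgaze.validate import (pursuit_validation, raycast_series,
                             target_interval_gaze_speed)

SESSION = Path("scratch/session")
RESULTS = Path("results")


def main() -> None:
    rec = io.read_recording(SESSION / "recording.csv")
    events = io.read_events(SESSION / "events.csv")
    cfg = io.PipelineConfig()
    layout = WorldLayout()
    speeds = kinematics.compute_speeds(rec, cfg)
    segments = clf.classify_recording(rec, cfg)
    truth_labels = pd.read_csv(SESSION / "ground_truth.csv")["label"] \
        .to_numpy(object)

    ray = raycast_series(rec, events, layout)
    ray.to_frame().to_csv(SESSION / "raycast.csv", index=False)
    report = pursuit_validation(segments, ray, events, truth=truth_labels)
    with open(RESULTS / "validation_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    tg = target_interval_gaze_speed(segments, ray, speeds, events,
                                    cfg.pursuit_eye_speed_exclusion)
    tg.to_csv(RESULTS / "target_gaze_speeds.csv", index=False)

    bc = report.by_condition
    print(f"pursuit-labeled time on static objects: "
          f"{report.pct_pursuit_on_static:.2f}% "
          f"(moving: {report.pct_pursuit_on_moving:.2f}%)")
    print("smooth-pursuit rate on the cued disk: "
          f"dynamic peripheral {bc['dynamic_peripheral']['pct_smooth_pursuit']:.2f}%, "
          f"dynamic parafoveal {bc['dynamic_parafoveal']['pct_smooth_pursuit']:.2f}%, "
          f"static {bc['static_all']['pct_smooth_pursuit']:.2f}%")
    g = tg.groupby(["condition_motion", "condition_eccentricity"])[
        "mean_gaze_speed"].mean()
    print("mean on-target gaze speed (deg/s):")
    print(g.to_string())


if __name__ == "__main__":
    main()
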