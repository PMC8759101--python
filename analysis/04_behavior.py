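#!/usr/bin/env python
"""Behavioural summaries: main sequence, reaction and disengagement times.

Groups first saccades by condition for main-sequence statistics (mean
amplitude, skewness, non-excess kurtosis) and tabulates per-trial saccadic
reaction time, button reaction time, and disengagement time.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vrgaze import classify as clf
from vrgaze import io
from vrgaze.paradigm import WorldLayout
from vrgaze.validate import (main_sequence_stats, raycast_series,
                             reaction_times, valid_sample_fraction)

SESSION = Path("scratch/session")
RESULTS = Path("results")


def main() -> None:
    rec = io.read_recording(SESSION / "recording.csv")
    events = io.read_events(SESSION / "events.csv")
    cfg = io.PipelineConfig()
    segments = clf.classify_recording(rec, cfg)
    ray = raycast_series(rec, events, WorldLayout())

    cues = events.of_kind("cue_onset")
    sacc = sorted((s for s in segments if s.label == "saccade"),
                  key=lambda s: s.t_start)
    onsets = np.array([s.t_start for s in sacc])
    groups: dict = {}
    for _, row in cues.iterrows():
        j = np.searchsorted(onsets, row["t"], side="right")
        if j < len(onsets):
            key = f"{row['condition_motion']}_{row['condition_eccentricity']}"
            groups.setdefault(key, []).append(sacc[j].amplitude)
    ms = main_sequence_stats(groups)
    ms.to_csv(RESULTS / "main_sequence.csv", index=False)

    rts = reaction_times(segments, events, ray, cfg.min_amplitude)
    rts = rts.merge(cues[["trial_id", "condition_motion",
                          "condition_eccentricity"]], on="trial_id")
    rts.to_csv(RESULTS / "reaction_times.csv", index=False)

    print(f"valid samples: {100 * valid_sample_fraction(rec):.1f}%")
    print("main sequence by condition:")
    print(ms.to_string(index=False))
    print("median RTs (s):")
    print(rts.groupby(["condition_motion", "condition_eccentricity"])[
        ["saccadic_rt", "button_rt", "disengagement"]].median().to_string())


if __name__ == "__main__":
    main()
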