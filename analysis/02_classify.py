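#!/usr/bin/env python
"""Classify the simulated session into saccades and 100 ms epochs.

Reads the recording written by 01_simulate.py, runs the head-speed-scaled
threshold pipeline, and reports the label inventory and how well the
detected saccades and epoch labels recover the generator's ground truth.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from vrgaze import classify as clf
from vrgaze import io, kinematics
from vrgaze.simulate import GroundTruth
from vrgaze.validate import classification_agreement, saccade_recovery

SESSION = Path("scratch/session")
RESULTS = Path("results")


def main() -> None:
    rec = io.read_recording(SESSION / "recording.csv")
    cfg = io.PipelineConfig()
    speeds = kinematics.compute_speeds(rec, cfg)
    segments = clf.classify_recording(rec, cfg)
    clf.segments_to_frame(segments).to_csv(SESSION / "segments.csv",
                                           index=False)

    gt = pd.read_csv(SESSION / "ground_truth.csv")
    truth = GroundTruth(
        t=gt["t"].to_numpy(), label=gt["label"].to_numpy(object),
        phase=gt["phase"].to_numpy(object),
        obj=gt["object"].fillna("").to_numpy(object),
        saccades=pd.read_csv(SESSION / "true_saccades.csv"))

    counts = Counter(s.label for s in segments)
    agreement = classification_agreement(segments, truth)
    recovery = saccade_recovery(segments, truth, usable=speeds.usable)
    summary = {
        "n_segments": len(segments),
        "segment_label_counts": dict(counts),
        "epoch_agreement": agreement["overall"],
        "agreement_by_truth_label": agreement["per_truth_label"],
        "saccade_recovery": recovery,
    }
    with open(RESULTS / "classification_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"{len(segments)} segments: {dict(counts)}")
    print(f"epoch-label agreement with ground truth: "
          f"{100 * agreement['overall']:.1f}%")
    print(f"saccade recovery: {recovery['n_recovered']}/"
          f"{recovery['n_eligible']} detectable true saccades "
          f"({100 * recovery['fraction']:.1f}%)")


if __name__ == "__main__":
    main()
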