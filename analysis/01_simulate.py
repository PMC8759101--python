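#!/usr/bin/env python
"""Simulate the full 288-trial session and write its streams to disk.

Generates the cued visual-discrimination session (120 Hz eye samples, head
pose, burst dropout, per-sample ground truth) and writes the bulky
per-sample CSVs under scratch/session/ plus a small summary under
results/.  Later drivers read the CSVs back, so the round trip through the
interchange format is part of the analysis.
"""

import json
from pathlib import Path

from vrgaze import io
from vrgaze.paradigm import WorldLayout, build_schedule
from vrgaze.simulate import SimulationParams, simulate_session
from vrgaze.validate import valid_sample_fraction

SEED = 1
OUT = Path("scratch/session")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    layout = WorldLayout()
    schedule = build_schedule(layout, seed=SEED)
    params = SimulationParams(seed=SEED)
    rec, events, truth = simulate_session(schedule, layout, params)

    io.write_recording(rec, OUT / "recording.csv")
    io.write_events(events, OUT / "events.csv")
    truth.to_frame().to_csv(OUT / "ground_truth.csv", index=False)
    truth.saccades.to_csv(OUT / "true_saccades.csv", index=False)

    summary = {
        "seed": SEED,
        "n_trials": schedule.n_trials,
        "n_samples": rec.n,
        "duration_s": float(rec.t[-1] - rec.t[0]),
        "valid_sample_fraction": valid_sample_fraction(rec),
        "n_true_saccades": int(len(truth.saccades)),
    }
    with open(RESULTS / "session_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"simulated {summary['n_trials']} trials: {summary['n_samples']} "
          f"samples over {summary['duration_s']:.0f} s, "
          f"{100 * summary['valid_sample_fraction']:.1f}% valid")


if __name__ == "__main__":
    main()
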