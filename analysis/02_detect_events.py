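"""Detect ignition onsets in the demo fluorescence movie and score them
against the simulated ground-truth events.

Reads scratch/demo_traces.tsv (written by 01_simulate_recording.py) and
writes results/detection_summary.json.
"""

import json
from pathlib import Path

import numpy as np

import burstnet as bn
from burstnet.io import read_events, read_traces, write_events

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    movie = read_traces(SCRATCH / "demo_traces.tsv")
    detected = bn.events_from_traces(movie)
    write_events(detected, RESULTS / "demo_detected_events.tsv")
    truth = read_events(RESULTS / "demo_events.tsv")

    # match each true event to the nearest detection of the same node
    tol = 3.0 / movie.frame_rate
    hits, errors = 0, []
    for node, t in zip(truth.node_ids, truth.times):
        cand = detected.times[detected.node_ids == node]
        if len(cand) and np.min(np.abs(cand - t)) <= tol:
            hits += 1
            errors.append(float(np.min(np.abs(cand - t))))
    summary = {
        "n_true_events": len(truth),
        "n_detected_events": len(detected),
        "hit_rate": hits / len(truth),
        "median_timing_error_ms": float(np.median(errors)) * 1e3,
    }
    (RESULTS / "detection_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"recovered {hits}/{len(truth)} true onsets "
        f"({summary['hit_rate']:.1%}), median timing error "
        f"{summary['median_timing_error_ms']:.1f} ms"
    )


if __name__ == "__main__":
    main()
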