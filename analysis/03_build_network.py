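"""Build the delay-weighted functional network from the detected events
and check its stability against the causal cut-off.

Writes results/demo_network.edgelist (+ JSON sidecar with sigma and burst
statistics) and results/cutoff_scan.json.
"""

import json
from pathlib import Path

import numpy as np

import burstnet as bn
from burstnet.io import read_events, write_network

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    train = read_events(RESULTS / "demo_detected_events.tsv")
    net, lag_model, bursts = bn.infer_network(train, cutoff=0.2)
    write_network(net, RESULTS / "demo_network.edgelist")
    sidecar = {
        "sigma_ms": lag_model.sigma * 1e3,
        "sigma_method": lag_model.fit_method,
        "cutoff_s": 0.2,
        "n_bursts": len(bursts),
        "burst_size_histogram": np.bincount([len(b) for b in bursts]).tolist(),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    (RESULTS / "demo_network.json").write_text(json.dumps(sidecar, indent=2))
    print(
        f"{len(bursts)} bursts; fitted sigma = {lag_model.sigma * 1e3:.1f} ms; "
        f"network has {net.n_edges} links over {net.n_nodes} nodes"
    )

    grid = np.round(np.arange(0.05, 0.55, 0.05), 10)
    scan = bn.cutoff_sensitivity(train, grid)
    payload = {
        "cutoffs_s": scan.cutoffs.tolist(),
        "vi_nats": scan.vi.tolist(),
        "plateau_cutoff_s": scan.plateau_cutoff,
    }
    (RESULTS / "cutoff_scan.json").write_text(json.dumps(payload, indent=2))
    print(
        f"burst grouping stabilizes at cut-off {scan.plateau_cutoff} s; "
        f"VI over the grid: {np.round(scan.vi, 4).tolist()}"
    )


if __name__ == "__main__":
    main()
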