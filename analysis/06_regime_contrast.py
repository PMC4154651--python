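"""Compare modular (conditional) and coherent (whole-population) activity
regimes: the weighted assortativity of the inferred functional networks.

Writes results/regime_contrast.tsv.
"""

from pathlib import Path

import numpy as np

from burstnet.experiments import run_contrast_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    reps = run_contrast_study(n_replicates=20, seed=3)
    with (RESULTS / "regime_contrast.tsv").open("w") as fh:
        fh.write("replicate\tmodular_r_w\tcoherent_r_w\n")
        for k, r in enumerate(reps):
            fh.write(f"{k}\t{r.modular_r:.4f}\t{r.coherent_r:.4f}\n")
    mod = [r.modular_r for r in reps]
    coh = [r.coherent_r for r in reps]
    wins = sum(m > c for m, c in zip(mod, coh))
    print(
        f"modular regime: weighted assortativity {np.mean(mod):+.3f} "
        f"(range {min(mod):+.3f} to {max(mod):+.3f})"
    )
    print(
        f"coherent regime: weighted assortativity {np.mean(coh):+.3f} "
        f"(range {min(coh):+.3f} to {max(coh):+.3f})"
    )
    print(f"modular exceeds coherent in {wins}/20 paired runs")


if __name__ == "__main__":
    main()
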