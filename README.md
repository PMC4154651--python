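# burstnet

Directed, weighted functional networks from burst-structured neuronal
activation sequences — and the topology statistics (weighted/directed
assortativity, rich-club) that characterize them.

## The problem

In clustered neuronal cultures, compact aggregates of neurons ("clusters")
behave as single units whose spontaneous activity is organized in
*bursts*: fast sequences of cluster ignitions, separated by tens of
seconds of quiet. The order and delays of ignitions within a burst carry
directional information: a cluster can only have influenced clusters that
fired *after* it, and the shorter the delay the stronger the plausible
influence. `burstnet` turns recorded onset times (or raw fluorescence
traces) into a directed weighted functional network and asks the
topological questions that matter for such systems: do well-connected
nodes preferentially link to each other (assortative mixing), and do the
strongest nodes form a tightly interconnected core (rich club)?

## The construction

1. **Bursts.** Events whose consecutive gaps exceed a causal cut-off
   (default 200 ms) cannot be causally related; the train is split into
   bursts at those gaps.
2. **Lag model.** The lags Δt between consecutive within-burst firings
   follow a Gaussian decay G(Δt) = exp(−Δt²/2σ²); σ is fitted per
   recording (half-normal MLE by default: σ = √(mean Δt²)).
3. **Weighting.** Every ordered pair (a, b) in a burst with
   0 < t_b − t_a ≤ cut-off adds g(t_b − t_a) = exp(−(t_b−t_a)²/2σ²) to
   w(a→b); simultaneous ignitions add weight 1 in both directions.
   Weights reinforce additively every time a sequence repeats.
4. **Topology.** Four assortativity variants over directed edges —
   Pearson/Spearman on degrees, and their *weighted* strength versions
   where each edge e contributes with its weight w_e
   (r^w = Σ w_e(x_e−x̄)(y_e−ȳ) / √(Σ w_e(x_e−x̄)² Σ w_e(y_e−ȳ)²),
   x = s_out(src), y = s_in(dst)) — with bootstrap errors, plus the
   directed weighted rich-club ratio φ(s) = W(s)/W_null(s) against the
   uncorrelated-strengths null.
5. **Cross-check.** An independent construction via time-delayed mutual
   information on activation series with surrogate-based significance
   (z-scored against temporally reshuffled firing series).

A synthetic-data module generates planted ground-truth networks, burst
cascades and fluorescence movies with the statistical structure above, so
the whole pipeline is testable end to end with no external data.

## Worked example

The numbered scripts under `analysis/` run the full story; they are thin
drivers over the library and write their tables under `results/`:

```bash
python analysis/01_simulate_recording.py
python analysis/02_detect_events.py
python analysis/03_build_network.py
python analysis/04_topology_metrics.py
python analysis/05_mi_crosscheck.py
python analysis/06_regime_contrast.py
```

Output of a run:

```
planted network: 25 nodes, 119 edges, degree assortativity +0.451
simulated 80 bursts, 250 events, mean burst size 3.12
recovered 237/250 true onsets (94.8%), median timing error 28.3 ms
80 bursts; fitted sigma = 41.8 ms; network has 329 links over 25 nodes
burst grouping stabilizes at cut-off 0.2 s
N = 25 nodes, E = 329 links, average degree 13.16, average strength 8.74
  pearson-degree                 -0.065 +- 0.064
  spearman-degree                -0.072 +- 0.061
  pearson-strength-weighted      +0.093 +- 0.077
  spearman-strength-weighted     +0.117 +- 0.072
rich-club ratio at the highest thresholds: 1.49
284 significant MI links; Jaccard overlap with the equally sized
top-weight delay-network edge set: 0.84
modular regime: weighted assortativity +0.914 (range +0.814 to +0.985)
coherent regime: weighted assortativity -0.001 (range -0.020 to +0.019)
modular exceeds coherent in 20/20 paired runs
```

Reading it: onset detection recovers ~95% of the simulated ignitions with
sub-frame timing error; the burst grouping is insensitive to the exact
cut-off past 0.2 s; the functional network inferred from an assortatively
planted circuit shows positive *weighted* assortativity and a rich-club
ratio above 1 at high strengths; the mutual-information construction
identifies essentially the same links; and modular (conditional) activity
produces strongly assortative functional networks while coherent
whole-population bursting does not — the two regimes bracket what
clustered versus homogeneous cultures show.

The same stages are available as a CLI (`burstnet simulate|detect|build|
metrics|mi|compare|run|cutoff-scan`); `burstnet run --config cfg.yaml
--out report.json` executes the whole pipeline from a YAML config and
emits one report with full provenance.

## Layout

```
src/burstnet/      library: synth, traces, core, metrics, minet, io,
                   pipeline, experiments, cli
analysis/          numbered narrative drivers (see worked example)
tests/             pytest suite, including end-to-end scientific checks
scripts/           acceptance.py (reproduction script)
docs/methods.md    models, defaults, calibration studies, limitations
```
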