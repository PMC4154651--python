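# Methods

`burstnet` infers directed, weighted functional networks from the burst
structure of neuronal activation sequences — as recorded, e.g., by calcium
imaging of clustered cortical cultures, where compact aggregates of neurons
("clusters") ignite collectively and act as single network nodes — and
quantifies their topology with weighted/directed assortativity and
rich-club statistics. This note documents the model, the defaults and
their rationale, the synthetic data the package is validated on, and the
numerical choices made where the design was genuinely open.

## From fluorescence to ignition times

Each node's fluorescence trace shows a stable resting baseline interrupted
by sharp transients: a fast (few-frame) rise at ignition followed by a slow
(~seconds) decay. Onset detection proceeds per node:

1. **Baseline.** A linear drift is fitted to the retained frames and frames
   more than `sd_factor` (default 2) residual standard deviations *above*
   the fit are discarded, iterating until the residual SD changes by less
   than 1% between passes (the iteration stop is our choice; transients
   only push fluorescence up, hence the one-sided rejection). The resting
   level F0 is the mean retained level after removing the drift about the
   recording midpoint; an exact fit (SD below a 1e-9 relative floor) stops
   immediately retaining every frame.
2. **Normalization.** dF/F = (F − F0)/F0 after drift removal; detection is
   therefore invariant under affine rescaling of the raw trace.
3. **Detection.** An ignition is a local maximum of the derivative of the
   boxcar-smoothed signal (window 3 frames) accompanied by dF/F above
   `sd_factor` background SDs for at least `min_frames` (default 5)
   consecutive frames. The derivative maximum must itself clear the
   background derivative noise (sd·√(2/3) after a 3-frame boxcar); this
   one extra condition rejects re-crossings where a decaying transient
   hovers at the amplitude threshold, and brings the false-positive rate
   on event-free noise below 1 per 10⁴ frames at defaults.
4. **Sub-frame refinement.** A least-squares line through the
   `n_background` (default 10) pre-onset frames and another through the
   `n_rise` (default 5) rise frames cross at the refined onset time. The
   refinement falls back to the frame time when fewer frames are
   available, when the lines are near-parallel, or when the crossing lands
   more than one frame away. The point counts are configurable because no
   canonical values exist; the refinement is only accurate when the true
   rise spans the fit window.

## From ignition times to the functional network

Activity is organized in *bursts*: fast sequences of node ignitions whose
consecutive gaps never exceed a causal cut-off (default 0.2 s — two times
the maximal plausible inter-node propagation delay; nodes firing further
apart cannot have influenced one another). Gaps exactly equal to the
cut-off stay within the burst (the boundary convention is ours).

Within each burst, the lags between *consecutive* firings are pooled over
the recording and their frequency distribution is summarized by the width
σ of a Gaussian decay G(Δt) = exp(−Δt²/2σ²). The default estimator is the
half-normal maximum likelihood σ = √(mean Δt²) over nonzero lags —
binning-free and robust at small sample sizes; a histogram least-squares
fit of A·exp(−Δt²/2σ²) is available (`sigma_method="histogram"`) for
fidelity to the graphical-fit formulation. At least 10 nonzero lags are
required.

Links are then accumulated: for every ordered pair (a, b) inside a burst
with 0 < t_b − t_a ≤ cut-off, w(a→b) gains g(t_b − t_a) = exp(−(t_b −
t_a)²/2σ²). All ordered pairs are linked, not only consecutive firings —
an early node can influence every later one — while σ is fitted from
consecutive lags only. Simultaneous ignitions (identical onset times,
typically the same acquisition frame) carry no causal direction and add
weight 1 to both directions. If a node fires more than once inside a
burst only its first onset is used: a burst is defined by ignition, and
repeated same-node events within the cut-off are not resolvable in
practice. Weights are reinforced additively across bursts; only nodes
with at least one event enter the network.

**Cut-off sensitivity.** Because the construction is deterministic given
the burst grouping, sensitivity to the cut-off is assessed on the grouping
itself: for successive cut-off values the variation of information
VI = H(A) + H(B) − 2·I(A, B) (in nats) between the induced partitions of
events into bursts is computed. Past the stabilization plateau (first grid
value after which VI stays below a threshold, default ~0) the grouping,
and hence every derived network, is unchanged. With the canonical
two-scale gap structure (~30 ms in-burst lags, ~30 s inter-burst gaps) the
grouping is invariant across the whole 0.15–0.30 s band.

## Topology metrics

Assortativity is the correlation, over directed edges, between a property
of the source and of the target:

* `pearson-degree` — Pearson of (k_out(src), k_in(dst)); Newman's directed
  degree assortativity.
* `pearson-strength-weighted` — weighted Pearson of (s_out(src),
  s_in(dst)) with per-edge weight w_e and H = Σ w_e, so heavier links
  contribute more.
* Spearman variants replace each endpoint value by its mid-rank among the
  node-level out-(in-)quantities before applying the same machinery. The
  ranks are node-level, not edge-multiset-level, following the
  rank-substitution reading of the Spearman construction.

The directed pairing (source out-X against target in-X) is forced for
degrees and extended identically to strengths. Errors are bootstrap
standard deviations over edge resamples (default 1000); resamples with
degenerate variance are discarded and counted, and the error is flagged
unreliable when they exceed half. Jackknife and Fisher-transform errors
are out of scope.

The rich-club curve ranks nodes by total strength s = s_in + s_out
(alternatives: in-only, out-only) and, for thresholds spanning the node
strength range, compares the interconnection weight W of the club
{i : s_i > s_thr} with the uncorrelated expectation

    W_null = [ (Σ_club s_out)(Σ_club s_in) − Σ_club s_out·s_in ] / S,

where S is the total network weight — the expectation when every unit of
out-strength lands on targets in proportion to their in-strength,
self-links excluded. φ = W/W_null > 1 at high thresholds indicates a rich
club. For symmetric networks the expression reduces to the undirected
formulation; a Monte-Carlo strength-preserving redistribution
(`sampled_rich_club_null`) reproduces the analytic null within a few
percent and serves as its cross-check.

## Mutual-information cross-construction

As an independent route, each node's train is mapped to a per-frame series
and, for every ordered pair, the delayed mutual cross information
I(x_t; y_{t+τ}) is computed over equal-width binnings (default 8 bins) of
each series' own range, maximized over τ ∈ [0, τ_max] (ties to the
smallest delay). Significance comes from surrogates that randomly permute
node j's per-frame firing entries (destroying all temporal structure,
preserving marginal counts; default 200 surrogates): z = (I* −
⟨I*_surr⟩)/rms, significant when the one-sided Gaussian tail probability
0.5·erfc(z/√2) is below α (default 0.01). The network weight is z where
significant, 0 otherwise.

Two series mappings are provided. The default *walk* is the cumulative
activation count. Its equal-width binning effectively slices time, so for
short recordings the observed and surrogate walks are both monotone
staircases dominated by the time trend and the co-firing signal needs very
long recordings (or bin counts commensurate with the event count) to reach
significance; the z statistic is, however, well calibrated under the null.
The alternative `walk_kind="indicator"` uses the raw per-frame firing
series — exactly the object the surrogate procedure reshuffles — and
discriminates co-firing sharply at short recording lengths; it is what the
short in-package cross-checks use. On cascade simulations the significant
indicator-MI edge set overlaps the equally sized top-weight delay-network
edge set with Jaccard ≈ 0.75–0.9: the two constructions identify
fundamentally the same links.

## Synthetic ground truth

No public recording accompanies this problem, so every stage is validated
on generated data whose statistical structure mirrors the target
recordings: a few dozen nodes, bursts of sequentially igniting nodes with
lags well below the 200 ms cut-off and Gaussian-decaying lag frequencies,
inter-burst intervals of tens of seconds, repeated-but-variable ignition
sequences, and fluorescence transients with fast rise and ~2 s decay over
noisy baselines.

* **Planted networks.** Out-degrees are log-normal (σ_ln = 0.5, location
  solved so the capped draw keeps the requested mean); in-degrees are made
  comparably heterogeneous through log-normal target attractiveness. Both
  are capped at 60% of n−1: a saturated node's edges cannot be swapped,
  which would make assortativity targets unreachable. Degree-preserving
  target swaps, steered Xulvi-Brunet/Sokolov-style (when assortativity
  must rise, the higher-out-degree source is paired with the
  higher-in-degree target) with 5% uphill acceptance and up to 5 random
  restarts, move the unweighted directed assortativity to the target
  (tolerance 0.05); failure to reach it is reported, never silent. Link
  weights are i.i.d. log-normal.
* **Cascades.** Each burst starts at one initiator (uniform by default,
  configurable) and propagates stochastically: an edge of weight w
  transmits once with probability 1 − exp(−transmission_scale·w) after a
  Gaussian delay truncated to (0, delay_max]; a node ignites at most once
  per burst (earliest arrival wins; its sender is logged as the true
  parent). Defaults: delay mean 30 ms, SD 30 ms, max 100 ms — the spread
  is set equal to the mean so the pooled consecutive-lag histogram has the
  monotone Gaussian-decay shape the σ fit assumes, rather than a peak at
  the mean delay. The default transmission scale 0.06 puts the cascade
  branching ratio below 1 ("conditional" bursts engaging small node
  subsets); with ~5 out-edges per node this keeps common-parent
  coactivation — whose near-zero sibling lags are the dominant source of
  spurious high-weight links — rare enough for the top quartile of
  inferred links to recover planted edges with precision ≥ 0.8 at 200
  bursts. Burst sizes are correspondingly small (mean ≈ 1.4 events
  including singleton initiations); denser, larger-burst regimes are a
  transmission-scale turn away but trade link precision for coverage. An
  optional fraction of transmission lags can be snapped to zero to
  exercise the simultaneity (bidirectional-link) rule.
* **Activity regimes.** `simulate_modular_bursts` emulates the
  conditional, module-at-a-time activity of clustered cultures: modules
  of uneven (Dirichlet) sizes and rates, each burst igniting most of one
  module in random order. Functional edges then form within modules, so
  edge endpoints share similar strengths and the inferred weighted
  assortativity is strongly positive (≈ 0.65–0.96). `simulate_coherent_bursts`
  ignites (nearly) the whole population each burst in random order, which
  homogenizes strengths and leaves the weighted assortativity near zero
  (|r| ≲ 0.03) — the in-silico twin of the clustered-versus-homogeneous
  contrast.
* **Fluorescence.** Each event adds a transient (linear rise over 3
  frames to 20 units above a baseline of 100, exponential decay with
  τ = 2 s) at 33 frames/s, plus white noise (SD 1) and optional linear
  drift; overlapping transients sum. The amplitude parameter is ours —
  some peak height must be chosen to set the synthetic SNR (default 20).

What the generator does *not* emulate: biophysics of calcium indicators
(nonlinear saturation, photobleaching beyond linear drift), spatial
embedding and distance-dependent connectivity, inhibition, and
multi-initiator bursts. Passing tests therefore show the *pipeline* is
correct and well calibrated under the stated statistical structure, not
that any particular biological recording satisfies that structure.

## Calibration studies and problem sizes

The standard in-package studies (in `burstnet.experiments`, also rerun by
`scripts/acceptance.py`) use sizes chosen to finish in seconds to minutes
on one CPU while keeping estimator noise acceptable:

* recovery: 20 replicates of 30 nodes / 200 bursts (positive weighted
  assortativity in ≈ 19–20 of 20; mean top-quartile precision ≈ 0.84);
* surrogate-test calibration: 500 independent Bernoulli firing-series
  pairs (2000 frames, ~20 events each), 200 surrogates, α = 0.05, with
  the cumulative-walk default — the measured type-I rate is within ±0.02
  of α (the erf-based Gaussian tail is approximate for a max-over-delays
  statistic, so mild deviations appear under other series models);
* cut-off stability: 40 bursts of 5 events, lag scale 30 ms, gaps 30 s,
  VI computed over a 0.10–0.35 s grid;
* contrast: 20 paired modular/coherent runs at 30 nodes / 200 bursts.

## Numerical choices and degenerate inputs

* Times are seconds (floats) throughout; frames appear only in trace
  detection and MI; frame indices are 0-based; node ids are opaque
  strings, sorted lexicographically in outputs.
* Zero-variance endpoint series make assortativity *undefined* (raised as
  an error, never NaN propagation); regular graphs are the canonical case.
* Rich-club thresholds with fewer than 2 qualifying nodes, or vanishing
  null weight, are dropped from the curve.
* Constant series have zero delayed MI by convention; zero surrogate
  spread makes significance undecidable and is flagged insignificant.
* Empty trains segment into no bursts; an edgeless network simulates
  singleton bursts (warned, flagged).
* Every random operation takes an explicit seed; derived sub-seeds are
  drawn below 2³¹ from a parent generator, so whole studies are
  reproducible from one integer.

## Known limitations

* Functional weights conflate transmission frequency and delay; the top
  links of the inferred network need not be structural edges (sibling
  coactivation is the main confound, as quantified above).
* The σ fit assumes a single lag scale per recording; mixtures (e.g.,
  maturation gradients) are averaged over.
* The cumulative-walk MI needs recording lengths far beyond what the
  in-package simulations use to detect links at its default binning; use
  the indicator switch at short scales.
* Bootstrap errors treat edges as exchangeable, ignoring that both
  endpoints' strengths are computed from the same network.
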