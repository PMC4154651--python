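"""Synthetic ground truth: planted networks, burst cascades, fluorescence.

Everything downstream (onset detection, burst segmentation, network
inference, topology metrics, the mutual-information cross-check) is
validated against data generated here, because no public recording
accompanies the problem domain.  The generator emulates the statistical
structure of spontaneous activity in clustered neuronal cultures:

* a few dozen interconnected nodes (clusters of neurons acting as units);
* *bursts* — fast chains of sequential node ignitions whose consecutive
  lags sit well below the 200 ms causal cut-off, with Gaussian-decaying
  lag frequencies;
* inter-burst intervals of tens of seconds;
* repeated-but-variable ignition sequences (the same pathways reused with
  stochastic participation and delays);
* fluorescence transients with a fast (few-frame) rise and ~seconds decay
  over a noisy, possibly drifting baseline.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EventTrain
from .network import DirectedWeightedNetwork


def _node_names(n: int) -> "list[str]":
    width = max(2, len(str(n - 1)))
    return [f"n{i:0{width}d}" for i in range(n)]


# -- planted networks ------------------------------------------------------


@dataclass
class GroundTruthNetwork:
    """A planted directed weighted network with a known assortativity."""

    n_nodes: int
    weights: np.ndarray  # dense, diagonal zero, >= 0
    planted_assortativity: float  # realized unweighted directed assortativity
    seed: int
    target_reached: bool = True
    nodes: "list[str]" = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = _node_names(self.n_nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edge_set(self) -> "set[tuple[str, str]]":
        src, dst = np.nonzero(self.weights)
        return {(self.nodes[i], self.nodes[j]) for i, j in zip(src, dst)}

    def to_network(self) -> DirectedWeightedNetwork:
        return DirectedWeightedNetwork(list(self.nodes), self.weights.copy())


def _lognormal_mu_for_capped_mean(target_mean: float, sigma: float, cap: float) -> float:
    """Location mu such that E[min(LogNormal(mu, sigma), cap)] = target_mean.

    Closed form for the capped mean plus a bisection solve; keeps the
    realized mean out-degree near the requested one even when the upper
    tail is truncated.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    if target_mean >= cap:
        return float(np.log(cap))

    def capped_mean(mu: float) -> float:
        a = (np.log(cap) - mu - sigma**2) / sigma
        b = (np.log(cap) - mu) / sigma
        return float(np.exp(mu + sigma**2 / 2) * norm.cdf(a) + cap * norm.sf(b))

    naive = np.log(target_mean) - sigma**2 / 2.0
    lo, hi = naive - 1.0, np.log(cap) + 5.0
    return float(brentq(lambda m: capped_mean(m) - target_mean, lo, hi))


def _directed_degree_assortativity(src: np.ndarray, dst: np.ndarray, n: int) -> float:
    """Pearson correlation of (out-degree of source, in-degree of target)
    over the directed edges given as parallel index arrays."""
    kout = np.bincount(src, minlength=n)
    kin = np.bincount(dst, minlength=n)
    x = kout[src].astype(float)
    y = kin[dst].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def generate_planted_network(
    n_nodes: int,
    mean_out_degree: float,
    weight_scale: float = 1.0,
    target_assortativity: float = 0.0,
    seed: int = 0,
    tolerance: float = 0.05,
    swap_budget: "int | None" = None,
    weight_sigma: float = 0.5,
) -> GroundTruthNetwork:
    """Plant a directed weighted network with a chosen degree assortativity.

    Out-degrees are drawn from a log-normal distribution (the strength
    heterogeneity that rich-club analysis needs), targets assigned at
    random, then degree-preserving edge swaps — exchanging the targets of
    two random edges — are accepted only when they move the unweighted
    directed assortativity toward ``target_assortativity``.  Link weights
    are i.i.d. log-normal times ``weight_scale``.

    If the target is not reached within the swap budget the closest
    attainable network is returned with ``target_reached=False`` and a
    warning, never silently.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if not mean_out_degree < n_nodes:
        raise ValueError("mean_out_degree must be below n_nodes")
    rng = np.random.default_rng(seed)
    # log-normal out-degrees with the requested mean.  Degrees are capped
    # below saturation (a node wired to almost every other node leaves no
    # freedom for the assortativity-steering swaps), and the log-normal
    # location is solved so the capped draw still hits the requested mean.
    sigma_ln = 0.5
    k_max = max(2, int(0.6 * (n_nodes - 1)))
    mu_ln = _lognormal_mu_for_capped_mean(mean_out_degree, sigma_ln, k_max)
    kout = np.clip(
        np.round(rng.lognormal(mu_ln, sigma_ln, size=n_nodes)).astype(int),
        1,
        k_max,
    )
    # heterogeneous in-degrees as well: targets drawn with log-normal
    # attractiveness, so both degree sequences carry the spread that makes
    # nontrivial assortativity targets attainable
    def assign_targets() -> "tuple[np.ndarray, np.ndarray]":
        # heterogeneous in-degrees via log-normal attractiveness, capped like
        # out-degrees so no node saturates and swaps stay feasible
        attractiveness = rng.lognormal(0.0, sigma_ln, size=n_nodes)
        kin_counts = np.zeros(n_nodes, dtype=int)
        src_list: list[int] = []
        dst_list: list[int] = []
        for i in rng.permutation(n_nodes):
            allowed = np.flatnonzero((np.arange(n_nodes) != i) & (kin_counts < k_max))
            k_i = min(kout[i], len(allowed))
            p = attractiveness[allowed] / attractiveness[allowed].sum()
            targets = rng.choice(allowed, size=k_i, replace=False, p=p)
            kin_counts[targets] += 1
            src_list.extend([int(i)] * k_i)
            dst_list.extend(targets.tolist())
        return np.array(src_list), np.array(dst_list)

    def anneal(src: np.ndarray, dst: np.ndarray, budget: int):
        # Directed Xulvi-Brunet/Sokolov-style steering: when assortativity
        # must rise, reassign two targets so the higher-out-degree source
        # points to the higher-in-degree target (reverse to lower it).  A
        # small uphill acceptance escapes local optima; best state is kept.
        n_edges = len(src)
        edge_lookup = {(int(a), int(b)) for a, b in zip(src, dst)}
        kin = np.bincount(dst, minlength=n_nodes)
        r = _directed_degree_assortativity(src, dst, n_nodes)
        best_r, best_dst = r, dst.copy()
        uphill_p = 0.05
        for _ in range(budget):
            if abs(best_r - target_assortativity) <= tolerance:
                break
            e1, e2 = rng.integers(0, n_edges, size=2)
            if e1 == e2:
                continue
            a, b = int(src[e1]), int(dst[e1])
            c, d = int(src[e2]), int(dst[e2])
            if kout[a] != kout[c] and kin[b] != kin[d]:
                want_up = r < target_assortativity
                aligned = (kout[a] > kout[c]) == (kin[b] > kin[d])
                if aligned == want_up and rng.random() > uphill_p:
                    continue  # already ordered the way we need
            # swap targets: (a->b, c->d) becomes (a->d, c->b)
            if a == d or c == b or (a, d) in edge_lookup or (c, b) in edge_lookup:
                continue
            dst[e1], dst[e2] = d, b
            r_new = _directed_degree_assortativity(src, dst, n_nodes)
            if (
                abs(r_new - target_assortativity) < abs(r - target_assortativity)
                or rng.random() < uphill_p
            ):
                edge_lookup.discard((a, b))
                edge_lookup.discard((c, d))
                edge_lookup.add((a, d))
                edge_lookup.add((c, b))
                r = r_new
                if abs(r - target_assortativity) < abs(best_r - target_assortativity):
                    best_r, best_dst = r, dst.copy()
            else:
                dst[e1], dst[e2] = b, d
        return best_r, best_dst

    # random restarts: redraw the target assignment when the swap search
    # lands in a local optimum, keeping the global best
    n_restarts = 5
    r, src, dst = np.inf, None, None
    for _ in range(n_restarts):
        src_try, dst_try = assign_targets()
        budget = swap_budget if swap_budget is not None else 60 * len(src_try)
        r_try, dst_try = anneal(src_try, dst_try, budget)
        if src is None or abs(r_try - target_assortativity) < abs(
            r - target_assortativity
        ):
            r, src, dst = r_try, src_try, dst_try
        if abs(r - target_assortativity) <= tolerance:
            break
    n_edges = len(src)
    target_reached = abs(r - target_assortativity) <= tolerance
    if not target_reached:
        warnings.warn(
            f"planted assortativity {r:.3f} did not reach target "
            f"{target_assortativity:.3f} within the swap budget",
            stacklevel=2,
        )
    w = np.zeros((n_nodes, n_nodes))
    w[src, dst] = weight_scale * rng.lognormal(0.0, weight_sigma, size=n_edges)
    return GroundTruthNetwork(
        n_nodes=n_nodes,
        weights=w,
        planted_assortativity=r,
        seed=seed,
        target_reached=target_reached,
    )


# -- burst cascades --------------------------------------------------------


@dataclass
class CascadeParams:
    """Parameters of the burst-cascade simulation.

    Delays between a node's ignition and that of a node it activates follow
    a Gaussian truncated to (0, delay_max]; defaults (mean 30 ms, sd 15 ms,
    max 100 ms) keep consecutive lags well below the 200 ms cut-off, with
    the Gaussian-decay lag histogram the weighting scheme assumes.  An edge
    of weight w transmits with probability 1 - exp(-transmission_scale * w).
    """

    delay_mean: float = 0.030  # s
    delay_sd: float = 0.030  # s; spread ~ mean gives the monotone Gaussian-decay lag histogram
    delay_max: float = 0.100  # s
    transmission_scale: float = 0.06  # sub-critical branching: conditional bursts
    inter_burst_interval_mean: float = 30.0  # s
    n_bursts: int = 200
    refractory: bool = True  # one firing per node per burst
    simultaneous_fraction: float = 0.0  # lags snapped to zero (same frame)
    initiator_weights: "np.ndarray | None" = None  # distribution over nodes

    def __post_init__(self) -> None:
        if not (0 < self.delay_mean <= self.delay_max):
            raise ValueError("need 0 < delay_mean <= delay_max")
        if self.delay_sd <= 0:
            raise ValueError("delay_sd must be positive")
        if self.n_bursts < 1:
            raise ValueError("n_bursts must be >= 1")
        if not 0.0 <= self.simultaneous_fraction <= 1.0:
            raise ValueError("simultaneous_fraction must lie in [0, 1]")


@dataclass
class BurstSimulation:
    """Simulated activity plus the ground-truth transmissions that caused it."""

    train: EventTrain
    transmissions: "list[tuple[str, str]]"  # (parent, child) actual activations
    burst_starts: np.ndarray
    no_edges: bool = False  # cascades were singleton initiator events only


def _truncated_delays(rng: np.random.Generator, p: CascadeParams, size: int) -> np.ndarray:
    """Gaussian delays rejected onto (0, delay_max]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(p.delay_mean, p.delay_sd, size=size - filled)
        ok = draw[(draw > 0) & (draw <= p.delay_max)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def simulate_bursts(
    net: "GroundTruthNetwork | DirectedWeightedNetwork",
    params: CascadeParams,
    seed: int = 0,
) -> BurstSimulation:
    """Simulate burst cascades on a ground-truth network.

    Each burst starts with one initiator (uniform over nodes unless
    ``initiator_weights`` is given) and propagates as a stochastic cascade:
    a newly ignited node tries each out-link once, transmitting with
    probability 1 - exp(-transmission_scale * w) after a truncated-Gaussian
    delay.  A node ignites at most once per burst (the earliest arriving
    activation wins, and its sender is logged as the true parent).  Bursts
    are separated by gaps drawn around ``inter_burst_interval_mean``, far
    above ``delay_max``.
    """
    if isinstance(net, GroundTruthNetwork):
        nodes, w = net.nodes, net.weights
    else:
        nodes, w = net.nodes, net.w
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    p_init = params.initiator_weights
    if p_init is not None:
        p_init = np.asarray(p_init, dtype=float)
        p_init = p_init / p_init.sum()
    p_transmit = 1.0 - np.exp(-params.transmission_scale * w)
    no_edges = not np.any(w > 0)
    if no_edges:
        warnings.warn("network has no edges; bursts are singleton events", stacklevel=2)
    out_neighbors = [np.flatnonzero(w[i]) for i in range(n)]

    min_gap = 10.0 * params.delay_max
    gaps = np.maximum(
        rng.normal(
            params.inter_burst_interval_mean,
            0.1 * params.inter_burst_interval_mean,
            size=params.n_bursts,
        ),
        min_gap,
    )
    burst_starts = np.cumsum(gaps)

    ev_nodes: list[str] = []
    ev_times: list[float] = []
    transmissions: list[tuple[str, str]] = []
    for t0 in burst_starts:
        initiator = int(rng.choice(n, p=p_init))
        # (time, tiebreak, node, parent) min-heap of pending activations
        heap: list[tuple[float, int, int, int]] = [(float(t0), 0, initiator, -1)]
        tiebreak = 1
        ignited: set[int] = set()
        while heap:
            t, _, node, parent = heapq.heappop(heap)
            if node in ignited:
                continue
            ignited.add(node)
            ev_nodes.append(nodes[node])
            ev_times.append(t)
            if parent >= 0:
                transmissions.append((nodes[parent], nodes[node]))
            nbrs = out_neighbors[node]
            if len(nbrs) == 0:
                continue
            fire = nbrs[rng.random(len(nbrs)) < p_transmit[node, nbrs]]
            if len(fire) == 0:
                continue
            delays = _truncated_delays(rng, params, len(fire))
            if params.simultaneous_fraction > 0:
                snap = rng.random(len(fire)) < params.simultaneous_fraction
                delays[snap] = 0.0
            for j, d in zip(fire, delays):
                if j not in ignited:
                    heapq.heappush(heap, (t + float(d), tiebreak, int(j), node))
                    tiebreak += 1
    train = EventTrain(np.array(ev_nodes, dtype=object), np.array(ev_times))
    return BurstSimulation(
        train=train,
        transmissions=transmissions,
        burst_starts=burst_starts,
        no_edges=no_edges,
    )


# -- activity regimes for the clustered-vs-homogeneous contrast ------------


def simulate_modular_bursts(
    n_nodes: int = 30,
    n_modules: int = 4,
    n_bursts: int = 200,
    participation: float = 0.9,
    params: "CascadeParams | None" = None,
    seed: int = 0,
) -> EventTrain:
    """Modular, conditional activity: each burst ignites one module.

    Emulates the clustered-culture regime, where bursting episodes comprise
    a small subset of nodes (a module) rather than the whole network.
    Modules have uneven sizes and firing rates, giving the strength
    heterogeneity that makes the inferred functional network assortative:
    edges form within modules, so endpoints share similar strengths.
    """
    if params is None:
        params = CascadeParams(n_bursts=n_bursts)
    rng = np.random.default_rng(seed)
    nodes = _node_names(n_nodes)
    # uneven module sizes via a Dirichlet split, at least 2 nodes each
    sizes = np.maximum(
        np.round(rng.dirichlet(np.full(n_modules, 2.0)) * n_nodes).astype(int), 2
    )
    while sizes.sum() > n_nodes:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_nodes:
        sizes[np.argmin(sizes)] += 1
    perm = rng.permutation(n_nodes)
    modules = []
    pos = 0
    for s in sizes:
        modules.append(perm[pos : pos + s])
        pos += s
    module_rate = rng.dirichlet(np.full(n_modules, 2.0))  # uneven burst rates
    gaps = np.maximum(
        rng.normal(
            params.inter_burst_interval_mean,
            0.1 * params.inter_burst_interval_mean,
            size=n_bursts,
        ),
        10.0 * params.delay_max,
    )
    burst_starts = np.cumsum(gaps)
    ev_nodes: list[str] = []
    ev_times: list[float] = []
    for t0 in burst_starts:
        m = modules[int(rng.choice(n_modules, p=module_rate))]
        firing = m[rng.random(len(m)) < participation]
        if len(firing) == 0:
            firing = m[:1]
        order = rng.permutation(firing)
        lags = _truncated_delays(rng, params, len(order))
        lags[0] = 0.0
        times = t0 + np.cumsum(lags)
        ev_nodes.extend(nodes[i] for i in order)
        ev_times.extend(times.tolist())
    return EventTrain(np.array(ev_nodes, dtype=object), np.array(ev_times))


def simulate_coherent_bursts(
    n_nodes: int = 30,
    n_bursts: int = 200,
    participation: float = 0.95,
    params: "CascadeParams | None" = None,
    seed: int = 0,
) -> EventTrain:
    """Coherent, whole-population activity: every burst ignites (nearly)
    every node in a random order.

    Emulates the homogeneous-culture regime.  Because each burst lights up
    the whole network, all nodes accumulate similar strengths and edge
    endpoints carry little strength correlation, so the inferred weighted
    assortativity stays near zero.
    """
    if params is None:
        params = CascadeParams(n_bursts=n_bursts)
    rng = np.random.default_rng(seed)
    nodes = _node_names(n_nodes)
    gaps = np.maximum(
        rng.normal(
            params.inter_burst_interval_mean,
            0.1 * params.inter_burst_interval_mean,
            size=n_bursts,
        ),
        10.0 * params.delay_max,
    )
    burst_starts = np.cumsum(gaps)
    all_idx = np.arange(n_nodes)
    ev_nodes: list[str] = []
    ev_times: list[float] = []
    for t0 in burst_starts:
        firing = all_idx[rng.random(n_nodes) < participation]
        if len(firing) == 0:
            firing = all_idx[:1]
        order = rng.permutation(firing)
        lags = _truncated_delays(rng, params, len(order))
        lags[0] = 0.0
        times = t0 + np.cumsum(lags)
        ev_nodes.extend(nodes[i] for i in order)
        ev_times.extend(times.tolist())
    return EventTrain(np.array(ev_nodes, dtype=object), np.array(ev_times))


# -- fluorescence synthesis ------------------------------------------------


@dataclass
class TraceParams:
    """Shape of synthetic calcium-fluorescence transients.

    A node ignition produces a linear rise over ``rise_frames`` frames to
    ``amplitude`` (fluorescence units above baseline) followed by an
    exponential decay back to baseline with time constant ``decay_tau``
    (seconds).  White noise of ``noise_sd`` and a linear drift of
    ``drift_slope`` are added on top of ``baseline``.
    """

    frame_rate: float = 33.0  # frames / s
    rise_frames: int = 3
    decay_tau: float = 2.0  # s
    noise_sd: float = 1.0  # fluorescence units
    drift_slope: float = 0.0  # fluorescence units / s
    baseline: float = 100.0  # fluorescence units
    amplitude: float = 20.0  # transient peak height, fluorescence units

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.decay_tau * self.frame_rate <= self.rise_frames:
            raise ValueError("decay_tau must be much longer than the rise")


@dataclass
class FluorescenceMovie:
    """Frames-by-nodes trace matrix with its acquisition frame rate."""

    values: np.ndarray  # (n_frames, n_nodes)
    frame_rate: float
    node_ids: "list[str]"

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def synthesize_fluorescence(
    train: EventTrain,
    tp: "TraceParams | None" = None,
    seed: int = 0,
    node_ids: "list[str] | None" = None,
    duration: "float | None" = None,
) -> FluorescenceMovie:
    """Render an event train as fluorescence traces, one column per node.

    The recording extends 5 decay constants past the last event so every
    transient returns to baseline.  Overlapping transients sum.  An empty
    train yields baseline + drift + noise only (``node_ids`` and
    ``duration`` must then be given).
    """
    if tp is None:
        tp = TraceParams()
    if len(train) == 0 and (node_ids is None or duration is None):
        raise ValueError("empty event train needs explicit node_ids and duration")
    rng = np.random.default_rng(seed)
    if node_ids is None:
        node_ids = train.nodes
    idx = {v: i for i, v in enumerate(node_ids)}
    fps = tp.frame_rate
    t_end = (train.times[-1] + 5.0 * tp.decay_tau) if len(train) else 0.0
    if duration is not None:
        t_end = max(t_end, duration)
    n_frames = int(np.ceil(t_end * fps)) + 1
    # transient template, anchored at the onset frame
    n_tail = int(np.ceil(5.0 * tp.decay_tau * fps))
    k = np.arange(tp.rise_frames + n_tail + 1)
    template = np.where(
        k <= tp.rise_frames,
        tp.amplitude * k / tp.rise_frames,
        tp.amplitude * np.exp(-(k - tp.rise_frames) / (tp.decay_tau * fps)),
    )
    values = np.zeros((n_frames, len(node_ids)))
    # warn when the acquisition cannot resolve the closest same-node events
    for node in node_ids:
        t_node = train.times[train.node_ids == node]
        if len(t_node) > 1 and np.min(np.diff(np.sort(t_node))) < 1.0 / fps:
            warnings.warn(
                f"frame rate {fps} too low to separate events of node {node}",
                stacklevel=2,
            )
            break
    for node, t in zip(train.node_ids, train.times):
        f0 = int(np.floor(t * fps))
        hi = min(f0 + len(template), n_frames)
        values[f0:hi, idx[str(node)]] += template[: hi - f0]
    tsec = np.arange(n_frames) / fps
    values += tp.baseline + tp.drift_slope * tsec[:, None]
    if tp.noise_sd > 0:
        values += rng.normal(0.0, tp.noise_sd, size=values.shape)
    return FluorescenceMovie(values=values, frame_rate=fps, node_ids=list(node_ids))
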