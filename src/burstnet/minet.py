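"""Delayed mutual-information network construction with surrogate testing.

An alternative, model-free route to the functional network: each node's
activation train is mapped to a *walk* (the cumulative activation count per
frame), and for every ordered pair (i, j) the time-delayed mutual cross
information

    I_ij(tau) = sum_{a,b} p(a, b) ln [ p(a, b) / (p(a) q(b)) ]

is computed over a binning of the two walks, where p(a, b) is the joint
probability of walk i falling in bin a and walk j falling in bin b exactly
tau frames later.  Only the maximum I* over delays tau in [0, tau_max] is
kept.  Significance is assessed against surrogates that reshuffle node j's
per-frame firing indicators (destroying temporal correlation, preserving
the marginal count): z = (I*_obs - <I*_surr>) / rms_surr, and a pair is
significant when the one-sided Gaussian tail probability of z is below
alpha.  The network weight matrix holds z where significant, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erfc, sqrt

import numpy as np

from .core import EventTrain
from .network import DirectedWeightedNetwork


@dataclass
class MIScore:
    pair: "tuple[str, str]"
    max_mi: float  # nats
    best_delay: int  # frames
    z: float
    p_value: float
    significant: bool
    undecidable: bool = False  # zero surrogate spread


def firing_series(
    train: EventTrain, frame_rate: float, n_frames: "int | None" = None,
    node_ids: "list[str] | None" = None,
) -> "tuple[np.ndarray, list[str]]":
    """Per-frame activation counts, shape (n_nodes, n_frames)."""
    if node_ids is None:
        node_ids = train.nodes
    if n_frames is None:
        n_frames = int(np.floor(train.times[-1] * frame_rate)) + 1 if len(train) else 1
    idx = {v: i for i, v in enumerate(node_ids)}
    fire = np.zeros((len(node_ids), n_frames))
    for node, t in zip(train.node_ids, train.times):
        f = int(np.floor(t * frame_rate))
        if 0 <= f < n_frames:
            fire[idx[str(node)], f] += 1
    return fire, list(node_ids)


def build_walks(
    train: EventTrain,
    frame_rate: float,
    n_frames: "int | None" = None,
    node_ids: "list[str] | None" = None,
    kind: str = "cumulative",
) -> "tuple[np.ndarray, list[str]]":
    """Map activation trains to walks, shape (n_nodes, n_frames).

    ``kind="cumulative"`` (default): value at frame t is the node's number
    of activations at frames <= t, a nondecreasing step series.
    ``kind="indicator"``: the raw per-frame activation counts.
    """
    fire, node_ids = firing_series(train, frame_rate, n_frames, node_ids)
    if kind == "cumulative":
        return np.cumsum(fire, axis=1), node_ids
    if kind == "indicator":
        return fire, node_ids
    raise ValueError(f"unknown walk kind: {kind!r}")


def _bin_series(x: np.ndarray, n_bins: int) -> "np.ndarray | None":
    """Equal-width bin indices over the series' own range; None if constant."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return None
    b = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(np.int64), n_bins - 1)
    return b


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    n = len(bx)
    joint /= n
    joint = joint.reshape(n_bins, n_bins)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nzi, nzj = np.nonzero(joint)
    return float(
        np.sum(joint[nzi, nzj] * np.log(joint[nzi, nzj] / (px[nzi] * py[nzj])))
    )


def delayed_mi(x: np.ndarray, y: np.ndarray, tau: int, n_bins: int = 8) -> float:
    """Time-delayed mutual cross information I(x_t ; y_{t+tau}) in nats.

    Each walk is discretized into ``n_bins`` equal-width bins over its own
    range.  A constant series carries no information: I = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tau < 0 or tau >= len(x):
        raise ValueError("need 0 <= tau < n_frames")
    if n_bins < 2:
        raise ValueError("need n_bins >= 2")
    bx = _bin_series(x, n_bins)
    by = _bin_series(y, n_bins)
    if bx is None or by is None:
        return 0.0
    n = len(x) - tau
    return _mi_from_bins(bx[:n], by[tau : tau + n], n_bins)


def max_mi(
    x: np.ndarray, y: np.ndarray, tau_max: int, n_bins: int = 8
) -> "tuple[float, int]":
    """Maximize the delayed MI over tau in {0, ..., tau_max}.

    Ties resolve to the smallest delay.
    """
    if tau_max < 0:
        raise ValueError("tau_max must be >= 0")
    best_i, best_tau = -np.inf, 0
    for tau in range(tau_max + 1):
        i_tau = delayed_mi(x, y, tau, n_bins)
        if i_tau > best_i:
            best_i, best_tau = i_tau, tau
    return float(best_i), int(best_tau)


def _max_mi_binned(
    bx: "np.ndarray | None", by: "np.ndarray | None", tau_max: int, n_bins: int
) -> "tuple[float, int]":
    """max_mi on pre-binned series (fast path for surrogate loops)."""
    if bx is None or by is None:
        return 0.0, 0
    best_i, best_tau = -np.inf, 0
    n_total = len(bx)
    for tau in range(tau_max + 1):
        n = n_total - tau
        i_tau = _mi_from_bins(bx[:n], by[tau : tau + n], n_bins)
        if i_tau > best_i:
            best_i, best_tau = i_tau, tau
    return float(best_i), int(best_tau)


def surrogate_significance(
    x_fire: np.ndarray,
    y_fire: np.ndarray,
    tau_max: int = 10,
    n_bins: int = 8,
    n_surrogates: int = 200,
    alpha: float = 0.01,
    seed: "int | None" = None,
    pair: "tuple[str, str]" = ("x", "y"),
    walk_kind: str = "cumulative",
) -> MIScore:
    """Surrogate test of the delayed MI between two firing series.

    ``x_fire`` / ``y_fire`` are per-frame activation counts.  Each
    surrogate randomly permutes y's firing series before rebuilding its
    walk, so the null preserves the marginal activation statistics while
    destroying all temporal structure.  With z = (I* - <I*_surr>) / rms,
    the pair is significant when 0.5 * erfc(z / sqrt(2)) < alpha.  A zero
    surrogate spread makes significance undecidable (flagged, insignificant).
    """
    if n_surrogates < 50:
        raise ValueError("need at least 50 surrogates")
    rng = np.random.default_rng(seed)

    def to_walk(f: np.ndarray) -> np.ndarray:
        return np.cumsum(f) if walk_kind == "cumulative" else f

    x_walk = to_walk(np.asarray(x_fire, dtype=float))
    bx = _bin_series(x_walk, n_bins)
    y_fire = np.asarray(y_fire, dtype=float)
    by = _bin_series(to_walk(y_fire), n_bins)
    i_obs, best_tau = _max_mi_binned(bx, by, tau_max, n_bins)
    surr = np.empty(n_surrogates)
    for k in range(n_surrogates):
        y_perm = rng.permutation(y_fire)
        surr[k] = _max_mi_binned(
            bx, _bin_series(to_walk(y_perm), n_bins), tau_max, n_bins
        )[0]
    rms = float(surr.std())
    if rms == 0.0:
        return MIScore(pair, i_obs, best_tau, 0.0, 1.0, False, undecidable=True)
    z = (i_obs - float(surr.mean())) / rms
    p = 0.5 * erfc(z / sqrt(2.0))
    return MIScore(pair, i_obs, best_tau, float(z), float(p), bool(p < alpha))


def mi_network(
    train: EventTrain,
    frame_rate: float,
    n_frames: "int | None" = None,
    tau_max: int = 10,
    n_bins: int = 8,
    alpha: float = 0.01,
    n_surrogates: int = 200,
    seed: "int | None" = None,
    walk_kind: str = "cumulative",
) -> DirectedWeightedNetwork:
    """Functional network from pairwise surrogate-tested delayed MI.

    M_ij = z_ij for significant ordered pairs, 0 otherwise; diagonal 0.
    """
    if len(train) == 0:
        return DirectedWeightedNetwork([], np.zeros((0, 0)))
    fire, nodes = firing_series(train, frame_rate, n_frames)
    n = len(nodes)
    w = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            score = surrogate_significance(
                fire[i],
                fire[j],
                tau_max=tau_max,
                n_bins=n_bins,
                n_surrogates=n_surrogates,
                alpha=alpha,
                seed=int(rng.integers(0, 2**31 - 1)),
                pair=(nodes[i], nodes[j]),
                walk_kind=walk_kind,
            )
            if score.significant and score.z > 0:
                w[i, j] = score.z
    return DirectedWeightedNetwork(nodes, w)


def top_edge_overlap(
    mi_net_: DirectedWeightedNetwork, delay_net: DirectedWeightedNetwork
) -> float:
    """Jaccard overlap between the significant MI edge set and the equally
    sized set of top-weight edges of the delay-based network.

    The two constructions are cross-checks of each other: a high overlap
    means they identify fundamentally the same functional links.
    """
    mi_edges = {
        (mi_net_.nodes[i], mi_net_.nodes[j]) for i, j in zip(*np.nonzero(mi_net_.w))
    }
    if not mi_edges:
        return 0.0
    k = len(mi_edges)
    src, dst = np.nonzero(delay_net.w)
    weights = delay_net.w[src, dst]
    order = np.argsort(weights)[::-1][:k]
    top_edges = {(delay_net.nodes[src[t]], delay_net.nodes[dst[t]]) for t in order}
    return len(mi_edges & top_edges) / len(mi_edges | top_edges)
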