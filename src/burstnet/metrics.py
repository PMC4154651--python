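"""Topology metrics for directed weighted networks.

Assortativity here is the correlation, computed over directed edges, between
a property of the source node and a property of the target node:

* ``pearson-degree`` — Pearson correlation of (out-degree of source,
  in-degree of target); Newman's directed degree assortativity.
* ``spearman-degree`` — the same after replacing each endpoint degree by its
  mid-rank among the node-level out-degrees (sources) / in-degrees (targets).
* ``pearson-strength-weighted`` — weighted Pearson correlation of
  (out-strength of source, in-strength of target), each edge contributing
  proportionally to its weight w_e, with H = sum_e w_e:

      r^w = sum_e w_e (x_e - xbar)(y_e - ybar) /
            sqrt(sum_e w_e (x_e - xbar)^2 * sum_e w_e (y_e - ybar)^2),
      xbar = sum_e w_e x_e / H.

* ``spearman-strength-weighted`` — ranks substituted for strengths, then the
  same weighted machinery.

The rich-club curve measures the excess interconnection weight among
high-strength nodes.  Ranking nodes by total strength s = s_in + s_out, for
each threshold s_thr the club V_> holds the nodes with s > s_thr;
W(s_thr) is the weight of the subgraph spanned by V_>, and the uncorrelated
null expectation is

    W_null(s_thr) = [ (sum_{i in V_>} s_out_i)(sum_{j in V_>} s_in_j)
                      - sum_{i in V_>} s_out_i s_in_i ] / S,

with S the total network weight — i.e. each unit of out-strength lands on a
target in proportion to that target's in-strength, self-links excluded.
phi = W / W_null > 1 at high thresholds signals a rich club.  For a
symmetric network (s_in = s_out) this reduces to the undirected formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import DirectedWeightedNetwork

VARIANTS = (
    "pearson-degree",
    "spearman-degree",
    "pearson-strength-weighted",
    "spearman-strength-weighted",
)


class UndefinedAssortativityError(ValueError):
    """Endpoint series has zero variance; the correlation is undefined."""


@dataclass
class AssortativityResult:
    variant: str
    value: float
    stderr: float
    n_edges: int
    n_boot: int
    unreliable: bool = False
    n_degenerate_resamples: int = 0


@dataclass
class RichClubCurve:
    thresholds: np.ndarray
    phi: np.ndarray
    w_observed: np.ndarray
    w_null: np.ndarray
    n_nodes_above: np.ndarray


# -- edge records ----------------------------------------------------------


def edge_table(net: DirectedWeightedNetwork) -> pd.DataFrame:
    """One row per nonzero directed link, with endpoint degrees, strengths
    and node-level mid-ranks of those quantities.

    Degrees count links (weights ignored); strengths sum weights; a
    reciprocal pair yields two rows.  Rank columns are the mid-ranks of the
    source's out-quantity among all node out-quantities and of the target's
    in-quantity among all node in-quantities, as used by the Spearman
    variants.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    kout, kin = net.out_degree(), net.in_degree()
    sout, sin = net.out_strength(), net.in_strength()
    kout_rank = rankdata(kout, method="average")
    kin_rank = rankdata(kin, method="average")
    sout_rank = rankdata(sout, method="average")
    sin_rank = rankdata(sin, method="average")
    src, dst = np.nonzero(net.w)
    return pd.DataFrame(
        {
            "src": [net.nodes[i] for i in src],
            "dst": [net.nodes[j] for j in dst],
            "weight": net.w[src, dst],
            "src_out_degree": kout[src],
            "dst_in_degree": kin[dst],
            "src_out_strength": sout[src],
            "dst_in_strength": sin[dst],
            "src_out_degree_rank": kout_rank[src],
            "dst_in_degree_rank": kin_rank[dst],
            "src_out_strength_rank": sout_rank[src],
            "dst_in_strength_rank": sin_rank[dst],
        }
    )


def _endpoint_series(records: pd.DataFrame, variant: str):
    """(x, y, edge weights) for a variant; weights are 1 for degree variants."""
    w = records["weight"].to_numpy(dtype=float)
    if variant == "pearson-degree":
        x = records["src_out_degree"].to_numpy(dtype=float)
        y = records["dst_in_degree"].to_numpy(dtype=float)
        w = np.ones_like(w)
    elif variant == "spearman-degree":
        x = records["src_out_degree_rank"].to_numpy(dtype=float)
        y = records["dst_in_degree_rank"].to_numpy(dtype=float)
        w = np.ones_like(w)
    elif variant == "pearson-strength-weighted":
        x = records["src_out_strength"].to_numpy(dtype=float)
        y = records["dst_in_strength"].to_numpy(dtype=float)
    elif variant == "spearman-strength-weighted":
        x = records["src_out_strength_rank"].to_numpy(dtype=float)
        y = records["dst_in_strength_rank"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown assortativity variant: {variant!r}")
    return x, y, w


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation; raises if either series is degenerate."""
    h = w.sum()
    xbar = (w * x).sum() / h
    ybar = (w * y).sum() / h
    vx = (w * (x - xbar) ** 2).sum()
    vy = (w * (y - ybar) ** 2).sum()
    if vx <= 0 or vy <= 0:
        raise UndefinedAssortativityError(
            "zero variance of an endpoint series; assortativity undefined"
        )
    return float((w * (x - xbar) * (y - ybar)).sum() / np.sqrt(vx * vy))


def assortativity(records: pd.DataFrame, variant: str) -> float:
    """Assortativity value for one variant (see module docstring)."""
    if len(records) < 3:
        raise ValueError("need at least 3 edges")
    x, y, w = _endpoint_series(records, variant)
    return weighted_pearson(x, y, w)


def bootstrap_error(
    records: pd.DataFrame,
    variant: str,
    n_boot: int = 1000,
    seed: "int | None" = None,
) -> "tuple[float, int, bool]":
    """Bootstrap standard error of an assortativity value.

    Resamples edge records with replacement ``n_boot`` times and returns
    (stderr, number of degenerate resamples, unreliable flag).  Resamples
    with zero endpoint variance are discarded; if more than half are
    degenerate (or fewer than 2 survive) the error is flagged unreliable.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 edges")
    rng = np.random.default_rng(seed)
    x, y, w = _endpoint_series(records, variant)
    n = len(x)
    values = []
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(weighted_pearson(x[idx], y[idx], w[idx]))
        except UndefinedAssortativityError:
            n_degenerate += 1
    if len(values) < 2 or n_degenerate > n_boot // 2:
        return (float(np.std(values)) if len(values) > 1 else 0.0, n_degenerate, True)
    return float(np.std(values, ddof=1)), n_degenerate, False


def assortativity_with_error(
    records: pd.DataFrame,
    variant: str,
    n_boot: int = 1000,
    seed: "int | None" = None,
) -> AssortativityResult:
    value = assortativity(records, variant)
    stderr, n_degen, unreliable = bootstrap_error(records, variant, n_boot, seed)
    return AssortativityResult(
        variant=variant,
        value=value,
        stderr=stderr,
        n_edges=len(records),
        n_boot=n_boot,
        unreliable=unreliable,
        n_degenerate_resamples=n_degen,
    )


# -- rich club -------------------------------------------------------------


def _ranking_strength(net: DirectedWeightedNetwork, ranking: str) -> np.ndarray:
    if ranking == "total":
        return net.total_strength()
    if ranking == "in":
        return net.in_strength()
    if ranking == "out":
        return net.out_strength()
    raise ValueError(f"unknown rich-club ranking: {ranking!r}")


def rich_club_at(
    net: DirectedWeightedNetwork, s_thr: float, ranking: str = "total"
) -> "tuple[float, float, float, int]":
    """(W, W_null, phi, |V_>|) at a single strength threshold.

    phi is nan when W_null <= 0 or fewer than 2 nodes pass the threshold.
    """
    s = _ranking_strength(net, ranking)
    keep = np.flatnonzero(s > s_thr)
    n_above = len(keep)
    if n_above < 2:
        return 0.0, 0.0, float("nan"), n_above
    w_obs = float(net.w[np.ix_(keep, keep)].sum())
    sout, sin = net.out_strength()[keep], net.in_strength()[keep]
    total = net.total_weight
    w_null = float((sout.sum() * sin.sum() - (sout * sin).sum()) / total)
    phi = w_obs / w_null if w_null > 0 else float("nan")
    return w_obs, w_null, phi, n_above


def rich_club_curve(
    net: DirectedWeightedNetwork,
    n_thresholds: int = 50,
    ranking: str = "total",
    thresholds: "np.ndarray | None" = None,
) -> RichClubCurve:
    """Rich-club ratio phi(s_thr) across strength thresholds.

    Thresholds span [min node strength, max node strength] of the ranking
    variable (total strength by default).  Thresholds where fewer than two
    nodes qualify, or where the null expectation vanishes, are dropped.
    """
    if net.n_nodes < 5:
        raise ValueError("need at least 5 nodes for a rich-club curve")
    s = _ranking_strength(net, ranking)
    if thresholds is None:
        thresholds = np.linspace(s.min(), s.max(), n_thresholds)
    rows = [rich_club_at(net, t, ranking) for t in thresholds]
    keep = np.array([np.isfinite(r[2]) for r in rows])
    return RichClubCurve(
        thresholds=np.asarray(thresholds)[keep],
        phi=np.array([r[2] for r in rows])[keep],
        w_observed=np.array([r[0] for r in rows])[keep],
        w_null=np.array([r[1] for r in rows])[keep],
        n_nodes_above=np.array([r[3] for r in rows])[keep],
    )


def sampled_rich_club_null(
    net: DirectedWeightedNetwork,
    s_thr: float,
    n_samples: int = 200,
    n_quanta: int = 2000,
    ranking: str = "total",
    seed: "int | None" = None,
) -> float:
    """Empirical uncorrelated-null club weight, by Monte-Carlo rewiring.

    Redistributes the total network weight S as ``n_quanta`` equal quanta,
    each assigned a source in proportion to out-strength and a target in
    proportion to in-strength (self-assignments rejected), and measures the
    club weight of the nodes above ``s_thr``.  Serves as a cross-check of
    the analytic null expectation.
    """
    rng = np.random.default_rng(seed)
    s = _ranking_strength(net, ranking)
    keep = np.flatnonzero(s > s_thr)
    in_club = np.zeros(net.n_nodes, dtype=bool)
    in_club[keep] = True
    sout, sin = net.out_strength(), net.in_strength()
    p_src = sout / sout.sum()
    p_dst = sin / sin.sum()
    quantum = net.total_weight / n_quanta
    w_vals = np.empty(n_samples)
    for k in range(n_samples):
        src = rng.choice(net.n_nodes, size=n_quanta, p=p_src)
        dst = rng.choice(net.n_nodes, size=n_quanta, p=p_dst)
        ok = src != dst
        # redraw self-assignments until none remain
        while not ok.all():
            bad = np.flatnonzero(~ok)
            dst[bad] = rng.choice(net.n_nodes, size=len(bad), p=p_dst)
            ok = src != dst
        w_vals[k] = quantum * np.count_nonzero(in_club[src] & in_club[dst])
    return float(w_vals.mean())


# -- summaries -------------------------------------------------------------


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_strength: float


@dataclass
class MetricReport:
    summary: NetworkSummary
    assortativity: "dict[str, AssortativityResult]"
    rich_club: "RichClubCurve | None"


def network_summary(net: DirectedWeightedNetwork) -> NetworkSummary:
    """Counts block only: nodes, directed links, average degree (links per
    node) and average strength (total link weight per node)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        average_degree=net.n_edges / net.n_nodes,
        average_strength=net.total_weight / net.n_nodes,
    )


def summarize_network(
    net: DirectedWeightedNetwork,
    n_boot: int = 1000,
    n_thresholds: int = 50,
    seed: "int | None" = None,
) -> MetricReport:
    """Table-style summary: counts, average degree/strength, all four
    assortativity variants with bootstrap errors, and the rich-club curve.

    Average degree is edges per node (directed links / nodes); average
    strength is total link weight per node.
    """
    summary = network_summary(net)
    records = edge_table(net)
    assort: dict[str, AssortativityResult] = {}
    rng = np.random.default_rng(seed)
    for variant in VARIANTS:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            assort[variant] = assortativity_with_error(
                records, variant, n_boot=n_boot, seed=sub_seed
            )
        except (UndefinedAssortativityError, ValueError) as exc:
            assort[variant] = AssortativityResult(
                variant=variant,
                value=float("nan"),
                stderr=float("nan"),
                n_edges=len(records),
                n_boot=0,
                unreliable=True,
            )
    rich = rich_club_curve(net, n_thresholds=n_thresholds) if net.n_nodes >= 5 else None
    return MetricReport(summary=summary, assortativity=assort, rich_club=rich)
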