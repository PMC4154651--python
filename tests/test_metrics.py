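"""Assortativity variants, bootstrap errors, rich-club curve and summaries."""

import numpy as np
import pytest

import burstnet as bn
from burstnet.metrics import (
    VARIANTS,
    UndefinedAssortativityError,
    rich_club_at,
    sampled_rich_club_null,
    weighted_pearson,
)


def net_from_edges(edges, nodes=None):
    return bn.DirectedWeightedNetwork.from_edges(edges, nodes)


def brute_force_assortativity(net, variant):
    """Naive oracle: explicit loops over edges, no shared machinery."""
    from scipy.stats import rankdata

    n = net.n_nodes
    kout = [(net.w[i] > 0).sum() for i in range(n)]
    kin = [(net.w[:, j] > 0).sum() for j in range(n)]
    sout = [net.w[i].sum() for i in range(n)]
    sin = [net.w[:, j].sum() for j in range(n)]
    if "degree" in variant:
        xsrc, ydst = kout, kin
    else:
        xsrc, ydst = sout, sin
    if variant.startswith("spearman"):
        xsrc = list(rankdata(xsrc))
        ydst = list(rankdata(ydst))
    xs, ys, ws = [], [], []
    for i in range(n):
        for j in range(n):
            if net.w[i, j] > 0:
                xs.append(xsrc[i])
                ys.append(ydst[j])
                ws.append(net.w[i, j] if "weighted" in variant else 1.0)
    h = sum(ws)
    xb = sum(w * x for w, x in zip(ws, xs)) / h
    yb = sum(w * y for w, y in zip(ws, ys)) / h
    cov = sum(w * (x - xb) * (y - yb) for w, x, y in zip(ws, xs, ys))
    vx = sum(w * (x - xb) ** 2 for w, x in zip(ws, xs))
    vy = sum(w * (y - yb) ** 2 for w, y in zip(ws, ys))
    return cov / np.sqrt(vx * vy)


class TestEdgeTable:
    def test_single_link_record(self):
        net = net_from_edges([("a", "b", 3.0)])
        rec = bn.edge_table(net)
        assert len(rec) == 1
        row = rec.iloc[0]
        assert row["src_out_strength"] == 3.0
        assert row["dst_in_strength"] == 3.0
        assert row["src_out_degree"] == 1 and row["dst_in_degree"] == 1

    def test_reciprocal_pair_yields_two_records(self):
        rec = bn.edge_table(net_from_edges([("a", "b", 1.0), ("b", "a", 2.0)]))
        assert len(rec) == 2

    def test_complete_three_node_digraph_has_six_records(self):
        edges = [(a, b, 1.0) for a in "abc" for b in "abc" if a != b]
        assert len(bn.edge_table(net_from_edges(edges))) == 6


class TestAssortativity:
    def test_uniform_ring_is_undefined(self):
        nodes = [f"n{i}" for i in range(6)]
        edges = [(nodes[i], nodes[(i + 1) % 6], 1.0) for i in range(6)]
        rec = bn.edge_table(net_from_edges(edges, nodes))
        for variant in VARIANTS:
            with pytest.raises(UndefinedAssortativityError):
                bn.assortativity(rec, variant)

    def test_equal_strength_dyads_are_perfectly_assortative(self):
        edges = [("a", "b", 10.0), ("b", "a", 10.0),
                 ("c", "d", 1.0), ("d", "c", 1.0)]
        rec = bn.edge_table(net_from_edges(edges))
        r = bn.assortativity(rec, "pearson-strength-weighted")
        assert r == pytest.approx(1.0)

    def test_random_iid_weights_are_neutral_within_error(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i:02d}" for i in range(50)]
        seen = set()
        edges = []
        while len(edges) < 400:
            i, j = rng.integers(0, 50, 2)
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                edges.append((nodes[i], nodes[j], float(rng.exponential())))
        rec = bn.edge_table(net_from_edges(edges, nodes))
        r = bn.assortativity(rec, "pearson-strength-weighted")
        stderr, _, _ = bn.bootstrap_error(rec, "pearson-strength-weighted",
                                          n_boot=300, seed=1)
        assert abs(r) < 3 * stderr

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_brute_force_oracle_on_random_digraphs(self, variant):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 8))
            n_edges = int(rng.integers(3, 11))
            nodes = [f"n{i}" for i in range(n)]
            seen = set()
            edges = []
            for _ in range(n_edges):
                i, j = rng.integers(0, n, 2)
                if i != j and (i, j) not in seen:
                    seen.add((i, j))
                    edges.append((nodes[i], nodes[j], float(rng.lognormal())))
            if len(edges) < 3:
                continue
            net = net_from_edges(edges, nodes)
            rec = bn.edge_table(net)
            try:
                got = bn.assortativity(rec, variant)
            except UndefinedAssortativityError:
                continue
            expected = brute_force_assortativity(net, variant)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
            checked += 1

    def test_unweighted_degree_variant_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        w = (rng.random((20, 20)) < 0.2).astype(float)
        np.fill_diagonal(w, 0)
        net = bn.DirectedWeightedNetwork([f"n{i}" for i in range(20)], w)
        rec = bn.edge_table(net)
        r = bn.assortativity(rec, "pearson-degree")
        expected = nx.degree_assortativity_coefficient(
            net.to_networkx(), x="out", y="in"
        )
        assert r == pytest.approx(expected, rel=1e-9)

    def test_equal_weights_reduce_to_unweighted_strength_correlation(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(12)]
        seen, edges = set(), []
        while len(edges) < 30:
            i, j = rng.integers(0, 12, 2)
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                edges.append((nodes[i], nodes[j], 2.5))  # all equal
        rec = bn.edge_table(net_from_edges(edges, nodes))
        weighted = bn.assortativity(rec, "pearson-strength-weighted")
        x = rec["src_out_strength"].to_numpy()
        y = rec["dst_in_strength"].to_numpy()
        plain = np.corrcoef(x, y)[0, 1]
        assert weighted == pytest.approx(plain, rel=1e-12)


class TestBootstrapError:
    def test_fixed_seed_reproduces_stderr(self, small_random_net):
        rec = bn.edge_table(small_random_net)
        a = bn.bootstrap_error(rec, "pearson-strength-weighted", 200, seed=5)
        b = bn.bootstrap_error(rec, "pearson-strength-weighted", 200, seed=5)
        assert a == b

    def test_resampling_variability_gives_positive_stderr(self, small_random_net):
        rec = bn.edge_table(small_random_net)
        stderr, _, unreliable = bn.bootstrap_error(
            rec, "pearson-strength-weighted", 300, seed=2
        )
        assert stderr > 0 and not unreliable

    def test_single_resample_flagged_unreliable(self, small_random_net):
        rec = bn.edge_table(small_random_net)
        stderr, _, unreliable = bn.bootstrap_error(
            rec, "pearson-strength-weighted", 1, seed=2
        )
        assert unreliable
        assert stderr == 0.0


class TestRichClub:
    def test_threshold_below_minimum_covers_whole_graph(self, small_random_net):
        net = small_random_net
        w_obs, w_null, phi, n_above = rich_club_at(net, -1.0)
        assert n_above == net.n_nodes
        assert w_obs == pytest.approx(net.total_weight)

    def test_uncorrelated_network_has_phi_near_one(self):
        rng = np.random.default_rng(0)
        n = 50
        sout = rng.lognormal(1, 0.6, n)
        sin = rng.lognormal(1, 0.6, n)
        w = np.outer(sout, sin) / sout.sum()
        np.fill_diagonal(w, 0)
        net = bn.DirectedWeightedNetwork([f"n{i:02d}" for i in range(n)], w)
        curve = bn.rich_club_curve(net, n_thresholds=20)
        assert np.all(np.abs(curve.phi - 1.0) < 0.1)

    def test_interlinked_top_nodes_show_phi_above_one(self):
        # 6 nodes: a,b,c form a strong triangle; d,e,f hang off weakly
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0),
                 ("b", "a", 1.0), ("c", "b", 1.0), ("a", "c", 1.0),
                 ("d", "a", 0.1), ("e", "b", 0.1), ("f", "c", 0.1)]
        net = net_from_edges(edges)
        s = net.total_strength()
        thr = np.sort(s)[-4] + 1e-9  # keep only the triangle
        w_obs, w_null, phi, n_above = rich_club_at(net, thr)
        assert n_above == 3
        # hand computation: club weight 6.0; null = (sum_out*sum_in - sum oi)/S
        keep = np.argsort(s)[-3:]
        so, si = net.out_strength()[keep], net.in_strength()[keep]
        expected_null = (so.sum() * si.sum() - (so * si).sum()) / net.total_weight
        assert w_obs == pytest.approx(6.0)
        assert w_null == pytest.approx(expected_null)
        assert phi > 1.0

    def test_symmetric_network_reduces_to_undirected_form(self):
        rng = np.random.default_rng(6)
        n = 12
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        w = (w + w.T) / 2  # symmetric
        np.fill_diagonal(w, 0)
        net = bn.DirectedWeightedNetwork([f"n{i}" for i in range(n)], w)
        s_und = w.sum(axis=1)  # undirected strength
        thr = np.median(s_und + s_und)
        w_obs, w_null, phi, _ = rich_club_at(net, thr)
        keep = np.flatnonzero(s_und + s_und > thr)
        # undirected null: [ (sum s)^2 - sum s^2 ] / S_total with s = s_in = s_out
        su = s_und[keep]
        expected = (su.sum() ** 2 - (su**2).sum()) / w.sum()
        assert w_null == pytest.approx(expected)

    def test_analytic_null_matches_monte_carlo_rewiring(self):
        rng = np.random.default_rng(0)
        n = 50
        sout = rng.lognormal(1, 0.6, n)
        sin = rng.lognormal(1, 0.6, n)
        w = np.outer(sout, sin) / sout.sum()
        np.fill_diagonal(w, 0)
        net = bn.DirectedWeightedNetwork([f"n{i:02d}" for i in range(n)], w)
        thr = float(np.quantile(net.total_strength(), 0.6))
        _, w_null, _, _ = rich_club_at(net, thr)
        empirical = sampled_rich_club_null(
            net, thr, n_samples=100, n_quanta=5000, seed=1
        )
        assert abs(empirical - w_null) / w_null < 0.05


class TestSummarizeNetwork:
    @pytest.mark.parametrize(
        "n_nodes,n_edges,expected",
        [(38, 544, 14.32), (17, 116, 6.82)],
    )
    def test_average_degree_matches_reported_two_decimals(
        self, n_nodes, n_edges, expected
    ):
        rng = np.random.default_rng(n_edges)
        nodes = [f"n{i:03d}" for i in range(n_nodes)]
        seen, edges = set(), []
        while len(edges) < n_edges:
            i, j = rng.integers(0, n_nodes, 2)
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                edges.append((nodes[i], nodes[j], float(rng.exponential())))
        net = net_from_edges(edges, nodes)
        report = bn.summarize_network(net, n_boot=50, seed=0)
        assert round(report.summary.average_degree, 2) == expected

    def test_single_link_summary(self):
        net = net_from_edges([("a", "b", 5.0)])
        report = bn.summarize_network(net, n_boot=50, seed=0)
        assert report.summary.average_degree == pytest.approx(0.5)
        assert report.summary.average_strength == pytest.approx(2.5)
        assert report.rich_club is None  # fewer than 5 nodes


def test_weighted_pearson_rejects_zero_variance():
    x = np.ones(5)
    y = np.arange(5.0)
    with pytest.raises(UndefinedAssortativityError):
        weighted_pearson(x, y, np.ones(5))
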