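"""Burst segmentation, lag fitting, network construction, VI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstnet as bn
from burstnet.core import InsufficientDataError, consecutive_lags


def make_train(times, nodes=None):
    times = np.asarray(times, dtype=float)
    if nodes is None:
        nodes = [f"n{i}" for i in range(len(times))]
    return bn.EventTrain(np.array(nodes, dtype=object), times)


class TestSegmentBursts:
    def test_gap_rule_splits_at_cutoff(self):
        train = make_train([0.0, 0.05, 0.10, 0.50, 0.55])
        bursts = bn.segment_bursts(train, cutoff=0.2)
        assert [len(b) for b in bursts] == [3, 2]
        assert np.allclose(bursts[0].times, [0.0, 0.05, 0.10])
        assert np.allclose(bursts[1].times, [0.50, 0.55])

    def test_single_event_is_singleton_burst(self):
        bursts = bn.segment_bursts(make_train([1.0]), cutoff=0.2)
        assert len(bursts) == 1 and len(bursts[0]) == 1

    def test_gap_equal_to_cutoff_stays_within_burst(self):
        train = make_train([0.0, 0.2, 0.4])
        assert len(bn.segment_bursts(train, cutoff=0.2)) == 1

    def test_empty_train_gives_no_bursts(self):
        empty = bn.EventTrain(np.array([], dtype=object), np.array([]))
        assert bn.segment_bursts(empty, 0.2) == []

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=0, max_size=40),
        st.floats(0.01, 5),
    )
    def test_partition_conserves_events(self, times, cutoff):
        train = make_train(sorted(times), nodes=["x"] * len(times))
        bursts = bn.segment_bursts(train, cutoff)
        assert sum(len(b) for b in bursts) == len(train)
        # maximality: gaps between neighboring bursts exceed the cutoff
        for b1, b2 in zip(bursts[:-1], bursts[1:]):
            assert b2.start - b1.end > cutoff


class TestLagModel:
    def test_constant_lags_give_sigma_equal_to_lag(self):
        train = make_train([0.0, 0.03, 0.06, 0.09, 0.12, 0.15,
                            10.0, 10.03, 10.06, 10.09, 10.12, 10.15])
        model = bn.fit_lag_model(bn.segment_bursts(train, 0.2))
        assert model.sigma == pytest.approx(0.03)

    def test_two_lag_hand_computation(self):
        # sigma = sqrt((0.03^2 + 0.04^2)/2) on lags {0.03, 0.04}, padded to
        # reach the minimum lag count with equal repeats
        lags = [0.03, 0.04] * 5
        times = np.concatenate([[100.0 * k, 100.0 * k + lag] for k, lag in enumerate(lags)])
        train = make_train(times, nodes=["a", "b"] * len(lags))
        model = bn.fit_lag_model(bn.segment_bursts(train, 0.2))
        assert model.sigma == pytest.approx(np.sqrt((0.0009 + 0.0016) / 2), rel=1e-12)
        assert model.sigma == pytest.approx(0.03536, abs=5e-6)

    def test_half_normal_monte_carlo_consistency(self):
        rng = np.random.default_rng(11)
        lags = np.abs(rng.normal(0, 0.02, 10_000))
        starts = np.arange(len(lags)) * 100.0
        times = np.concatenate([starts, starts + lags])
        nodes = ["a"] * len(lags) + ["b"] * len(lags)
        train = make_train(times, nodes=nodes)
        model = bn.fit_lag_model(bn.segment_bursts(train, 1.0))
        assert 0.0195 <= model.sigma <= 0.0205

    def test_histogram_fit_agrees_with_mle_on_half_normal(self):
        rng = np.random.default_rng(5)
        lags = np.abs(rng.normal(0, 0.03, 5000))
        starts = np.arange(len(lags)) * 100.0
        times = np.concatenate([starts, starts + lags])
        train = make_train(times, nodes=["a"] * len(lags) + ["b"] * len(lags))
        bursts = bn.segment_bursts(train, 1.0)
        m1 = bn.fit_lag_model(bursts, method="mle")
        m2 = bn.fit_lag_model(bursts, method="histogram")
        assert m2.sigma == pytest.approx(m1.sigma, rel=0.15)

    def test_too_few_lags_raises_with_count(self):
        train = make_train([0.0, 0.03])
        with pytest.raises(InsufficientDataError, match="1"):
            bn.fit_lag_model(bn.segment_bursts(train, 0.2))


class TestGaussianWeight:
    def test_closed_forms(self):
        assert bn.gaussian_weight(0.0, 0.05) == 1.0
        assert bn.gaussian_weight(0.05, 0.05) == pytest.approx(np.exp(-0.5))
        assert bn.gaussian_weight(0.10, 0.05) == pytest.approx(np.exp(-2.0))

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            bn.gaussian_weight(-0.01, 0.05)

    @given(st.floats(1e-4, 1.0), st.floats(0, 3), st.floats(0.01, 1))
    def test_strictly_decreasing_in_dt(self, sigma, u, eps):
        # delays expressed in units of sigma, staying clear of underflow
        dt = u * sigma
        assert bn.gaussian_weight(dt + eps * sigma, sigma) < bn.gaussian_weight(
            dt, sigma
        )


def brute_force_network(bursts, sigma, cutoff):
    """Independent oracle: exhaustive all-pairs enumeration."""
    weights: dict = {}
    nodes = set()
    for b in bursts:
        first = {}
        for n, t in zip(b.node_ids, b.times):
            if n not in first:
                first[n] = t
        nodes.update(first)
        for a in first:
            for c in first:
                if a == c:
                    continue
                dt = first[c] - first[a]
                if dt == 0.0:
                    weights[(a, c)] = weights.get((a, c), 0.0) + 1.0
                elif 0 < dt <= cutoff:
                    weights[(a, c)] = weights.get((a, c), 0.0) + np.exp(
                        -(dt**2) / (2 * sigma**2)
                    )
    return sorted(nodes), weights


class TestBuildFunctionalNetwork:
    def test_single_burst_links_all_later_pairs_forward_only(
        self, three_node_burst_train
    ):
        bursts = bn.segment_bursts(three_node_burst_train, 0.2)
        model = bn.LagModel(lags=np.array([]), sigma=0.05, fit_method="fixed", cutoff=0.2)
        net = bn.build_functional_network(bursts, model, 0.2)
        g = lambda dt: np.exp(-(dt**2) / (2 * 0.05**2))
        i = {n: k for k, n in enumerate(net.nodes)}
        assert net.w[i["a"], i["b"]] == pytest.approx(g(0.03))
        assert net.w[i["a"], i["c"]] == pytest.approx(g(0.08))
        assert net.w[i["b"], i["c"]] == pytest.approx(g(0.05))
        # no reverse links
        assert net.w[i["b"], i["a"]] == 0
        assert net.w[i["c"], i["a"]] == 0
        assert net.w[i["c"], i["b"]] == 0

    def test_repeated_sequence_reinforces_additively(self):
        k, delta = 7, 0.04
        times = np.concatenate([[100.0 * j, 100.0 * j + delta] for j in range(k)])
        train = make_train(times, nodes=["a", "b"] * k)
        bursts = bn.segment_bursts(train, 0.2)
        model = bn.LagModel(np.array([]), sigma=0.05, fit_method="fixed", cutoff=0.2)
        net = bn.build_functional_network(bursts, model, 0.2)
        i = {n: j for j, n in enumerate(net.nodes)}
        assert net.w[i["a"], i["b"]] == pytest.approx(k * np.exp(-(delta**2) / 0.005))

    def test_simultaneous_pairs_become_bidirectional_unit_links(self):
        k = 5
        times = np.repeat(np.arange(k) * 100.0, 2)
        train = make_train(times, nodes=["a", "b"] * k)
        bursts = bn.segment_bursts(train, 0.2)
        model = bn.LagModel(np.array([]), sigma=0.05, fit_method="fixed", cutoff=0.2)
        net = bn.build_functional_network(bursts, model, 0.2)
        i = {n: j for j, n in enumerate(net.nodes)}
        assert net.w[i["a"], i["b"]] == k
        assert net.w[i["b"], i["a"]] == k

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_matches_brute_force_on_small_trains(self, data):
        n_events = data.draw(st.integers(1, 5))
        times = sorted(
            data.draw(
                st.lists(
                    st.sampled_from([0.0, 0.01, 0.05, 0.1, 0.15, 0.3, 1.0]),
                    min_size=n_events,
                    max_size=n_events,
                )
            )
        )
        nodes = data.draw(
            st.lists(st.sampled_from(["a", "b", "c"]), min_size=n_events,
                     max_size=n_events)
        )
        train = make_train(times, nodes=nodes)
        cutoff, sigma = 0.2, 0.05
        bursts = bn.segment_bursts(train, cutoff)
        model = bn.LagModel(np.array([]), sigma=sigma, fit_method="fixed", cutoff=cutoff)
        net = bn.build_functional_network(bursts, model, cutoff)
        oracle_nodes, oracle_w = brute_force_network(bursts, sigma, cutoff)
        assert net.nodes == oracle_nodes
        for (a, c), w in oracle_w.items():
            assert net.w[net.nodes.index(a), net.nodes.index(c)] == pytest.approx(w)
        assert net.total_weight == pytest.approx(sum(oracle_w.values()))

    def test_total_weight_bounded_by_pair_count(self, planted_net):
        sim = bn.simulate_bursts(planted_net, bn.CascadeParams(n_bursts=50), seed=3)
        net, _, bursts = bn.infer_network(sim.train)
        bound = sum(len(set(map(str, b.node_ids))) * (len(set(map(str, b.node_ids))) - 1)
                    for b in bursts)
        assert net.total_weight <= bound + 1e-9


class TestVariationOfInformation:
    def test_identical_partitions_have_zero_distance(self):
        p = [[1, 2], [3], [4, 5, 6]]
        assert bn.variation_of_information(p, p) == 0.0

    def test_pairs_versus_singletons_closed_form(self):
        vi = bn.variation_of_information([[1, 2], [3, 4]], [[1], [2], [3], [4]])
        assert vi == pytest.approx(np.log(2), rel=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_symmetry(self, data):
        n = data.draw(st.integers(2, 12))
        la = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        lb = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        pa = [[i for i in range(n) if la[i] == g] for g in set(la)]
        pb = [[i for i in range(n) if lb[i] == g] for g in set(lb)]
        ab = bn.variation_of_information(pa, pb)
        ba = bn.variation_of_information(pb, pa)
        assert ab == pytest.approx(ba)
        assert ab >= 0

    def test_sklearn_oracle_agreement(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(2)
        la = rng.integers(0, 4, 60)
        lb = rng.integers(0, 3, 60)
        pa = [list(np.flatnonzero(la == g)) for g in range(4)]
        pb = [list(np.flatnonzero(lb == g)) for g in range(3)]
        pa = [g for g in pa if g]
        pb = [g for g in pb if g]

        def entropy(labels):
            _, c = np.unique(labels, return_counts=True)
            p = c / c.sum()
            return -np.sum(p * np.log(p))

        expected = entropy(la) + entropy(lb) - 2 * mutual_info_score(la, lb)
        assert bn.variation_of_information(pa, pb) == pytest.approx(expected)

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValueError):
            bn.variation_of_information([[1, 2]], [[1], [3]])


class TestCutoffSensitivity:
    def test_bimodal_gap_structure_stabilizes_past_true_scale(self):
        # consecutive lags ~30 ms within bursts, ~30 s between bursts
        rng = np.random.default_rng(4)
        times, t = [], 0.0
        for _ in range(40):
            t += 30.0 + rng.normal(0, 1)
            for lag in np.abs(rng.normal(0.03, 0.01, 5)):
                times.append(t)
                t += lag
        train = make_train(np.sort(times), nodes=["x"] * len(times))
        grid = np.arange(0.05, 0.55, 0.05)
        scan = bn.cutoff_sensitivity(train, grid)
        plateau_region = scan.vi[(grid[:-1] >= 0.15) & (grid[:-1] <= 0.30)]
        assert np.all(plateau_region == 0.0)
        assert scan.plateau_cutoff is not None and scan.plateau_cutoff <= 0.15

    def test_identical_partitions_everywhere_give_zero_vi(self):
        train = make_train([0.0, 0.01, 50.0, 50.01], nodes=list("abab"))
        scan = bn.cutoff_sensitivity(train, [0.1, 0.2, 0.3])
        assert np.all(scan.vi == 0.0)

    def test_two_point_grid_yields_single_value(self):
        train = make_train([0.0, 0.1, 0.4], nodes=list("abc"))
        scan = bn.cutoff_sensitivity(train, [0.05, 0.3])
        assert len(scan.vi) == 1

    def test_network_edge_sets_identical_across_plateau(self, planted_net):
        sim = bn.simulate_bursts(planted_net, bn.CascadeParams(n_bursts=100), seed=9)
        edge_sets = []
        for cutoff in (0.15, 0.2, 0.25, 0.3):
            net, _, _ = bn.infer_network(sim.train, cutoff=cutoff)
            src, dst = np.nonzero(net.w)
            edge_sets.append({(net.nodes[i], net.nodes[j]) for i, j in zip(src, dst)})
        assert all(s == edge_sets[0] for s in edge_sets[1:])
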