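import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icemoor import synthetic
from icemoor.network import (
    build_network,
    fdr_adjust,
    group_connectivity,
    is_disrupted,
    oscillation_signal,
    regularize_series,
    robust_threshold,
    signal_correlations,
    signals_from_series,
)


def edges_from_graph(graph: nx.Graph, r: float = 0.8) -> pd.DataFrame:
    rows = [(min(a, b), max(a, b), r, 1e-8, 1e-6) for a, b in graph.edges()]
    return pd.DataFrame(rows, columns=["asv_i", "asv_j", "r", "p_raw", "p_adj"])


class TestRegularize:
    def test_regular_weekly_series_unchanged(self):
        dates = pd.date_range("2020-01-01", periods=30, freq="7D")
        values = np.sin(np.arange(30))
        grid, out = regularize_series(dates, values)
        np.testing.assert_allclose(out, values)
        assert len(grid) == 30

    def test_linear_midpoint(self):
        dates = pd.to_datetime(
            ["2020-01-01", "2020-01-15", "2020-07-15", "2020-07-29"]
        )
        grid, out = regularize_series(dates, [0.0, 1.0, 1.0, 0.0])
        assert out[1] == pytest.approx(0.5)  # midpoint of the 14-day gap

    def test_interpolation_stays_within_observed_range(self, rng):
        for _ in range(100):
            n = rng.integers(5, 20)
            days = np.sort(rng.choice(np.arange(0, 400), size=n, replace=False))
            dates = pd.Timestamp("2020-01-01") + pd.to_timedelta(days, unit="D")
            values = rng.normal(size=n)
            _, out = regularize_series(dates, values)
            assert out.min() >= values.min() - 1e-12
            assert out.max() <= values.max() + 1e-12

    def test_too_few_or_too_short(self):
        short = pd.date_range("2020-01-01", periods=3, freq="7D")
        with pytest.raises(ValueError):
            regularize_series(short, [1, 2, 3])
        narrow = pd.date_range("2020-01-01", periods=6, freq="7D")
        with pytest.raises(ValueError):
            regularize_series(narrow, np.arange(6))


class TestOscillationSignal:
    def test_pure_cosine_concentrates_in_first_harmonic(self):
        t = np.arange(52)
        series = 3.5 * np.cos(2 * np.pi * t / 52)
        sig = oscillation_signal(series)
        assert sig.amplitudes[0] == pytest.approx(3.5, rel=1e-9)
        assert np.all(sig.amplitudes[1:] < 1e-9)

    def test_constant_series_has_zero_amplitudes(self):
        sig = oscillation_signal(np.full(52, 7.0))
        assert np.all(sig.amplitudes == 0)

    def test_cos_vs_sin_quarter_period_phase_shift(self):
        t = np.arange(52)
        sig_cos = oscillation_signal(np.cos(2 * np.pi * t / 52))
        sig_sin = oscillation_signal(np.sin(2 * np.pi * t / 52))
        assert sig_cos.amplitudes[0] == pytest.approx(sig_sin.amplitudes[0])
        delta = abs(sig_cos.phases[0] - sig_sin.phases[0])
        assert delta == pytest.approx(np.pi / 2, abs=1e-9)

    def test_agrees_with_direct_dft_oracle(self, rng):
        series = rng.normal(size=52)
        sig = oscillation_signal(series, n_harmonics=4)
        x = series - series.mean()
        n = len(x)
        for k in range(1, 5):
            coeff = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
            assert sig.amplitudes[k - 1] == pytest.approx(2 * abs(coeff) / n)
            assert sig.phases[k - 1] == pytest.approx(np.angle(coeff))

    def test_parseval_consistency(self, rng):
        series = rng.normal(size=52)
        sig = oscillation_signal(series, n_harmonics=6)
        # retained sinusoid power (a^2/2 each) cannot exceed total variance
        assert np.sum(sig.amplitudes**2) / 2 <= series.var() * (1 + 1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            oscillation_signal(np.arange(10), n_harmonics=6)


class TestSignalCorrelations:
    def test_identical_signals_correlate_perfectly(self, rng):
        x = rng.normal(size=52)
        series = pd.DataFrame([x, x], index=["a", "b"])
        edges = signal_correlations(signals_from_series(series))
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_signal_anticorrelates(self, rng):
        x = rng.normal(size=52)
        series = pd.DataFrame([x, -x], index=["a", "b"])
        edges = signal_correlations(signals_from_series(series))
        assert edges["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_signal_skipped(self, rng):
        series = pd.DataFrame(
            [rng.normal(size=52), np.full(52, 3.0), rng.normal(size=52)],
            index=["a", "flat", "c"],
        )
        edges = signal_correlations(signals_from_series(series))
        assert "flat" not in set(edges["asv_i"]) | set(edges["asv_j"])
        assert len(edges) == 1

    def test_co_oscillating_pairs_exceed_strong_threshold(self):
        wins = 0
        for seed in range(20):
            series, truth = synthetic.generate_oscillating_pairs(
                n_cooc_pairs=1, n_indep_pairs=0, n_years=1, noise_sd=0.1, seed=seed
            )
            edges = signal_correlations(signals_from_series(series))
            if edges["r"].iloc[0] > 0.7:
                wins += 1
        assert wins >= 18  # >= 90% of seeds

    def test_permutation_p_close_to_t_approximation(self, rng):
        series = pd.DataFrame(rng.normal(size=(4, 52)), index=list("abcd"))
        sigs = signals_from_series(series)
        t_edges = signal_correlations(sigs, method="t")
        perm_edges = signal_correlations(sigs, method="permutation", seed=3)
        # same ordering of evidence, seeded and reproducible
        assert (perm_edges["p_raw"] > 0).all()
        again = signal_correlations(sigs, method="permutation", seed=3)
        pd.testing.assert_frame_equal(perm_edges, again)
        assert np.corrcoef(t_edges["r"], perm_edges["r"])[0, 1] == pytest.approx(1.0)


class TestFdrAdjust:
    def test_hand_applied_benjamini_hochberg(self):
        adjusted = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_agrees_with_stepup_oracle(self, rng):
        p = rng.uniform(size=40)
        adjusted = fdr_adjust(p)
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1)
        np.testing.assert_allclose(adjusted, expect, atol=1e-12)
        assert (adjusted >= p).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjustment_preserves_ranks_and_bounds(self, p):
        adjusted = fdr_adjust(p)
        assert (adjusted <= 1).all()
        assert (adjusted >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestRobustThreshold:
    def test_triangle_is_robust_at_its_edge_strength(self):
        edges = edges_from_graph(nx.cycle_graph(3), r=0.8)
        assert robust_threshold(edges) == pytest.approx(0.80)

    def test_path_graph_never_qualifies(self):
        edges = edges_from_graph(nx.path_graph(["a", "b", "c"]), r=0.9)
        assert robust_threshold(edges) is None

    def test_planted_biconnected_core_with_pendants(self):
        edges = synthetic.planted_robustness_edges(seed=2)
        assert robust_threshold(edges) == pytest.approx(0.70)
        # below the core strength the pendant anchors are cut vertices
        from icemoor.network import _graph_at

        assert is_disrupted(_graph_at(edges, 0.5, 0.05))

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError):
            robust_threshold(pd.DataFrame(columns=["asv_i", "asv_j", "r", "p_adj"]))

    def test_articulation_detection_matches_node_deletion_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 26))
            g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.4), seed=int(rng.integers(2**31)))
            giant_nodes = max(nx.connected_components(g), key=len)
            giant = g.subgraph(giant_nodes).copy()
            if giant.number_of_nodes() < 3:
                continue
            brute = any(
                nx.number_connected_components(
                    giant.subgraph(set(giant) - {v})
                ) > 1
                for v in giant
            )
            assert is_disrupted(g) == brute


class TestBuildNetwork:
    def test_star_center_carries_all_betweenness(self):
        net = build_network(edges_from_graph(nx.star_graph(4)), 0.5)
        stats = net.node_stats
        assert stats.loc[0, "betweenness"] == pytest.approx(1.0)
        assert np.allclose(stats.drop(index=0)["betweenness"], 0.0)
        assert stats.loc[0, "degree"] == 4

    def test_complete_graph_has_no_betweenness(self):
        net = build_network(edges_from_graph(nx.complete_graph(6)), 0.5)
        assert np.allclose(net.node_stats["betweenness"], 0.0)

    def test_betweenness_matches_brute_force_shortest_paths(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=7)
        net = build_network(edges_from_graph(g), 0.5)
        # brute-force oracle: enumerate all shortest paths per pair
        nodes = list(g.nodes)
        accum = {v: 0.0 for v in nodes}
        for i, s in enumerate(nodes):
            for t in nodes[i + 1:]:
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for path in paths:
                    for v in path[1:-1]:
                        accum[v] += 1 / len(paths)
        scale = (len(nodes) - 1) * (len(nodes) - 2) / 2
        for v in nodes:
            if v in net.node_stats.index:
                assert net.node_stats.loc[v, "betweenness"] == pytest.approx(
                    accum[v] / scale
                )

    def test_edge_retention_is_monotone_in_threshold(self, rng):
        rows = [
            (f"a{i}", f"b{i}", r, 1e-8, 1e-6)
            for i, r in enumerate(rng.uniform(0.3, 0.99, size=50))
        ]
        edges = pd.DataFrame(rows, columns=["asv_i", "asv_j", "r", "p_raw", "p_adj"])
        prev = None
        for t in [0.5, 0.6, 0.7, 0.8, 0.9]:
            kept = set(build_network(edges, t).graph.edges())
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_insignificant_edges_excluded(self):
        edges = pd.DataFrame(
            [("a", "b", 0.9, 0.2, 0.4), ("b", "c", 0.9, 1e-8, 1e-6)],
            columns=["asv_i", "asv_j", "r", "p_raw", "p_adj"],
        )
        net = build_network(edges, 0.7)
        assert set(net.graph.edges()) == {("b", "c")}

    def test_no_surviving_edges_warns_and_returns_empty(self):
        edges = pd.DataFrame(
            [("a", "b", 0.4, 1e-8, 1e-6)],
            columns=["asv_i", "asv_j", "r", "p_raw", "p_adj"],
        )
        with pytest.warns(UserWarning, match="no edges"):
            net = build_network(edges, 0.7)
        assert net.graph.number_of_edges() == 0


class TestGroupConnectivity:
    def test_clique_group_versus_isolated_groups(self):
        net = build_network(edges_from_graph(nx.complete_graph(5)), 0.5)
        net.graph.add_nodes_from(["r1", "t1"])  # isolated resident/transient
        groups = {i: "intermittent" for i in range(5)}
        groups.update({"r1": "resident", "t1": "transient"})
        means = group_connectivity(net, groups)
        assert means["intermittent"] == pytest.approx(4.0)
        assert means["resident"] == 0.0
        assert means["transient"] == 0.0

    def test_empty_network_reports_zero_for_labelled_groups(self):
        edges = pd.DataFrame(
            [("a", "b", 0.4, 1e-8, 1e-6)],
            columns=["asv_i", "asv_j", "r", "p_raw", "p_adj"],
        )
        with pytest.warns(UserWarning):
            net = build_network(edges, 0.9)
        means = group_connectivity(net, {"a": "resident", "b": "transient"})
        assert means == {"resident": 0.0, "transient": 0.0}

    def test_unlabelled_node_rejected(self):
        net = build_network(edges_from_graph(nx.path_graph(["a", "b"])), 0.5)
        with pytest.raises(ValueError):
            group_connectivity(net, {"a": "resident"})
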