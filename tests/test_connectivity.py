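"""Connectivity estimation oracle checks, filtering rules, and graph
metrics (degree, distance-weighted clustering, length distributions,
Bhattacharyya distance)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from measeg import (
    ConnectivityMatrix,
    ElectrodeLayout,
    SpikeTrains,
    bhattacharyya,
    clustering_coefficient,
    estimate_cm_tspe,
    grid_layout,
    label_intra_inter,
    length_distributions,
    node_degree,
    speed_filter,
    strong_connections,
    threshold_cm,
)
from measeg.synth import SynthConfig, generate_spike_trains

from conftest import poisson_trains


def _cm(weights, layout, delays=None):
    w = np.asarray(weights, dtype=float)
    d = np.asarray(delays, dtype=float) if delays is not None else \
        np.where(w != 0, 5.0, 0.0)
    return ConnectivityMatrix(w, d, layout.ids)


@pytest.fixture(scope="module")
def pair_layout():
    return ElectrodeLayout(
        ("a", "b", "c"),
        np.array([[0.0, 0.0], [600.0, 0.0], [0.0, 600.0]]),
        ("C1", "C1", "C2"),
    )


class TestEstimator:
    def test_shifted_train_recovers_lag_and_direction(self, pair_layout):
        rng = np.random.default_rng(0)
        ti = np.sort(rng.uniform(0, 600, 1000))
        tj = np.unique(np.clip(ti + 0.005, 0, 600))
        tk = np.sort(rng.uniform(0, 600, 800))
        trains = SpikeTrains({"a": ti, "b": tj, "c": tk}, 600.0)
        cm = estimate_cm_tspe(trains, pair_layout)
        w_ab, tau_ab = cm.weights[0, 1], cm.delays_ms[0, 1]
        # oracle: the raw cross-correlogram of the two trains peaks at 5 ms
        lags = np.rint((tj[:, None] - ti[None, :]) * 1000).astype(int)
        inwin = lags[(lags >= 1) & (lags <= 25)]
        assert np.bincount(inwin).argmax() == 5
        assert w_ab > 0.05
        assert abs(tau_ab - 5.0) <= 1.0
        assert w_ab > cm.weights[1, 0]
        # the independent electrode stays near zero
        assert abs(cm.weights[0, 2]) < 0.2 * w_ab

    def test_diagonal_zero(self, pair_layout):
        trains = poisson_trains(3, 2.0, 120.0, seed=1)
        trains = SpikeTrains(
            dict(zip(("a", "b", "c"), trains.trains.values())), 120.0)
        cm = estimate_cm_tspe(trains, pair_layout)
        assert np.all(np.diag(cm.weights) == 0)

    def test_fewer_than_two_active_rejected(self, pair_layout):
        st = SpikeTrains({"a": np.linspace(1, 119, 500), "b": np.empty(0),
                          "c": np.empty(0)}, 120.0)
        with pytest.raises(ValueError, match="active"):
            estimate_cm_tspe(st, pair_layout)


class TestSpeedFilter:
    def test_arithmetic_band(self, pair_layout):
        # 0.6 mm / 10 ms = 60 mm/s kept; 0.6 mm / 1 ms = 600 mm/s removed
        w = np.zeros((3, 3))
        d = np.zeros((3, 3))
        w[0, 1] = 1.0
        d[0, 1] = 10.0
        w[1, 0] = 1.0
        d[1, 0] = 1.0
        out = speed_filter(_cm(w, pair_layout, d), pair_layout)
        assert out.weights[0, 1] == 1.0
        assert out.weights[1, 0] == 0.0

    def test_out_of_band_planted_pairs_all_removed(self):
        layout = grid_layout()
        cfg = SynthConfig(duration_s=300.0, seed=5, nb_rate_per_min=0.0,
                          n_events=0, n_coupled_pairs=6,
                          coupled_pairs_in_band=False)
        trains, truth = generate_spike_trains(cfg, layout)
        cm = estimate_cm_tspe(trains, layout)
        out = speed_filter(cm, layout)
        idx = {e: k for k, e in enumerate(layout.ids)}
        for p in truth.coupled_pairs:
            assert out.weights[idx[p.source], idx[p.target]] == 0.0

    def test_zero_delay_edge_removed(self, pair_layout):
        w = np.zeros((3, 3))
        w[0, 1] = 2.0
        out = speed_filter(_cm(w, pair_layout, np.zeros((3, 3))), pair_layout)
        assert out.n_edges() == 0


class TestThreshold:
    def test_hand_computed_survivors(self, pair_layout):
        # entries {0.1,0.2,0.3,0.4,0.9}: mu=0.38, sample SD=0.3114 ->
        # only 0.9 > mu + sigma survives
        lay = grid_layout()
        w = np.zeros((120, 120))
        vals = [0.1, 0.2, 0.3, 0.4, 0.9]
        for k, v in enumerate(vals):
            w[0, k + 1] = v
        tcm, mu, sigma = threshold_cm(_cm(w, lay))
        assert mu == pytest.approx(0.38)
        assert sigma == pytest.approx(np.std(vals, ddof=1))
        nz = tcm.weights[tcm.weights != 0]
        np.testing.assert_allclose(nz, [0.9])

    def test_sign_symmetry(self, pair_layout):
        rng = np.random.default_rng(2)
        w = rng.normal(0, 1, (3, 3))
        np.fill_diagonal(w, 0.0)
        t_pos, _, _ = threshold_cm(_cm(w, pair_layout))
        t_neg, _, _ = threshold_cm(_cm(-w, pair_layout))
        np.testing.assert_allclose(t_neg.weights, -t_pos.weights)

    def test_degenerate_equal_entries_empty(self, pair_layout):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 0.5
        tcm, mu, sigma = threshold_cm(_cm(w, pair_layout))
        assert sigma == 0.0
        assert tcm.n_edges() == 0  # strict inequality at mu +/- 0

    def test_all_zero_rejected(self, pair_layout):
        with pytest.raises(ValueError):
            threshold_cm(_cm(np.zeros((3, 3)), pair_layout))


class TestStrong:
    def test_strong_subset_and_dominant_edge(self, pair_layout):
        lay = grid_layout()
        w = np.zeros((120, 120))
        for k, v in enumerate([0.1, 0.12, 0.11, 0.13, 2.0]):
            w[0, k + 1] = v
        cm = _cm(w, lay)
        tcm, mu, sigma = threshold_cm(cm)
        strong = strong_connections(tcm, mu, sigma)
        s_edges = set(zip(*np.nonzero(strong.weights)))
        t_edges = set(zip(*np.nonzero(tcm.weights)))
        assert s_edges <= t_edges
        assert (0, 5) in s_edges  # the dominant edge is strong

    def test_empty_tcm_empty_strong(self, pair_layout):
        tcm = _cm(np.zeros((3, 3)), pair_layout)
        assert strong_connections(tcm, 0.5, 0.5).n_edges() == 0


class TestLabels:
    def test_intra_inter_and_unclassified(self, small_layout):
        w = np.zeros((6, 6))
        w[0, 1] = 1.0   # a1 -> a2: intra C1
        w[0, 3] = 1.0   # a1 -> b1: inter
        w[0, 5] = 1.0   # a1 -> u1: unclassified
        res = label_intra_inter(_cm(w, small_layout), small_layout)
        assert res["n_intra"] == 1 and res["n_inter"] == 1
        assert res["n_unclassified"] == 1
        assert res["pct_intra"] + res["pct_inter"] == pytest.approx(100.0)
        assert res["intra_inter_ratio"] == pytest.approx(1.0)

    def test_uncoupled_synth_strong_edges_intra(self):
        layout = grid_layout()
        cfg = SynthConfig(duration_s=300.0, seed=1, p_couple=0.0)
        trains, _ = generate_spike_trains(cfg, layout)
        cm = estimate_cm_tspe(trains, layout)
        tcm, mu, sigma = threshold_cm(speed_filter(cm, layout))
        res = label_intra_inter(strong_connections(tcm, mu, sigma), layout)
        assert res["pct_inter"] <= 5.0


class TestGraphMetrics:
    def test_degree_counts_in_plus_out(self, small_layout):
        w = np.zeros((6, 6))
        w[1, 0] = w[2, 0] = 1.0            # two incoming to a1
        w[0, 3] = w[0, 4] = w[0, 5] = 1.0  # three outgoing from a1
        k = node_degree(_cm(w, small_layout))
        assert k["a1"] == 5
        assert k.sum() == 2 * 5  # handshake identity

    def test_empty_matrix_zero_degree(self, small_layout):
        assert node_degree(_cm(np.zeros((6, 6)), small_layout)).sum() == 0

    def test_clustering_two_neighbours_at_1mm(self):
        lay = ElectrodeLayout(
            ("i", "j1", "j2"),
            np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]]),
            ("C1", "C1", "C1"),
        )
        w = np.zeros((3, 3))
        w[0, 1] = w[0, 2] = 1.0
        cc = clustering_coefficient(_cm(w, lay), lay)
        assert cc["i"] == pytest.approx(2.0)  # (1 + 1) / (2*1/2)
        assert cc["j1"] == 0.0  # k < 2 convention

    def test_clustering_quarter_under_distance_doubling(self):
        for scale in (1.0, 2.0):
            lay = ElectrodeLayout(
                ("i", "j1", "j2"),
                np.array([[0.0, 0.0], [scale * 1000, 0.0],
                          [0.0, scale * 1000]]),
                ("C1", "C1", "C1"),
            )
            w = np.zeros((3, 3))
            w[0, 1] = w[0, 2] = 1.0
            cc = clustering_coefficient(_cm(w, lay), lay)["i"]
            if scale == 1.0:
                base = cc
        assert cc == pytest.approx(base / 4.0)

    def test_reciprocal_edges_not_double_counted(self, small_layout):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 1.0  # reciprocal pair
        w[0, 2] = 1.0
        cc = clustering_coefficient(_cm(w, small_layout), small_layout)
        # a1 has two unique neighbours (a2, a3), both at 200 um = 0.2 mm
        assert cc["a1"] == pytest.approx((2 / 0.04) / 1.0)


class TestLengthsAndBhattacharyya:
    def test_histograms_normalized_shared_bins(self, small_layout):
        w = np.zeros((6, 6))
        w[0, 1] = 1.0  # intra, 0.2 mm
        w[0, 3] = 1.0  # inter, 1.0 mm
        A, B, edges = length_distributions(_cm(w, small_layout), small_layout)
        assert A.sum() == pytest.approx(1.0)
        assert B.sum() == pytest.approx(1.0)
        assert A.size == B.size == edges.size - 1

    def test_all_intra_network_flagged(self, small_layout):
        w = np.zeros((6, 6))
        w[0, 1] = 1.0
        with pytest.raises(ValueError, match="inter"):
            length_distributions(_cm(w, small_layout), small_layout)

    def test_empty_edge_set_rejected(self, small_layout):
        with pytest.raises(ValueError, match="empty"):
            length_distributions(_cm(np.zeros((6, 6)), small_layout),
                                 small_layout)

    def test_identical_histograms_zero(self):
        a = np.array([0.25, 0.5, 0.25])
        assert bhattacharyya(a, a) == 0.0

    def test_hand_computed_value(self):
        # sum(sqrt) = sqrt(0.45) + sqrt(0.05) ~ 0.8944 -> BC ~ 0.1116
        bc = bhattacharyya(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
        assert bc == pytest.approx(0.11157, abs=1e-4)

    def test_disjoint_supports_infinite(self):
        assert math.isinf(bhattacharyya(np.array([1.0, 0.0]),
                                        np.array([0.0, 1.0])))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
        st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
    )
    def test_symmetric_nonnegative_zero_iff_equal(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if a.sum() == 0 or b.sum() == 0:
            return
        a, b = a / a.sum(), b / b.sum()
        bc_ab, bc_ba = bhattacharyya(a, b), bhattacharyya(b, a)
        assert bc_ab == pytest.approx(bc_ba, rel=1e-9)
        assert bc_ab >= 0.0
        if np.allclose(a, b, atol=1e-12):
            assert bc_ab == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya(np.ones(3) / 3, np.ones(4) / 4)


class TestPipelineNesting:
    def test_strong_within_thresholded_within_filtered(self):
        layout = grid_layout()
        cfg = SynthConfig(duration_s=120.0, seed=8, n_events=15,
                          n_coupled_pairs=5)
        trains, _ = generate_spike_trains(cfg, layout)
        cm = estimate_cm_tspe(trains, layout)
        cm_v = speed_filter(cm, layout)
        tcm, mu, sigma = threshold_cm(cm_v)
        strong = strong_connections(tcm, mu, sigma)

        def edges(m):
            return set(zip(*np.nonzero(m.weights)))

        assert edges(strong) <= edges(tcm) <= edges(cm_v) <= edges(cm)
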