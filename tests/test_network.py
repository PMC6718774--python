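"""Cross-correlation identities against a textbook Pearson oracle, map
data, and constrained network reconstruction with planted connectivity."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caflux.network import (
    CorrelationSpec,
    NetworkParams,
    adjacency,
    centroid_distance_um,
    correlation_table,
    heatmap_values,
    reconstruct_network,
    spatiotemporal_map_data,
    xcorr,
)
from caflux.segmentation import ROI, ROISet
from caflux.timeseries import SpikeTrain

from conftest import roi_from_coords


def pearson_oracle(f, g, tau):
    """Textbook Pearson sum over the aligned overlap, means/norms on the
    full series (independent reference implementation)."""
    f = np.asarray(f, float)
    g = np.asarray(g, float)
    fc, gc = f - f.mean(), g - g.mean()
    nf, ng = np.sqrt((fc**2).sum()), np.sqrt((gc**2).sum())
    total = 0.0
    for n in range(len(g)):
        if 0 <= n - tau < len(f):
            total += fc[n - tau] * gc[n]
    return total / (nf * ng)


class TestXcorr:
    def test_self_correlation_is_one(self, rng):
        f = rng.random(50)
        assert abs(xcorr(f, f, 0) - 1.0) <= 1e-12

    @pytest.mark.parametrize("k", [-5, -2, 0, 1, 3, 5])
    def test_planted_shift_recovered_as_argmax(self, k, rng):
        f = np.zeros(120)
        f[rng.choice(np.arange(10, 100), size=14, replace=False)] = 1.0
        g = np.roll(f, k)  # g delayed by k -> f leads by k
        lags = range(-5, 6)
        values = [xcorr(f, g, tau) for tau in lags]
        assert list(lags)[int(np.argmax(values))] == k

    def test_constant_series_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert xcorr(np.full(20, 2.0), np.arange(20.0), 0) == 0.0

    def test_excessive_lag_raises(self):
        with pytest.raises(ValueError):
            xcorr(np.arange(5.0), np.arange(5.0), 5)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            f, g = rng.normal(size=40), rng.normal(size=40)
            tau = int(rng.integers(-5, 6))
            assert abs(xcorr(f, g, tau) - pearson_oracle(f, g, tau)) <= 1e-10

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(-5, 5))
    def test_time_reversal_symmetry(self, seed, tau):
        rng = np.random.default_rng(seed)
        f, g = rng.normal(size=30), rng.normal(size=30)
        assert abs(xcorr(f, g, tau) - xcorr(g, f, -tau)) <= 1e-12

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            f, g = rng.normal(size=25), rng.normal(size=25)
            tau = int(rng.integers(-5, 6))
            assert abs(xcorr(f, g, tau)) <= 1.0 + 1e-10


class TestCorrelationTable:
    def test_identical_rois_have_unit_zero_lag(self, rng):
        f = rng.random(30)
        table = correlation_table({1: f, 2: f.copy()}, CorrelationSpec("b", 3))
        row = table[(table.roi_a == 1) & (table.roi_b == 2) & (table.lag == 0)]
        assert abs(float(row.correlation.iloc[0]) - 1.0) <= 1e-12

    def test_antiphase_alternation_is_minus_one(self):
        f = np.tile([1.0, -1.0], 15)
        table = correlation_table({1: f, 2: -f}, CorrelationSpec("b", 0))
        row = table[(table.roi_a == 1) & (table.roi_b == 2)]
        assert abs(float(row.correlation.iloc[0]) + 1.0) <= 1e-12

    def test_zero_lag_matrix_symmetric(self, rng):
        data = {k: rng.normal(size=40) for k in (1, 2, 3)}
        table = correlation_table(data, CorrelationSpec("b", 2))
        at0 = table[table.lag == 0].set_index(["roi_a", "roi_b"]).correlation
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                assert abs(at0[(a, b)] - at0[(b, a)]) <= 1e-12


class TestHeatmap:
    def test_single_roi_is_self_max(self):
        assert heatmap_values({1: SpikeTrain(1, np.array([0, 1, 1]))}, "s") == {1: 1.0}

    def test_spike_counts_normalized(self):
        trains = {
            1: SpikeTrain(1, np.array([1, 1, 0, 0])),
            2: SpikeTrain(2, np.array([1, 1, 1, 1])),
        }
        assert heatmap_values(trains, "s") == {1: 0.5, 2: 1.0}

    def test_all_silent_gives_zeros(self):
        trains = {k: SpikeTrain(k, np.zeros(5, dtype=int)) for k in (1, 2)}
        assert heatmap_values(trains, "s") == {1: 0.0, 2: 0.0}


class TestCentroidDistance:
    def test_same_centroid_is_zero(self):
        a = roi_from_coords(1, [(2, 2)])
        assert centroid_distance_um(a, a, 1.5) == 0.0

    def test_three_four_five_triangle(self):
        a = roi_from_coords(1, [(0, 0)])
        b = roi_from_coords(2, [(3, 4)])
        assert centroid_distance_um(a, b, 2.0) == pytest.approx(10.0)

    def test_random_pairs_match_direct_formula(self, rng):
        for _ in range(10):
            pa, pb = rng.integers(0, 50, size=2), rng.integers(0, 50, size=2)
            a, b = roi_from_coords(1, [tuple(pa)]), roi_from_coords(2, [tuple(pb)])
            expected = float(np.sqrt(((pa - pb) ** 2).sum())) * 0.7
            assert centroid_distance_um(a, b, 0.7) == pytest.approx(expected)


def _pair_rois(offset_px):
    a = roi_from_coords(1, [(5, 5)])
    b = roi_from_coords(2, [(5, 5 + offset_px)])
    return ROISet([a, b], shape=(10, offset_px + 10))


def _shifted_trains(rng, n=200, lag=1):
    s1 = np.zeros(n, dtype=int)
    s1[rng.choice(np.arange(12, n - 10), size=15, replace=False)] = 1
    s2 = np.roll(s1, lag)
    return {1: SpikeTrain(1, s1), 2: SpikeTrain(2, s2)}


PUBLISHED = NetworkParams(min_corr=0.25, max_dist_um=208.0, max_delay_s=0.5)


class TestReconstructNetwork:
    def test_shifted_pair_gives_single_directed_edge(self, rng):
        trains = _shifted_trains(rng)
        graph = reconstruct_network(_pair_rois(50), trains, PUBLISHED, fps=10.0)
        assert graph.edge_set() == {(1, 2)}
        (edge,) = graph.edges
        assert edge.best_lag == 1 and edge.delay_s == pytest.approx(0.1)
        assert edge.correlation > 0.25

    def test_distance_filter_removes_edge(self, rng):
        trains = _shifted_trains(rng)
        graph = reconstruct_network(_pair_rois(300), trains, PUBLISHED, fps=10.0)
        assert graph.edge_set() == set()

    def test_zero_lag_gives_reciprocal_edges(self, rng):
        trains = _shifted_trains(rng, lag=0)
        graph = reconstruct_network(_pair_rois(50), trains, PUBLISHED, fps=10.0)
        assert graph.edge_set() == {(1, 2), (2, 1)}

    def test_independent_trains_give_no_edges(self, rng):
        edges = 0
        for _ in range(10):
            s1 = (rng.random(200) < 0.05).astype(int)
            s2 = (rng.random(200) < 0.05).astype(int)
            trains = {1: SpikeTrain(1, s1), 2: SpikeTrain(2, s2)}
            graph = reconstruct_network(_pair_rois(50), trains, PUBLISHED, fps=10.0)
            edges += len(graph.edges)
        assert edges <= 1  # expected approximately zero at min_corr 0.25

    def test_filter_monotonicity(self, rng):
        trains = _shifted_trains(rng)
        rois = _pair_rois(50)

        def n_edges(min_corr=0.25, max_dist=208.0, max_delay=0.5):
            p = NetworkParams(min_corr=min_corr, max_dist_um=max_dist, max_delay_s=max_delay)
            return len(reconstruct_network(rois, trains, p, fps=10.0).edges)

        base = n_edges()
        assert n_edges(min_corr=0.8) <= base
        assert n_edges(max_dist=10.0) <= base
        assert n_edges(max_delay=0.0) <= base


class TestAdjacency:
    def test_matrix_is_indicator_of_edge_list(self, rng):
        trains = _shifted_trains(rng)
        graph = reconstruct_network(_pair_rois(50), trains, PUBLISHED, fps=10.0)
        adj = adjacency(graph)
        ids = graph.roi_ids
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert adj[i, j] == int((a, b) in graph.edge_set())
        # row/col sums are out-/in-degrees
        assert adj.sum(axis=1).tolist() == [
            sum(1 for e in graph.edges if e.source_roi == a) for a in ids
        ]

    def test_no_edges_gives_zero_matrix(self, rng):
        trains = _shifted_trains(rng)
        graph = reconstruct_network(_pair_rois(300), trains, PUBLISHED, fps=10.0)
        assert (adjacency(graph) == 0).all()


class TestSpatiotemporalMap:
    def test_inactive_roi_excluded_and_n_avg(self):
        rois = ROISet(
            [roi_from_coords(1, [(0, 0)]), roi_from_coords(2, [(3, 3)])], shape=(5, 5)
        )
        s1 = np.zeros(10, dtype=int)
        s1[[1, 3]] = 1  # frames 2 and 4
        trains = {1: SpikeTrain(1, s1), 2: SpikeTrain(2, np.zeros(10, dtype=int))}
        table = spatiotemporal_map_data(trains, rois)
        assert table.roi_id.tolist() == [1]
        assert float(table.n_avg.iloc[0]) == pytest.approx(3.0)
        assert int(table.spike_count.iloc[0]) == 2
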