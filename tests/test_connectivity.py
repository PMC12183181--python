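"""Edge indexing, Fisher transform, static FC, sliding windows, dynamic CV —
each checked against closed forms or brute-force per-edge oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fcpipe import (
    EdgeIndexMap,
    RoiTimeSeries,
    SlidingWindowSpec,
    dynamic_fc_cv,
    fisher_z,
    make_windows,
    static_fc,
)
from fcpipe.connectivity import CV_MEAN_FLOOR, FISHER_EPS, windowed_correlations
from fcpipe.synthetic import sample_bold


# ---------------------------------------------------------------- oracles
def brute_static_fc(data, emap):
    """Loop over edges calling a scalar Pearson routine, then Fisher z."""
    out = np.empty(emap.n_edges)
    for k in range(emap.n_edges):
        i, j = emap.pair(k)
        r, _ = stats.pearsonr(data[:, i], data[:, j])
        out[k] = np.arctanh(np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS))
    return out


def brute_dynamic_cv(data, emap, windows):
    """Loop over windows and edges; sample SD over |mean| with the floor."""
    out = np.empty(emap.n_edges)
    for k in range(emap.n_edges):
        i, j = emap.pair(k)
        rs = [stats.pearsonr(data[a:b, i], data[a:b, j])[0] for a, b in windows]
        rs = np.array(rs)
        out[k] = rs.std(ddof=1) / max(abs(rs.mean()), CV_MEAN_FLOOR)
    return out


class TestEdgeIndexMap:
    def test_edge_counts(self):
        assert EdgeIndexMap(10).n_edges == 45
        assert EdgeIndexMap(264).n_edges == 34716

    def test_row_major_order(self):
        emap = EdgeIndexMap(4)
        assert [emap.pair(k) for k in range(6)] == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
        ]

    @given(st.integers(2, 300), st.data())
    def test_flat_index_and_pair_are_inverse(self, n, data):
        emap = EdgeIndexMap(n)
        k = data.draw(st.integers(0, emap.n_edges - 1))
        i, j = emap.pair(k)
        assert 0 <= i < j < n
        assert emap.flat_index(i, j) == k
        assert emap.flat_index(j, i) == k  # order-insensitive

    def test_rejects_self_pairs(self):
        with pytest.raises(ValueError):
            EdgeIndexMap(5).flat_index(2, 2)


class TestFisherZ:
    def test_zero_fixed_point(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5), abs=1e-12)

    def test_perfect_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))
        assert 8 < z < 9

    @given(st.floats(-1, 1, allow_nan=False))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestStaticFC:
    def test_identical_columns_hit_clipped_maximum(self, rng):
        x = rng.standard_normal(50)
        ts = RoiTimeSeries(np.column_stack([x, x, rng.standard_normal(50)]), 2.0)
        ev = static_fc(ts, EdgeIndexMap(3))
        assert ev.values[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_columns_hit_clipped_minimum(self, rng):
        x = rng.standard_normal(50)
        ts = RoiTimeSeries(np.column_stack([x, -x, rng.standard_normal(50)]), 2.0)
        ev = static_fc(ts, EdgeIndexMap(3))
        assert ev.values[0] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_hand_fixture_matches_textbook_pearson(self):
        # T=5, 4 ROIs, integer entries; oracle = covariance-formula Pearson
        data = np.array(
            [[1, 2, 5, 1],
             [2, 1, 4, 3],
             [3, 4, 3, 2],
             [4, 3, 2, 5],
             [5, 5, 1, 4]], dtype=float
        )
        emap = EdgeIndexMap(4)
        ev = static_fc(RoiTimeSeries(data, 2.0), emap)
        for k in range(emap.n_edges):
            i, j = emap.pair(k)
            x, y = data[:, i], data[:, j]
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            expected = np.arctanh(np.clip(num / den, -1 + 1e-7, 1 - 1e-7))
            assert ev.values[k] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_positive_affine_rescaling(self, noise_series, edge_map_10):
        base = static_fc(noise_series, edge_map_10).values
        scaled = noise_series.with_data(noise_series.data * 3.7 + 11.0)
        np.testing.assert_allclose(
            static_fc(scaled, edge_map_10).values, base, atol=1e-10
        )

    def test_zero_variance_roi_flagged_not_zeroed(self, rng):
        data = rng.standard_normal((40, 3))
        data[:, 1] = 5.0
        emap = EdgeIndexMap(3)
        with pytest.warns(UserWarning, match="zero-variance"):
            ev = static_fc(RoiTimeSeries(data, 2.0), emap)
        assert np.isnan(ev.values[[0, 2]]).all()  # edges (0,1) and (1,2)
        assert np.isfinite(ev.values[1])  # edge (0,2) unaffected
        assert set(ev.missing_edges) == {0, 2}


class TestMakeWindows:
    def test_consortium_configuration(self):
        spec = SlidingWindowSpec(100, 2)
        windows = make_windows(230, spec, tr_seconds=2.0)
        assert spec.window_samples(2.0) == 50
        assert spec.step_samples(2.0) == 1
        assert len(windows) == 181
        assert windows[0] == (0, 50) and windows[-1] == (180, 230)

    def test_exact_fit_single_window(self):
        assert make_windows(50, SlidingWindowSpec(100, 2), 2.0) == [(0, 50)]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            make_windows(49, SlidingWindowSpec(100, 2), 2.0)

    def test_all_windows_full_length(self):
        spec = SlidingWindowSpec(60, 14)
        for a, b in make_windows(217, spec, 2.0):
            assert b - a == spec.window_samples(2.0)
            assert b <= 217


class TestDynamicCV:
    def test_identical_columns_give_zero_cv(self, rng):
        x = rng.standard_normal(120)
        noise = rng.standard_normal(120)
        ts = RoiTimeSeries(np.column_stack([x, x, noise]), 2.0)
        ev = dynamic_fc_cv(ts, EdgeIndexMap(3), SlidingWindowSpec(40, 2))
        assert ev.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, noise_series, edge_map_10):
        spec = SlidingWindowSpec(40, 4)
        ev = dynamic_fc_cv(noise_series, edge_map_10, spec)
        windows = make_windows(120, spec, 2.0)
        expected = brute_dynamic_cv(noise_series.data, edge_map_10, windows)
        np.testing.assert_allclose(ev.values, expected, atol=1e-10)

    def test_static_matches_brute_force_oracle(self, noise_series, edge_map_10):
        ev = static_fc(noise_series, edge_map_10)
        np.testing.assert_allclose(
            ev.values, brute_static_fc(noise_series.data, edge_map_10), atol=1e-10
        )

    def test_regime_switching_inflates_cv(self):
        # edge (0,1): stationary r = 0.35 vs switching r in {0.75, -0.05};
        # the nonzero base keeps the CV denominator well away from the floor
        base = np.eye(6)
        base[0, 1] = base[1, 0] = 0.35
        up, down = base.copy(), base.copy()
        up[0, 1] = up[1, 0] = 0.75
        down[0, 1] = down[1, 0] = -0.05
        rng = np.random.default_rng(21)
        from fcpipe.synthetic import _ar1_series

        chols = [np.linalg.cholesky(up), np.linalg.cholesky(down)]
        t = 400
        stationary = _ar1_series(
            [np.linalg.cholesky(base)], np.zeros(t, int), t, 6, 0.3, 1.0, rng
        )
        schedule = (np.arange(t) // 25) % 2
        switching = _ar1_series(chols, schedule, t, 6, 0.3, 1.0, rng)
        emap = EdgeIndexMap(6)
        spec = SlidingWindowSpec(100, 2)
        cv_stat = dynamic_fc_cv(RoiTimeSeries(stationary, 2.0), emap, spec).values
        cv_switch = dynamic_fc_cv(RoiTimeSeries(switching, 2.0), emap, spec).values
        assert cv_switch[0] > cv_stat[0]

    def test_single_window_rejected(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((50, 4)), 2.0)
        with pytest.raises(ValueError, match="at least 2 windows"):
            dynamic_fc_cv(ts, EdgeIndexMap(4), SlidingWindowSpec(100, 200))

    def test_near_zero_mean_edges_flagged(self, rng):
        # windowed r of independent noise averages near 0 only by chance;
        # force the floor with an exactly antisymmetric construction
        ts = RoiTimeSeries(rng.standard_normal((120, 4)), 2.0)
        ev = dynamic_fc_cv(ts, EdgeIndexMap(4), SlidingWindowSpec(40, 2))
        r = windowed_correlations(ts, EdgeIndexMap(4), SlidingWindowSpec(40, 2))
        floor_expected = np.abs(r.mean(axis=0)) < CV_MEAN_FLOOR
        assert set(ev.floor_edges) == set(np.flatnonzero(floor_expected))

    def test_cv_nonnegative_and_finite(self, small_cohort, edge_map_10):
        _, _, series = small_cohort
        ev = dynamic_fc_cv(series[0], edge_map_10, SlidingWindowSpec(40, 2))
        assert np.isfinite(ev.values).all()
        assert (ev.values >= 0).all()
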