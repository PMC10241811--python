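"""QPP template matching, event detection and event summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hierflux import (
    build_template,
    classify_trajectory,
    detect_events,
    event_network_fc,
    event_traces,
    gradient_projection,
    phase_align,
    sliding_match,
)
from hierflux.core import RegionTimeSeries
from hierflux.qpp import QPPEventSet, QPPTemplate
from hierflux.synth import inject_qpp, make_gradient, make_qpp_template


@pytest.fixture()
def template20():
    return make_qpp_template(make_gradient(20).primary, L=30, dt=0.72)


def brute_force_match(ts, template):
    L = template.length
    tpl = template.data.ravel()
    out = []
    for tau in range(ts.n_frames - L + 1):
        seg = ts.data[tau : tau + L].T.ravel()
        if seg.std() == 0 or tpl.std() == 0:
            out.append(0.0)
        else:
            out.append(stats.pearsonr(seg, tpl).statistic)
    return np.array(out)


class TestSlidingMatch:
    def test_verbatim_template_perfect_match(self, template20, rng):
        base = RegionTimeSeries(1e-12 * rng.standard_normal((200, 20)), 0.72)
        ts = inject_qpp(base, template20, [77], gain=1.0)
        r = sliding_match(ts, template20)
        assert np.isclose(r[77], 1.0, atol=1e-9)

    def test_negated_template(self, template20, rng):
        base = RegionTimeSeries(1e-12 * rng.standard_normal((100, 20)), 0.72)
        ts = inject_qpp(base, template20, [30], gain=-1.0)
        r = sliding_match(ts, template20)
        assert np.isclose(r[30], -1.0, atol=1e-9)

    def test_matches_bruteforce_per_lag(self, template20, rng):
        ts = RegionTimeSeries(rng.standard_normal((120, 20)), 0.72)
        got = sliding_match(ts, template20)
        want = brute_force_match(ts, template20)
        assert np.allclose(got, want, atol=1e-8)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        template20 = make_qpp_template(make_gradient(20).primary, L=30, dt=0.72)
        rng = np.random.default_rng(3)
        ts = RegionTimeSeries(rng.standard_normal((90, 20)), 0.72)
        ts2 = RegionTimeSeries(a * ts.data + b, 0.72)
        assert np.allclose(
            sliding_match(ts, template20), sliding_match(ts2, template20), atol=1e-6
        )


class TestDetectEvents:
    def test_all_zero_series_empty(self):
        assert detect_events(np.zeros(100)).n_events == 0

    def test_single_peak(self):
        r = np.zeros(200)
        r[100] = 0.9
        ev = detect_events(r, 0.4)
        assert list(ev.onsets) == [100]
        assert ev.correlations[0] == 0.9

    def test_plateau_leftmost(self):
        r = np.zeros(50)
        r[20:23] = 0.6
        ev = detect_events(r, 0.4)
        assert list(ev.onsets) == [20]

    def test_close_peaks_keep_higher(self):
        r = np.zeros(100)
        r[40], r[45] = 0.5, 0.7
        ev = detect_events(r, 0.4, min_sep=10)
        assert list(ev.onsets) == [45]

    @given(st.floats(0.1, 0.8))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, thresh):
        rng = np.random.default_rng(11)
        r = rng.uniform(-1, 1, 300)
        low = set(detect_events(r, thresh).onsets)
        high = set(detect_events(r, min(thresh + 0.1, 0.95)).onsets)
        assert high.issubset(low)


class TestBuildTemplate:
    def test_periodic_data_recovers_cycle(self, rng):
        g = make_gradient(50).primary
        tpl = make_qpp_template(g, L=30, dt=0.72)
        base = RegionTimeSeries(1e-9 * rng.standard_normal((600, 50)), 0.72)
        ts = inject_qpp(base, tpl, np.arange(20) * 30, gain=1.0)
        built, events = build_template(ts, 30, seed=1)
        _, aligned = phase_align(tpl, built, max_shift=15)
        r = stats.pearsonr(tpl.data.ravel(), aligned.data.ravel()).statistic
        assert abs(r) > 0.99

    def test_fixed_point_on_own_output(self, rng):
        g = make_gradient(30).primary
        tpl = make_qpp_template(g, L=20, dt=1.0)
        base = RegionTimeSeries(0.3 * rng.standard_normal((500, 30)), 1.0)
        ts = inject_qpp(base, tpl, np.arange(8) * 60 + 5, gain=1.0)
        built, events = build_template(ts, 20, seed=2)
        r = sliding_match(ts, built)
        again = detect_events(r, threshold=built.threshold, min_sep=20)
        assert np.array_equal(again.onsets, events.onsets)

    def test_white_noise_high_threshold_degenerate(self, rng):
        ts = RegionTimeSeries(rng.standard_normal((300, 40)), 1.0)
        try:
            _, events = build_template(ts, 30, threshold=0.8, seed=0)
            assert events.n_events <= 2
        except ValueError:
            pass  # no super-threshold events is the documented outcome


class TestPhaseAlign:
    def test_identical_zero_shift(self, template20):
        shift, aligned = phase_align(template20, template20, 5)
        assert shift == 0
        assert np.allclose(aligned.data, template20.data)

    def test_rolled_template_recovered(self, template20):
        rolled = QPPTemplate(np.roll(template20.data, 3, axis=1), 0.72)
        shift, aligned = phase_align(template20, rolled, 6)
        assert shift == -3
        assert np.allclose(aligned.data, template20.data)

    def test_matches_crosscorrelation_argmax(self, template20):
        rng = np.random.default_rng(5)
        b = QPPTemplate(np.roll(template20.data, -4, axis=1)
                        + 0.01 * rng.standard_normal(template20.data.shape), 0.72)
        shift, _ = phase_align(template20, b, 8)
        rs = {
            s: stats.pearsonr(
                template20.data.ravel(), np.roll(b.data, s, axis=1).ravel()
            ).statistic
            for s in range(-8, 9)
        }
        assert shift == max(rs, key=rs.get)


class TestGradientProjection:
    def test_frame_equal_gradient(self):
        g = np.linspace(-1, 1, 10)
        assert np.isclose(gradient_projection(g, g), np.sum(g**2))

    def test_orthogonal_frame(self):
        g = np.array([1.0, -1.0, 1.0, -1.0])
        frame = np.ones(4)
        assert gradient_projection(frame, g) == 0.0

    def test_matches_dot_oracle(self, rng):
        v, g = rng.standard_normal(30), rng.standard_normal(30)
        assert np.isclose(gradient_projection(v, g), v @ g, atol=1e-12)


class TestEventTraces:
    def test_homogeneous_regions_equal_traces(self, rng):
        row = rng.standard_normal(200)
        ts = RegionTimeSeries(np.tile(row[:, None], (1, 20)), 0.72)
        events = QPPEventSet(np.array([10]), np.array([0.9]), 0.4)
        (low, high), = event_traces(ts, events, np.linspace(-1, 1, 20), L=30)
        assert np.allclose(low, high)

    def test_propagating_wave_high_lags_low(self, rng):
        g = make_gradient(50).primary
        tpl = make_qpp_template(g, L=40, dt=0.72, phase_span=np.pi / 2)
        base = RegionTimeSeries(1e-9 * rng.standard_normal((200, 50)), 0.72)
        ts = inject_qpp(base, tpl, [60], gain=1.0)
        events = QPPEventSet(np.array([60]), np.array([1.0]), 0.4)
        (low, high), = event_traces(ts, events, g, L=40)
        assert np.argmax(high) > np.argmax(low)
        assert len(low) == 40

    def test_too_small_fraction_error(self, rng):
        ts = RegionTimeSeries(rng.standard_normal((100, 4)), 1.0)
        events = QPPEventSet(np.array([5]), np.array([0.9]), 0.4)
        with pytest.raises(ValueError, match="frac"):
            event_traces(ts, events, np.linspace(-1, 1, 4), L=20, frac=0.1)


class TestClassifyTrajectory:
    def test_identical_typical(self, rng):
        t = rng.standard_normal(30)
        assert classify_trajectory(t, t) == "typical"

    def test_negated_atypical(self, rng):
        t = rng.standard_normal(30)
        assert classify_trajectory(-t, t) == "atypical"

    def test_boundary_is_typical(self):
        # traces with Pearson r exactly 0.5 sit on the boundary -> typical
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([0.0, 2.0, 1.0])
        assert np.isclose(stats.pearsonr(a, b).statistic, 0.5, atol=1e-12)
        assert classify_trajectory(b, a, r_thresh=0.5) == "typical"

    def test_constant_trace_atypical(self):
        assert classify_trajectory(np.ones(10), np.arange(10.0)) == "atypical"


class TestEventNetworkFc:
    def test_identical_event_groups_zero_t(self, rng):
        ts = RegionTimeSeries(np.tile(rng.standard_normal((40, 12)), (4, 1)), 1.0)
        ev_a = QPPEventSet(np.array([0, 40]), np.array([0.9, 0.9]), 0.4)
        ev_b = QPPEventSet(np.array([80, 120]), np.array([0.9, 0.9]), 0.4)
        labels = np.repeat([0, 1, 2], 4)
        out = event_network_fc(ts, ev_a, labels, L=40, events_b=ev_b)
        assert np.allclose(out["t_map"], 0.0)

    def test_symmetric_unit_diagonal(self, rng):
        ts = RegionTimeSeries(rng.standard_normal((200, 12)), 1.0)
        ev = QPPEventSet(np.array([0, 50, 100]), np.array([0.9] * 3), 0.4)
        out = event_network_fc(ts, ev, np.repeat([0, 1, 2], 4), L=40)
        fc = out["mean_fc"]
        assert np.allclose(fc, fc.T) and np.allclose(np.diag(fc), 1.0)

    def test_planted_anticorrelated_networks_detected(self, rng):
        n_fr = 400
        labels = np.repeat([0, 1], 6)
        # group A events: networks anti-correlated; group B: independent
        data = rng.standard_normal((n_fr, 12)) * 0.2
        shared = rng.standard_normal(200)
        data[:200, :6] += shared[:, None]
        data[:200, 6:] -= shared[:, None]
        ts = RegionTimeSeries(data, 1.0)
        ev_a = QPPEventSet(np.array([0, 50, 100, 150]), np.array([0.9] * 4), 0.4)
        ev_b = QPPEventSet(np.array([200, 250, 300, 350]), np.array([0.9] * 4), 0.4)
        out = event_network_fc(ts, ev_a, labels, L=50, events_b=ev_b)
        assert out["mean_fc"][0, 1] < -0.5
        assert out["t_map"][0, 1] < 0 and out["p_map"][0, 1] < 0.05

    def test_empty_network_error(self, rng):
        ts = RegionTimeSeries(rng.standard_normal((100, 6)), 1.0)
        ev = QPPEventSet(np.array([0]), np.array([0.9]), 0.4)
        labels = np.array([0, 0, 0, 2, 2, 2])
        out = event_network_fc(ts, ev, labels, L=30)
        assert out["mean_fc"].shape == (2, 2)  # only present networks count
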