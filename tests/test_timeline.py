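"""Event pairing, alignment fitting, and time-map application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikesync import (
    AlignmentModel,
    EventSeries,
    SampledTrace,
    fit_pre_alignment,
    fit_prepost_alignment,
    pair_events,
    resample_trace,
    transform_events,
)
from spikesync.timeline import InsufficientAnchorsError

from conftest import brute_force_pairing, events, grid_search_prepost


def _pair_and_fit(ref, tgt, n_pre, n_post, max_lag=1.0):
    pairing = pair_events(ref, tgt, max_lag)
    return pairing, fit_prepost_alignment(ref, tgt, pairing, n_pre, n_post)


class TestPairEvents:
    def test_identical_series_identity_matching(self):
        t = np.arange(300) * 2.0
        pairing = pair_events(EventSeries(t), EventSeries(t), max_lag=1.0)
        assert len(pairing) == 300
        np.testing.assert_array_equal(pairing.reference_indices, np.arange(300))
        np.testing.assert_array_equal(pairing.target_indices, np.arange(300))

    def test_pure_offset_below_max_lag(self):
        pairing = pair_events(events(0, 2, 4), events(0.5, 2.5, 4.5), max_lag=1.0)
        assert pairing.pairs == [(0, 0), (1, 1), (2, 2)]

    def test_dropped_reference_event_matches_brute_force(self):
        ref, tgt = np.array([0.0, 2, 4, 6]), np.array([0.5, 4.49, 6.5])
        pairing = pair_events(EventSeries(ref), EventSeries(tgt), max_lag=1.0)
        assert pairing.pairs == [(0, 0), (2, 1), (3, 2)]
        assert pairing.n_unmatched_reference == 1
        assert pairing.pairs == brute_force_pairing(ref, tgt, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_noisy_series_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = np.arange(7) * 2.0
        keep = rng.random(7) > 0.25
        tgt = np.sort(ref[keep] + 0.3 + rng.normal(0, 0.05, keep.sum()))
        if tgt.size == 0:
            pytest.skip("degenerate draw")
        pairing = pair_events(EventSeries(ref), EventSeries(tgt), max_lag=1.0)
        assert pairing.pairs == brute_force_pairing(ref, tgt, 1.0)

    def test_empty_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            pairing = pair_events(events(), events(0, 2), max_lag=1.0)
        assert len(pairing) == 0
        assert pairing.n_unmatched_target == 2

    def test_nonpositive_max_lag_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            pair_events(events(0), events(0), max_lag=0.0)


class TestPrePostAlignment:
    def test_identity_recovered(self):
        t = np.arange(20) * 2.0
        _, model = _pair_and_fit(EventSeries(t), EventSeries(t), 5, 5)
        assert model.offset == pytest.approx(0.0, abs=1e-12)
        assert model.scale == pytest.approx(1.0, abs=1e-12)

    def test_known_affine_map_inverted(self):
        ref = np.arange(50) * 2.0
        tgt = (ref - 0.5) / 1.0001
        ref_s, tgt_s = EventSeries(ref), EventSeries(tgt)
        pairing, model = _pair_and_fit(ref_s, tgt_s, 1, 1)
        mapped = transform_events(tgt_s, model).times
        np.testing.assert_allclose(mapped, ref, atol=1e-9)

    def test_anchor_medians_zero_to_machine_precision(self):
        rng = np.random.default_rng(3)
        ref = np.arange(300) * 2.0
        tgt = (ref + rng.normal(0, 1.7e-3, ref.size) - 0.25) / (1 + 1e-4)
        ref_s, tgt_s = EventSeries(ref), EventSeries(np.sort(tgt))
        pairing, model = _pair_and_fit(ref_s, tgt_s, 10, 10)
        resid = ref[pairing.reference_indices] - model.apply(
            tgt_s.times[pairing.target_indices]
        )
        assert abs(np.median(resid[:10])) < 1e-12
        assert abs(np.median(resid[-10:])) < 1e-12

    def test_matches_grid_search_oracle_on_small_series(self):
        rng = np.random.default_rng(11)
        ref = np.arange(40) * 2.0
        tgt = (ref + rng.normal(0, 1.7e-3, ref.size) - 0.1) / (1 + 2e-4)
        ref_s, tgt_s = EventSeries(ref), EventSeries(np.sort(tgt))
        pairing, model = _pair_and_fit(ref_s, tgt_s, 10, 10)
        r = ref[pairing.reference_indices]
        t = tgt_s.times[pairing.target_indices]
        da, db = 2e-4, 2e-6
        a0, b0, score = grid_search_prepost(
            r, t, 10, 10,
            (model.offset - 50 * da, model.offset + 50 * da),
            (model.scale - 50 * db, model.scale + 50 * db),
            n_grid=101,
        )
        assert model.offset == pytest.approx(a0, abs=da)
        assert model.scale == pytest.approx(b0, abs=db)

    @pytest.mark.parametrize("n_pre,n_post", [(1, 1), (3, 5), (10, 10)])
    def test_noise_free_recovery_of_injected_map(self, n_pre, n_post):
        ref = np.arange(100) * 2.0
        a_true, b_true = 0.72, 1 + 7.3e-4
        tgt = (ref - a_true) / b_true
        ref_s, tgt_s = EventSeries(ref), EventSeries(tgt)
        _, model = _pair_and_fit(ref_s, tgt_s, n_pre, n_post)
        assert model.offset == pytest.approx(a_true, rel=1e-9)
        assert model.scale == pytest.approx(b_true, rel=1e-9)

    def test_insufficient_anchors(self):
        t = np.arange(5) * 2.0
        pairing = pair_events(EventSeries(t), EventSeries(t), 1.0)
        with pytest.raises(InsufficientAnchorsError):
            fit_prepost_alignment(EventSeries(t), EventSeries(t), pairing, 3, 3)

    def test_two_pulse_minimal_fit(self):
        # the smallest legal configuration: single anchors at each end
        t = np.arange(2) * 2.0
        pairing = pair_events(EventSeries(t), EventSeries(t), 1.0)
        model = fit_prepost_alignment(EventSeries(t), EventSeries(t), pairing, 1, 1)
        assert model.offset == pytest.approx(0.0, abs=1e-12)
        assert model.scale == pytest.approx(1.0, abs=1e-12)


class TestPreOnlyAlignment:
    def test_identity(self):
        t = np.arange(20) * 2.0
        pairing = pair_events(EventSeries(t), EventSeries(t), 1.0)
        model = fit_pre_alignment(EventSeries(t), EventSeries(t), pairing, 10)
        assert model.offset == 0.0 and model.scale == 1.0
        assert model.method == "pre_only"

    def test_constant_delivery_delay_recovered(self):
        # cf. a hardware path with an advertised 72 ms delivery delay
        ref = np.arange(20) * 2.0
        tgt = ref - 0.072
        pairing = pair_events(EventSeries(ref), EventSeries(tgt), 1.0)
        model = fit_pre_alignment(EventSeries(ref), EventSeries(tgt), pairing, 5)
        assert model.offset == pytest.approx(0.072, abs=1e-12)

    def test_drift_residual_grows_linearly(self):
        delta = 1e-4
        ref = np.arange(300) * 2.0
        tgt = ref * (1 + delta)  # target clock runs fast, no jitter
        pairing = pair_events(EventSeries(ref), EventSeries(tgt), 1.0)
        model = fit_pre_alignment(EventSeries(ref), EventSeries(tgt), pairing, 10)
        resid = ref - model.apply(tgt)
        anchor = np.median(ref[:10])
        np.testing.assert_allclose(resid, -delta * (ref - anchor), atol=1e-9)

    def test_insufficient_anchors(self):
        t = np.arange(5) * 2.0
        pairing = pair_events(EventSeries(t), EventSeries(t), 1.0)
        with pytest.raises(InsufficientAnchorsError):
            fit_pre_alignment(EventSeries(t), EventSeries(t), pairing, 6)


class TestTransformEvents:
    @pytest.mark.parametrize(
        "model,times,expected",
        [
            (AlignmentModel.identity(), (0, 2, 4), (0, 2, 4)),
            (AlignmentModel(offset=1.0, scale=1.0), (0, 2, 4), (1, 3, 5)),
            (AlignmentModel(offset=0.0, scale=2.0), (1, 2), (2, 4)),
        ],
    )
    def test_affine_map(self, model, times, expected):
        out = transform_events(events(*times), model)
        np.testing.assert_allclose(out.times, expected)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        a=st.floats(-100, 100),
        b=st.floats(0.9, 1.1),
        n=st.integers(2, 30),
    )
    def test_round_trip_through_inverse(self, a, b, n):
        series = EventSeries(np.arange(n) * 2.0)
        model = AlignmentModel(offset=a, scale=b)
        back = transform_events(transform_events(series, model), model.invert())
        np.testing.assert_allclose(back.times, series.times, atol=1e-12)


class TestResampleTrace:
    def test_identity_model_bit_exact(self):
        rng = np.random.default_rng(0)
        trace = SampledTrace(rng.normal(size=1000), rate_nominal=1000.0)
        out = resample_trace(trace, AlignmentModel.identity(), out_rate=1000.0)
        np.testing.assert_array_equal(out.values, trace.values)
        assert out.start_time == trace.start_time

    def test_integer_sample_shift_zero_pads(self):
        rng = np.random.default_rng(1)
        trace = SampledTrace(rng.normal(size=100) + 5.0, rate_nominal=100.0)
        shift = 3 / 100.0
        out = resample_trace(trace, AlignmentModel(offset=shift, scale=1.0), out_rate=100.0)
        np.testing.assert_allclose(out.values[3:], trace.values[:-3], atol=1e-9)
        np.testing.assert_allclose(out.values[:3], 0.0, atol=1e-9)

    def test_linear_ramp_warped_exactly(self):
        # a linear signal is represented exactly by linear interpolation
        rate, b = 1000.0, 1 + 1e-4
        t = np.arange(2000) / rate
        trace = SampledTrace(t.copy(), rate_nominal=rate)
        out = resample_trace(trace, AlignmentModel(offset=0.0, scale=b), out_rate=rate)
        t_out = out.start_time + np.arange(len(out)) / rate
        interior = (t_out / b >= t[1]) & (t_out / b <= t[-2])
        np.testing.assert_allclose(out.values[interior], t_out[interior] / b, atol=1e-9)

    def test_crop_edge_drops_outside_samples(self):
        trace = SampledTrace(np.ones(100), rate_nominal=100.0)
        out = resample_trace(
            trace, AlignmentModel(offset=0.1, scale=1.0), out_rate=100.0, edge="crop"
        )
        assert len(out) == 90
        assert np.all(out.values == 1.0)

    def test_empty_trace(self):
        trace = SampledTrace(np.empty(0), rate_nominal=100.0)
        out = resample_trace(trace, AlignmentModel.identity())
        assert len(out) == 0


class TestInvariantsOfTypes:
    def test_event_series_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            EventSeries(np.array([0.0, 2.0, 2.0]))

    def test_trace_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            SampledTrace(np.array([0.0, np.nan]), rate_nominal=100.0)

    def test_pre_only_model_scale_locked(self):
        with pytest.raises(ValueError):
            AlignmentModel(offset=0.0, scale=1.001, method="pre_only")
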