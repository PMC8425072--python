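"""The four-step detector: smoothing, trend, searches, editing, summaries."""

import numpy as np
import pytest

from psckit.detection import (
    DetectionError,
    DetectionParams,
    baseline_search,
    delete_event,
    detect,
    estimate_trend,
    finalize_events,
    fit_decay,
    initial_search,
    redetect_sweep,
    select_events,
    sg_smooth,
    summarize_events,
    sweep_summaries,
)
from psckit.signalio import Recording
from psckit.simulation import (
    KernelParams,
    SimConfig,
    add_noise,
    match_events,
    precision_recall_f1,
    psc_kernel,
    simulate_recording,
)

from conftest import RATE, single_event_recording

KERNEL = KernelParams()


class TestSgSmooth:
    def test_constant_trace_unchanged(self):
        out = sg_smooth(np.full(200, -42.5), 3, 14)
        np.testing.assert_allclose(out, -42.5, rtol=1e-12)

    def test_cubic_reproduced_exactly(self):
        """A degree-3 filter reproduces any cubic, edges included."""
        x = np.linspace(-2, 2, 300)
        y = 0.3 * x**3 - 1.2 * x**2 + x - 7
        out = sg_smooth(y, 3, 14)
        np.testing.assert_allclose(out, y, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("poly,side", [(3, 14), (2, 5), (4, 20)])
    def test_polynomial_degree_leq_order_reproduced(self, poly, side):
        rng = np.random.default_rng(1)
        coeffs = rng.normal(size=poly + 1)
        x = np.linspace(0, 1, 400)
        y = np.polynomial.polynomial.polyval(x, coeffs)
        np.testing.assert_allclose(sg_smooth(y, poly, side), y, atol=1e-8)

    def test_interior_matches_per_point_regression_oracle(self):
        """Each interior output equals an independently solved LSQ fit."""
        rng = np.random.default_rng(2)
        y = rng.normal(size=120)
        poly, side = 3, 14
        out = sg_smooth(y, poly, side)
        for i in (side, 40, 60, 119 - side):
            xs = np.arange(i - side, i + side + 1) - i
            fit = np.polynomial.polynomial.polyfit(xs, y[i - side : i + side + 1], poly)
            assert out[i] == pytest.approx(fit[0], abs=1e-8)

    def test_edges_use_shrunken_windows(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        out = sg_smooth(y, 3, 10)
        xs = np.arange(0, 11).astype(float)  # first point: window [0, side]
        fit = np.polynomial.polynomial.polyfit(xs, y[:11], 3)
        assert out[0] == pytest.approx(fit[0], abs=1e-8)

    def test_window_must_fit_trace(self):
        with pytest.raises(DetectionError):
            sg_smooth(np.zeros(20), 3, 14)


class TestEstimateTrend:
    def test_flat_trace_reproduced(self):
        trend = estimate_trend(np.full(20000, -50.0), RATE)
        np.testing.assert_allclose(trend, -50.0, atol=1e-12)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 3, 20000)
        t1 = estimate_trend(y, RATE)
        t2 = estimate_trend(y + 17.5, RATE)
        np.testing.assert_allclose(t2 - t1, 17.5, atol=1e-9)

    def test_single_event_barely_perturbs_trend(self):
        rec = single_event_recording(amplitude_pa=30.0)
        trend = estimate_trend(rec.sweeps[0], RATE)
        assert np.max(np.abs(trend)) <= 1.5

    def test_trend_tracks_slow_drift_through_events(self):
        rec = single_event_recording(amplitude_pa=30.0, duration_s=2.0)
        drift = np.linspace(-40.0, -60.0, rec.n_samples)
        trend = estimate_trend(rec.sweeps[0] + drift, RATE)
        ss_res = np.sum((trend - drift) ** 2)
        ss_tot = np.sum((drift - drift.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99


class TestInitialSearch:
    def test_subthreshold_noise_yields_nothing(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.3, 20000)
        sm = sg_smooth(y, 3, 14)
        trend = estimate_trend(sm, RATE)
        assert initial_search(sm, trend, "negative", 3.0, RATE).size == 0

    def test_single_clean_event_single_candidate_at_kernel_peak(self):
        rec = single_event_recording(amplitude_pa=30.0, onset_s=0.5)
        sm = sg_smooth(rec.sweeps[0], 3, 14)
        trend = estimate_trend(sm, RATE)
        cand = initial_search(sm, trend, "negative", 3.0, RATE)
        assert cand.size == 1
        t_star_ms = 0.5 * 3.0 / 2.5 * np.log(6.0)  # analytic biexp peak time
        expected = int(round((0.5 + t_star_ms * 1e-3) * RATE))
        assert abs(int(cand[0]) - expected) <= 2

    def test_two_events_in_time_order(self):
        rec1 = single_event_recording(onset_s=0.4)
        rec2 = single_event_recording(onset_s=0.5)
        trace = rec1.sweeps[0] + rec2.sweeps[0]
        sm = sg_smooth(trace, 3, 14)
        trend = estimate_trend(sm, RATE)
        cand = initial_search(sm, trend, "negative", 3.0, RATE)
        assert cand.size == 2
        assert np.all(np.diff(cand) > 0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DetectionError):
            initial_search(np.zeros(10), np.zeros(11))


class TestBaselineSearch:
    def test_single_event_amplitude_recovered_within_5pct(self):
        rec = single_event_recording(amplitude_pa=30.0)
        evset = detect(rec, DetectionParams())
        assert evset.n_events == 1
        ev = evset.events[0]
        assert abs(ev.baseline_value_pa) <= 0.05 * 30.0
        assert ev.amplitude_pa == pytest.approx(30.0, rel=0.05)

    def test_monotone_run_longer_than_window_hits_edge(self):
        y = np.concatenate([np.linspace(0, -50, 400), np.linspace(-50, 0, 100)])
        b = baseline_search(y, 399, "negative", 10.0, RATE)
        assert b == 399 - 100  # 10 ms lookback at 10 kHz

    def test_polarity_symmetry(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 2, 2000) - 30 * np.exp(-((np.arange(2000) - 1500) / 40.0) ** 2)
        peak = int(np.argmin(y))
        b_neg = baseline_search(y, peak, "negative", 10.0, RATE)
        b_pos = baseline_search(-y, peak, "positive", 10.0, RATE)
        assert b_neg == b_pos

    def test_peak_at_zero_is_error(self):
        with pytest.raises(DetectionError):
            baseline_search(np.zeros(100), 0)


class TestFinalize:
    def make(self, amp):
        sm = np.zeros(100)
        sm[50] = -amp
        return sm

    def test_amplitude_below_threshold_discarded(self):
        events = finalize_events(self.make(9.9), [50], [10], DetectionParams(), RATE)
        assert events == []

    def test_amplitude_exactly_at_threshold_retained(self):
        events = finalize_events(self.make(10.0), [50], [10], DetectionParams(), RATE)
        assert len(events) == 1
        assert events[0].amplitude_pa == pytest.approx(10.0)

    def test_strict_boundary_configurable(self):
        params = DetectionParams(strict_amplitude=True)
        assert finalize_events(self.make(10.0), [50], [10], params, RATE) == []

    def test_low_noise_benchmark_amplitudes_all_above_minimum(self, benchmark):
        clean, truth = benchmark
        noisy = add_noise(clean, 2.0, seed=21)
        evset = detect(noisy, DetectionParams())
        assert evset.n_events >= 250
        assert np.all(evset.amplitudes >= 10.0)


class TestDetect:
    def test_single_30pa_event(self):
        rec = single_event_recording(amplitude_pa=30.0)
        evset = detect(rec, DetectionParams())
        assert evset.n_events == 1
        assert evset.events[0].amplitude_pa == pytest.approx(30.0, rel=0.05)

    def test_flat_recording_empty(self):
        rec = Recording(RATE, 1.0, np.full((2, int(RATE)), -40.0))
        assert detect(rec, DetectionParams()).n_events == 0

    def test_low_noise_benchmark_f1(self, benchmark):
        """sigma = 2 pA, default parameters: near-perfect detection."""
        clean, truth = benchmark
        noisy = add_noise(clean, 2.0, seed=21)
        evset = detect(noisy, DetectionParams())
        cm = match_events(evset, truth, duration_s=250.0)
        assert precision_recall_f1(cm)[2] >= 0.99

    def test_determinism(self):
        rec = single_event_recording()
        a = detect(rec, DetectionParams())
        b = detect(rec, DetectionParams())
        assert a.to_frame().equals(b.to_frame())

    def test_polarity_mirror_symmetry(self):
        clean, _ = simulate_recording(SimConfig(n_events=15, duration_s=15, seed=7))
        noisy = add_noise(clean, 4.0, seed=8)
        mirrored = Recording(noisy.sampling_rate_hz, noisy.sweep_duration_s,
                             -noisy.sweeps)
        neg = detect(noisy, DetectionParams(polarity="negative"))
        pos = detect(mirrored, DetectionParams(polarity="positive"))
        assert neg.n_events == pos.n_events
        np.testing.assert_allclose(neg.peak_times, pos.peak_times)
        np.testing.assert_allclose(neg.amplitudes, pos.amplitudes)
        np.testing.assert_allclose(
            [e.peak_value_pa for e in neg.events],
            [-e.peak_value_pa for e in pos.events],
        )

    def test_raising_threshold_yields_subset(self):
        clean, _ = simulate_recording(SimConfig(n_events=20, duration_s=20, seed=9))
        noisy = add_noise(clean, 6.0, seed=10)
        loose = detect(noisy, DetectionParams(min_amplitude_pa=5.0))
        tight = detect(noisy, DetectionParams(min_amplitude_pa=15.0))
        loose_keys = {(e.sweep_index, e.peak_index) for e in loose.events}
        tight_keys = {(e.sweep_index, e.peak_index) for e in tight.events}
        assert tight_keys <= loose_keys

    def test_detected_amplitude_unimodal_in_side_points(self):
        """Smoothing first deepens (overshoot) then attenuates a fixed event."""
        rec = single_event_recording(amplitude_pa=30.0)
        amps = []
        for side in range(2, 51, 4):
            evset = detect(rec, DetectionParams(side_points=side))
            assert evset.n_events == 1
            amps.append(evset.events[0].amplitude_pa)
        diffs = np.diff(amps)
        sign_changes = np.sum(np.diff(np.sign(diffs[diffs != 0])) != 0)
        assert sign_changes <= 1  # rises to a single maximum, then decays
        assert amps[-1] < amps[0]  # heavy smoothing attenuates


class TestFitDecay:
    def test_pure_exponential_recovered_within_1pct(self):
        tau_ms = 3.0
        t = np.arange(600) / RATE
        y = -5.0 + (-30.0 + 5.0) * np.exp(-t / (tau_ms * 1e-3))
        from psckit.detection import Event

        ev = Event(0, 0, 0.0, y[0], 0, 0.0, 30.0)
        res = fit_decay(y, ev, RATE)
        assert res.ok
        assert res.tau_ms == pytest.approx(tau_ms, rel=0.01)

    def test_flat_segment_flagged_failure(self):
        from psckit.detection import Event

        ev = Event(0, 0, 0.0, -20.0, 0, 0.0, 20.0)
        res = fit_decay(np.full(200, -20.0), ev, RATE)
        assert not res.ok and res.tau_ms is None

    def test_too_short_segment_flagged(self):
        from psckit.detection import Event

        ev = Event(0, 195, 0.0, -20.0, 190, 0.0, 20.0)
        res = fit_decay(np.linspace(0, -20, 200), ev, RATE)
        assert not res.ok

    def test_kernel_event_tau_within_15pct_of_tau2(self):
        rec = single_event_recording(amplitude_pa=30.0)
        evset = detect(rec, DetectionParams())
        res = fit_decay(rec.sweeps[0], evset.events[0], RATE)
        assert res.ok
        assert res.tau_ms == pytest.approx(KERNEL.tau2_ms, rel=0.15)


class TestEditing:
    def test_redetect_with_same_params_is_identity(self, small_eventset):
        rec, evset = small_eventset
        again = redetect_sweep(rec, evset, 0, evset.params_used)
        assert again.to_frame().drop(columns=["selected"]).equals(
            evset.to_frame().drop(columns=["selected"])
        )

    def test_redetect_other_sweeps_untouched(self):
        clean, _ = simulate_recording(SimConfig(n_events=12, duration_s=12, seed=13))
        rec = Recording(clean.sampling_rate_hz, 4.0,
                        clean.sweeps[0].reshape(3, -1))
        evset = detect(rec, DetectionParams())
        override = DetectionParams(min_amplitude_pa=20.0, side_points=30)
        redone = redetect_sweep(rec, evset, 1, override)
        for sweep in (0, 2):
            before = [e.peak_index for e in evset.events_of_sweep(sweep)]
            after = [e.peak_index for e in redone.events_of_sweep(sweep)]
            assert before == after
        assert redone.overrides == {1: override}

    def test_redetect_with_looser_threshold_recovers_missed_event(self):
        """A borderline event lost to a strict criterion reappears on
        redetection with adjusted parameters; prior events persist."""
        strong = single_event_recording(amplitude_pa=30.0, onset_s=0.4)
        weak = single_event_recording(amplitude_pa=12.0, onset_s=1.2)
        rec = Recording(RATE, 2.0, strong.sweeps + weak.sweeps)
        evset = detect(rec, DetectionParams(min_amplitude_pa=15.0))
        assert evset.n_events == 1
        redone = redetect_sweep(rec, evset, 0, DetectionParams(min_amplitude_pa=10.0))
        assert redone.n_events == 2
        assert evset.events[0].peak_index in [e.peak_index for e in redone.events]

    def test_delete_then_redetect_restores(self, small_eventset):
        rec, evset = small_eventset
        n = evset.n_events
        dropped = delete_event(evset, 1)
        assert dropped.n_events == n - 1
        restored = redetect_sweep(rec, dropped, 0, evset.params_used)
        assert restored.n_events == n

    def test_delete_unknown_identifier(self, small_eventset):
        _, evset = small_eventset
        with pytest.raises(DetectionError):
            delete_event(evset, evset.n_events)

    def test_delete_twice_errors_on_missing(self, small_eventset):
        _, evset = small_eventset
        once = delete_event(evset, evset.n_events - 1)
        with pytest.raises(DetectionError):
            delete_event(once, once.n_events)


class TestSelection:
    def test_select_all(self, small_eventset):
        _, evset = small_eventset
        sel = select_events(evset, 0, evset.n_events)
        assert sel.selected_mask.sum() == evset.n_events

    def test_select_contiguous_block(self, small_eventset):
        _, evset = small_eventset
        sel = select_events(evset, 1, 2)
        np.testing.assert_array_equal(sel.selected_mask, [0, 1, 1])

    def test_reselection_overwrites(self, small_eventset):
        _, evset = small_eventset
        sel = select_events(select_events(evset, 0, 2), 2, 1)
        np.testing.assert_array_equal(sel.selected_mask, [0, 0, 1])

    def test_deficit_reported(self, small_eventset):
        _, evset = small_eventset
        with pytest.raises(DetectionError, match="2 event"):
            select_events(evset, 2, 3)

    def test_selected_stats_match_recompute(self, small_eventset):
        _, evset = small_eventset
        sel = select_events(evset, 1, 2)
        table = summarize_events(sel)
        mask = sel.selected_mask.astype(bool)
        assert table.loc["selected", "mean_amplitude_pa"] == pytest.approx(
            sel.amplitudes[mask].mean()
        )


class TestSummaries:
    def test_flat_sweep_row(self):
        rec = Recording(RATE, 1.0, np.full((1, int(RATE)), -45.0))
        table = sweep_summaries(rec, detect(rec, DetectionParams()))
        row = table.iloc[0]
        assert row["mean_holding_current_pa"] == pytest.approx(-45.0)
        assert row["n_events"] == 0
        assert np.isnan(row["mean_amplitude_pa"])

    def test_event_counts_conserved(self, small_eventset):
        rec, evset = small_eventset
        table = sweep_summaries(rec, evset)
        assert table["n_events"].sum() == evset.n_events

    def test_iei_from_absolute_times(self, small_eventset):
        _, evset = small_eventset
        table = summarize_events(evset)
        times = evset.peak_times
        assert table.loc["total", "mean_iei_s"] == pytest.approx(np.diff(times).mean())

    def test_single_event_iei_missing(self):
        rec = single_event_recording()
        table = summarize_events(detect(rec, DetectionParams()))
        assert table.loc["total", "n"] == 1
        assert np.isnan(table.loc["total", "mean_iei_s"])
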