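"""Generator-level tests: pulse shapes, the OSN rate model, presynaptic
inhibition, spike sampling, signal rendering, and fly simulation."""

import numpy as np
import pytest

from odorcontrast import contrast, synthgen as sg, traceproc
from odorcontrast.core import (
    ArenaConfig,
    BleachModel,
    InvalidInputError,
    InvalidParameterError,
    TimeSeries,
)


class TestMakeOdorPulse:
    def test_zero_duration_gives_all_zero_trace(self):
        spec = sg.OdorPulseSpec(onset_s=1.0, duration_s=0.0, peak=1.0)
        ts = sg.make_odor_pulse(spec, total_s=4.0, sample_rate=125.0)
        assert np.all(ts.values == 0.0)

    def test_post_offset_decay_is_first_order(self):
        # one decay time constant after offset the trace is at e^-1 of its
        # offset value
        spec = sg.OdorPulseSpec(onset_s=1.0, duration_s=1.0, peak=1.0,
                                rise_tau_s=0.02, decay_tau_s=0.4)
        ts = sg.make_odor_pulse(spec, total_s=6.0, sample_rate=1000.0)
        v_off = ts.value_at(spec.offset_s)
        v_tau = ts.value_at(spec.offset_s + spec.decay_tau_s)
        assert v_tau == pytest.approx(np.exp(-1.0) * v_off, rel=5e-3)

    def test_rise_completes_for_fast_rise_tau(self):
        # 1 s pulse with 0.05 s rise: offset value is 1 - e^-20 of peak
        # (onset on the sample grid so the offset sample is exact)
        spec = sg.OdorPulseSpec(onset_s=1.0, duration_s=1.0, peak=2.0, rise_tau_s=0.05)
        ts = sg.make_odor_pulse(spec, total_s=4.0, sample_rate=125.0)
        assert ts.value_at(spec.offset_s) >= 0.99 * spec.peak

    def test_zero_baseline_before_onset(self, std_pulse):
        ts = sg.make_odor_pulse(std_pulse, total_s=8.0, sample_rate=125.0)
        assert np.all(ts.window_slice(0.0, std_pulse.onset_s) == 0.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            sg.OdorPulseSpec(rise_tau_s=-1.0)
        with pytest.raises(InvalidParameterError):
            sg.make_odor_pulse(sg.OdorPulseSpec(), total_s=8.0, sample_rate=0.0)
        with pytest.raises(InvalidParameterError):
            # trace does not cover the pulse
            sg.make_odor_pulse(sg.OdorPulseSpec(onset_s=5.0), total_s=4.0, sample_rate=125.0)


class TestArenaPid:
    def test_identity_profile_at_distance_zero(self, std_pulse):
        ts_port = sg.arena_pid(0.0, std_pulse, profile=lambda d: (1.0, 1.0),
                               total_s=8.0)
        ts_ref = sg.make_odor_pulse(std_pulse, total_s=8.0, sample_rate=125.0)
        np.testing.assert_array_equal(ts_port.values, ts_ref.values)

    def test_decay_time_increases_with_distance(self, std_pulse):
        # plume-like dynamics near the port, slow swell beyond 3-4 cm
        tau_near = contrast.decay_time(sg.arena_pid(2.0, std_pulse, total_s=20.0))
        tau_far = contrast.decay_time(sg.arena_pid(5.0, std_pulse, total_s=20.0))
        assert tau_near < tau_far

    def test_tau_and_peak_monotone_over_grid(self, std_pulse):
        taus, peaks = [], []
        for d in np.linspace(0.0, 5.0, 11):
            ts = sg.arena_pid(d, std_pulse, total_s=25.0)
            taus.append(contrast.decay_time(ts))
            peaks.append(ts.values.max())
        assert np.all(np.diff(taus) >= -1e-9)
        assert np.all(np.diff(peaks) <= 1e-9)

    def test_distance_beyond_arena_rejected(self, std_pulse):
        with pytest.raises(InvalidParameterError):
            sg.arena_pid(12.0, std_pulse)


class TestOsnRate:
    def test_zero_stimulus_gives_constant_spontaneous_rate(self):
        pid = TimeSeries(t0=0.0, sample_rate=125.0, values=np.zeros(500))
        rate = sg.osn_rate(pid, sg.OSNParams(r_spont=8.0))
        np.testing.assert_allclose(rate.values, 8.0)

    def test_supra_threshold_pulse_sustains_postpulse_firing(self, std_pid):
        # sustained firing 1.5 s after offset for intensities above the
        # sustained-activity threshold
        p = sg.OSNParams()
        rate = sg.osn_rate(std_pid, p)
        assert rate.value_at(3.5) > p.r_spont

    def test_sub_threshold_pulse_inhibits_postpulse_firing(self, weak_pulse):
        pid = sg.make_odor_pulse(weak_pulse, total_s=8.0, sample_rate=125.0)
        p = sg.OSNParams()
        rate = sg.osn_rate(pid, p)
        assert rate.value_at(3.5) < p.r_spont

    def test_adaptation_matches_closed_form_solution(self):
        # constant stimulus, no sustained component, no inhibition during
        # the pulse: a(t) = (1-depth) + depth*exp(-(t-onset)/tau), so the
        # end-of-pulse / peak rate ratio has a closed form
        p = sg.OSNParams(r_spont=5.0, gain=100.0, adapt_tau_s=0.3, adapt_depth=0.6,
                         sustain_threshold=10.0, inhib_depth=0.0)
        sr, onset, dur, peak = 2000.0, 0.5, 1.0, 0.4
        t = np.arange(int(3.0 * sr)) / sr
        step = np.where((t >= onset) & (t < onset + dur), peak, 0.0)
        rate = sg.osn_rate(TimeSeries(t0=0.0, sample_rate=sr, values=step), p)
        r_peak = rate.values.max()
        r_end = rate.value_at(onset + dur - rate.dt)
        a_end = (1 - p.adapt_depth) + p.adapt_depth * np.exp(-dur / p.adapt_tau_s)
        expected = (p.r_spont + p.gain * peak * a_end) / (p.r_spont + p.gain * peak)
        assert r_end / r_peak == pytest.approx(expected, rel=0.01)

    def test_mismatched_negative_pid_rejected(self):
        pid = TimeSeries(t0=0.0, sample_rate=125.0, values=np.array([0.0, -0.1, 0.0]))
        with pytest.raises(InvalidInputError):
            sg.osn_rate(pid, sg.OSNParams())


class TestPresynapticInhibition:
    def test_zero_weights_are_identity(self, sustained_rate):
        q = sg.InhibitionParams(gA_weight=0.0, gB_weight=0.0)
        out = sg.apply_presynaptic_inhibition(sustained_rate, q)
        np.testing.assert_array_equal(out.values, sustained_rate.values)

    def test_never_increases_rate_and_never_negative(self, sustained_rate):
        out = sg.apply_presynaptic_inhibition(sustained_rate, sg.InhibitionParams())
        assert np.all(out.values <= sustained_rate.values + 1e-12)
        assert np.all(out.values >= 0.0)

    def test_inhibition_sharpens_sustained_response(self, sustained_rate):
        before = contrast.sharpness_offset(sustained_rate, 2.0).coefficient
        out = sg.apply_presynaptic_inhibition(sustained_rate, sg.InhibitionParams())
        after = contrast.sharpness_offset(out, 2.0).coefficient
        assert after >= before

    def test_disabling_both_kernels_raises_peak(self, sustained_rate):
        on = sg.apply_presynaptic_inhibition(sustained_rate, sg.InhibitionParams())
        off = sg.apply_presynaptic_inhibition(
            sustained_rate, sg.InhibitionParams(gA_enabled=False, gB_enabled=False)
        )
        assert off.values.max() > on.values.max()

    def test_kernel_tau_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            sg.InhibitionParams(gA_tau_s=2.0, gB_tau_s=1.0)


class TestSampleSpikes:
    def test_zero_rate_gives_empty_train(self):
        rate = TimeSeries(t0=0.0, sample_rate=125.0, values=np.zeros(1000))
        train = sg.sample_spikes(rate, seed=0)
        assert train.n == 0

    def test_fixed_seed_reproducible(self, sustained_rate):
        a = sg.sample_spikes(sustained_rate, seed=42)
        b = sg.sample_spikes(sustained_rate, seed=42)
        np.testing.assert_array_equal(a.times, b.times)

    def test_interspike_intervals_respect_refractory(self, sustained_rate):
        train = sg.sample_spikes(sustained_rate, refractory_s=0.002, seed=7)
        assert train.n > 10
        assert np.all(np.diff(train.times) >= 0.002)

    def test_mean_count_matches_rate_integral(self):
        # Monte-Carlo oracle: for refractory << 1/r the thinned process is
        # Poisson with mean = integral of r dt
        rate = TimeSeries(t0=0.0, sample_rate=100.0, values=np.full(500, 12.0))
        expected = 12.0 * 5.0
        counts = [sg.sample_spikes(rate, refractory_s=1e-4, seed=s).n for s in range(500)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-9


class TestRenderExtracellular:
    def test_silence_renders_to_zero(self):
        from odorcontrast.core import SpikeTrain

        empty = SpikeTrain(unit_label="A", times=np.empty(0), amplitudes=np.empty(0))
        ts = sg.render_extracellular([(empty, 10.0)], total_s=0.5, noise_sd=0.0)
        assert np.all(ts.values == 0.0)

    def test_single_spike_extremum_near_spike_time(self):
        from odorcontrast.core import SpikeTrain

        train = SpikeTrain(unit_label="A", times=np.array([0.25]), amplitudes=np.array([1.0]))
        ts = sg.render_extracellular([(train, 8.0)], total_s=0.5, noise_sd=0.0)
        t_ext = ts.times[np.argmax(np.abs(ts.values))]
        assert abs(t_ext - 0.25) <= 1e-3

    def test_spike_outside_span_rejected(self):
        from odorcontrast.core import SpikeTrain

        train = SpikeTrain(unit_label="A", times=np.array([1.0]), amplitudes=np.array([1.0]))
        with pytest.raises(InvalidInputError):
            sg.render_extracellular([(train, 8.0)], total_s=0.5)


class TestRenderFluorescence:
    def test_zero_drive_returns_exact_bleach_baseline(self, bleach):
        drive = TimeSeries(t0=0.0, sample_rate=125.0, values=np.zeros(1000))
        f = sg.render_arclight(drive, bleach=bleach, noise_sd=0.0)
        np.testing.assert_allclose(f.values, bleach.baseline(f.times), rtol=1e-12)

    def test_gcamp_zero_rate_returns_pure_baseline(self, bleach):
        rate = TimeSeries(t0=0.0, sample_rate=125.0, values=np.zeros(1000))
        f = sg.render_gcamp(rate, bleach=bleach, noise_sd=0.0)
        np.testing.assert_allclose(f.values, bleach.baseline(f.times), rtol=1e-12)

    def test_saturation_compresses_response_ratio(self, sustained_rate, bleach):
        # the during-pulse / postpulse response ratio shrinks when the
        # indicator saturates during the pulse
        lin = sg.render_arclight(sustained_rate, sat_level=np.inf, bleach=bleach)
        satd = sg.render_arclight(sustained_rate, sat_level=0.5, bleach=bleach)

        def ratio(f):
            dff = 100.0 * (f.values / bleach.baseline(f.times) - 1.0)
            ts = f.copy_with(dff)
            return abs(ts.value_at(1.9)) / abs(ts.value_at(3.5))

        assert ratio(satd) < ratio(lin)

    def test_gcamp_slow_kernel_sustains_postpulse_signal(self, sustained_rate, bleach):
        # 3 s calcium decay: 1.5 s after offset the ΔF/F is still above
        # half its in-pulse maximum, unlike the electrical response
        f = sg.render_gcamp(sustained_rate, ca_rise_s=0.05, ca_decay_s=3.0, bleach=bleach)
        dff = f.copy_with(100.0 * (f.values / bleach.baseline(f.times) - 1.0))
        assert dff.value_at(3.5) > 0.5 * dff.values.max()

    def test_gcamp_linearity_in_unsaturated_regime(self, sustained_rate, bleach):
        ref = float(sustained_rate.values.max())
        half = sustained_rate.copy_with(sustained_rate.values / 2.0)
        f1 = sg.render_gcamp(sustained_rate, bleach=bleach, drive_ref=ref, sat_level=np.inf)
        f2 = sg.render_gcamp(half, bleach=bleach, drive_ref=ref, sat_level=np.inf)
        d1 = f1.values / bleach.baseline(f1.times) - 1.0
        d2 = f2.values / bleach.baseline(f2.times) - 1.0
        mask = np.abs(d1) > 1e-4
        np.testing.assert_allclose(d2[mask], d1[mask] / 2.0, rtol=0.01)


class TestRenderMovie:
    def test_noiseless_roi_pixels_equal_trace(self, bleach):
        trace = TimeSeries(t0=0.0, sample_rate=125.0, values=np.linspace(1.0, 2.0, 50))
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:20, 30:40] = True
        stack = sg.render_movie(trace, mask, pixel_noise_sd=0.0)
        np.testing.assert_array_equal(stack[:, mask], np.tile(trace.values[:, None], (1, mask.sum())))

    def test_roi_average_recovers_trace_within_noise_bound(self):
        trace = TimeSeries(t0=0.0, sample_rate=125.0, values=np.full(200, 500.0))
        mask = np.zeros((80, 80), dtype=bool)
        mask[20:40, 20:40] = True  # 400 pixels
        sd = 5.0
        stack = sg.render_movie(trace, mask, pixel_noise_sd=sd, seed=3)
        rec = traceproc.roi_average(stack, mask, sample_rate=125.0)
        # per-frame error is ~N(0, sd/sqrt(mask size)); check the RMSE and
        # that no frame is a gross outlier
        se = sd / np.sqrt(mask.sum())
        err = rec.values - trace.values
        assert np.sqrt(np.mean(err**2)) < 1.2 * se
        assert np.max(np.abs(err)) < 5 * se

    def test_fixed_seed_identical_stack(self):
        trace = TimeSeries(t0=0.0, sample_rate=125.0, values=np.ones(10))
        mask = np.ones((80, 80), dtype=bool)
        a = sg.render_movie(trace, mask, pixel_noise_sd=1.0, seed=5)
        b = sg.render_movie(trace, mask, pixel_noise_sd=1.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empty_mask_rejected(self):
        trace = TimeSeries(t0=0.0, sample_rate=125.0, values=np.ones(10))
        with pytest.raises(InvalidParameterError):
            sg.render_movie(trace, np.zeros((80, 80), dtype=bool))

    def test_tiff_roundtrip(self, tmp_path):
        trace = TimeSeries(t0=0.0, sample_rate=125.0, values=np.linspace(0, 10, 12))
        mask = np.zeros((80, 80), dtype=bool)
        mask[5:9, 5:9] = True
        stack = sg.render_movie(trace, mask, pixel_noise_sd=0.5, seed=4)
        path = tmp_path / "movie.tif"
        sg.write_movie_tiff(stack, path)
        back = sg.read_movie_tiff(path)
        assert back.shape == stack.shape
        np.testing.assert_allclose(back, stack, rtol=1e-6)


class TestSimulateFlies:
    def test_positions_stay_inside_arena(self, arena, std_pulse):
        bp = sg.BehaviorParams(drift_gain=sg.avoidance_drift(), persistence_s=1.0)
        trajs, _ = sg.simulate_flies(20, arena, bp, [std_pulse], total_s=6.0, seed=11)
        for tr in trajs:
            assert np.all(np.linalg.norm(tr.xy, axis=1) <= arena.radius_cm + 1e-9)

    def test_zero_drift_net_displacement_unbiased(self, arena, std_pulse):
        # Monte-Carlo oracle: without chemotactic drift the mean change in
        # distance-to-port over the pulse is zero within 3 SE
        from odorcontrast import behavior

        bp = sg.BehaviorParams(drift_gain=lambda c: 0.0)
        port = arena.active_port_xy
        means = []
        for seed in range(200):
            trajs, _ = sg.simulate_flies(3, arena, bp, [std_pulse], total_s=3.0, seed=seed)
            net = behavior.net_displacement(trajs, port, pulse_end_s=2.0, onset_s=1.0)
            means.append(net.attrs["mean"])
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-9

    def test_avoidance_regime_repels_flies(self, arena):
        from odorcontrast import behavior

        spec = sg.OdorPulseSpec(onset_s=1.0, duration_s=10.0, peak=1.5, dilution_label="1:1")
        bp = sg.BehaviorParams(drift_gain=sg.avoidance_drift(), persistence_s=0.5)
        trajs, _ = sg.simulate_flies(40, arena, bp, [spec], total_s=13.0, seed=21)
        net = behavior.net_displacement(trajs, arena.active_port_xy, pulse_end_s=11.0, onset_s=1.0)
        assert net.attrs["mean"] < 0  # mean Δd at pulse end negative = avoidance

    def test_detection_table_matches_trajectories_when_clean(self, arena, std_pulse):
        bp = sg.BehaviorParams(drift_gain=lambda c: 0.0)
        trajs, det = sg.simulate_flies(5, arena, bp, [std_pulse], total_s=3.0, seed=2)
        assert len(det) == 5 * trajs[0].n
        one = det[det["fly_id"] == 3].sort_values("frame")
        np.testing.assert_allclose(one[["x_cm", "y_cm"]].to_numpy(), trajs[3].xy)

    def test_same_seed_is_deterministic(self, arena, std_pulse):
        bp = sg.BehaviorParams(drift_gain=sg.avoidance_drift())
        t1, d1 = sg.simulate_flies(4, arena, bp, [std_pulse], total_s=3.0, seed=9)
        t2, d2 = sg.simulate_flies(4, arena, bp, [std_pulse], total_s=3.0, seed=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.xy, b.xy)
        assert d1.equals(d2)
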