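"""Synthetic generator: kernel shapes, sensor kinetics, renderer, behavior."""

import numpy as np
import pytest

import oddphot as op
from oddphot.synth import Bump


class TestSensorResponse:
    def test_impulse_rise_time_70ms(self, sensor):
        h = op.sensor_impulse_response(sensor, 1000.0)
        assert op.rise_time_10_90(h, 1000.0) * 1e3 == pytest.approx(70.0, abs=0.5)

    def test_constant_input_constant_output(self, sensor):
        x = np.full(3000, 2.0)
        y = op.sensor_response(x, sensor, 100.0)
        gain = op.synth.sensor_steady_state_gain(sensor, 100.0)
        # once transients settle, output is the constant times the DC gain
        assert np.allclose(y[-100:], 2.0 * gain, rtol=1e-6)

    def test_linearity_of_stacked_impulses(self, sensor):
        x1 = np.zeros(500); x1[10] = 1.0
        x2 = np.zeros(500); x2[200] = 1.0
        y1 = op.sensor_response(x1, sensor, 100.0)
        y2 = op.sensor_response(x2, sensor, 100.0)
        y12 = op.sensor_response(x1 + x2, sensor, 100.0)
        assert np.allclose(y12, y1 + y2, atol=1e-12)

    def test_decay_not_exceeding_rise_rejected(self):
        with pytest.raises(op.ParameterError):
            op.SensorParams(rise_s=0.5, decay_s=0.1)


class TestDopamineKernel:
    def test_zero_amplitude_gives_zero_trace(self):
        k = op.KernelParams(
            onset_positive=Bump(96, 0.0, 30, 50),
            onset_negative=Bump(602, 0.0, 150, 200),
            intra_dip_z=0.0,
            offset_positive=Bump(549, 0.0, 150, 250),
            intensity_gain=0.0,
        )
        ev = op.StimulusEvent(onset=0, duration=6.0, intensity=80)
        assert np.all(op.dopamine_kernel(k, ev, 1000.0) == 0.0)

    def test_nominal_peak_in_onset_window(self, kernel):
        ev = op.StimulusEvent(onset=0, duration=6.0, intensity=80)
        y = op.dopamine_kernel(kernel, ev, 1000.0)
        t = np.arange(y.size) / 1000.0
        m = (t > 0) & (t <= 0.3)
        i = np.argmax(y[m])
        assert t[m][i] == pytest.approx(0.096, abs=0.002)

    def test_drop_amplitude_proportional_to_decrement(self, kernel):
        """80->60 vs 80->20: nominal drop amplitudes in ratio 20:60."""
        evs = {
            db: op.StimulusEvent(
                onset=0, duration=6.0, intensity=80, intensity2=db, change_time=3.0
            )
            for db in (60.0, 20.0)
        }
        amps = {}
        for db, ev in evs.items():
            y = op.dopamine_kernel(kernel, ev, 1000.0)
            y0 = op.dopamine_kernel(
                kernel,
                op.StimulusEvent(onset=0, duration=6.0, intensity=80),
                1000.0,
            )
            amps[db] = (y - y0).max()
        assert amps[60.0] / amps[20.0] == pytest.approx(20.0 / 60.0, rel=1e-9)


class TestCalibratedEventResponse:
    def test_long_stimulus_hits_targets_on_fine_grid(self, kernel, sensor):
        ev = op.StimulusEvent(onset=0, duration=6.0, intensity=80)
        y = op.event_response(kernel, sensor, ev, 1000.0)
        t = np.arange(y.size) / 1000.0
        f = op.component_features(t, y, 6.0)
        assert f.onset_positive == pytest.approx((0.224, 96.0), abs=1e-3)
        assert f.onset_negative == pytest.approx((-0.860, 602.0), abs=1e-3)
        assert f.offset_positive == pytest.approx((0.744, 549.0), abs=1e-3)
        assert f.intra_dip == pytest.approx(-0.327, abs=1e-3)

    def test_deviant_gain_scales_value_components_only(self, sensor):
        k15 = op.KernelParams(deviant_gain=1.5)
        dev = op.StimulusEvent(
            onset=0, duration=6.0, intensity=80, role="deviant"
        )
        std = op.StimulusEvent(
            onset=0, duration=6.0, intensity=80, role="standard"
        )
        yd = op.event_response(k15, sensor, dev, 1000.0)
        ys = op.event_response(k15, sensor, std, 1000.0)
        t = np.arange(yd.size) / 1000.0
        fd = op.component_features(t, yd, 6.0)
        fs = op.component_features(t, ys, 6.0)
        assert fd.intra_dip == pytest.approx(1.5 * fs.intra_dip, rel=0.01)
        assert fd.onset_negative[0] < fs.onset_negative[0]
        # onset-positive (alerting component) nearly unchanged; the deepened
        # trough spills slightly into the onset window
        assert fd.onset_positive[0] == pytest.approx(fs.onset_positive[0], rel=0.10)


class TestRenderRecording:
    def test_zero_kernel_zero_noise_gives_flat_dff(self, sensor):
        k = op.KernelParams(
            onset_positive=Bump(96, 0.0, 30, 50),
            onset_negative=Bump(602, 0.0, 150, 200),
            intra_dip_z=0.0,
            offset_positive=Bump(549, 0.0, 150, 250),
        )
        noise = op.NoiseParams(
            white_sd_exc=0.0,
            white_sd_iso=0.0,
            artifact_sd=0.0,
            bleach_exc=((0.0, 60.0),),
            bleach_iso=((0.0, 60.0),),
        )
        seq = op.gen_simple(6.0, 80.0, 2, 3.0)
        rec, _ = op.render_recording(seq, kernel=k, sensor=sensor, noise=noise)
        dff = op.preprocess_recording(rec)
        assert np.max(np.abs(dff.dff)) < 1e-12

    def test_noise_free_latency_recovery_within_one_sample(
        self, simple_recording_noise_free
    ):
        rec, truth = simple_recording_noise_free
        dff = op.preprocess_recording(rec)
        zt = op.zscore(dff, "global_session")
        epochs = op.extract_epochs(zt, rec.events, window=(-2.0, 8.0))
        f = op.component_features(epochs.t_rel, epochs.data.mean(axis=0), 6.0)
        lats = truth.events[0]["latencies_ms"]
        dt_ms = 1e3 / rec.sampling_rate
        assert abs(f.onset_positive[1] - lats["onset_positive"]) <= dt_ms
        assert abs(f.onset_negative[1] - lats["onset_negative"]) <= dt_ms
        assert abs(f.offset_positive[1] - lats["offset_positive"]) <= dt_ms

    def test_same_seed_identical_recordings(self, kernel, sensor):
        seq = op.gen_simple(1.0, 80.0, 2, 1.0)
        r1, _ = op.render_recording(seq, kernel=kernel, sensor=sensor, seed=5)
        r2, _ = op.render_recording(seq, kernel=kernel, sensor=sensor, seed=5)
        assert np.array_equal(r1.excitation, r2.excitation)
        assert np.array_equal(r1.isosbestic, r2.isosbestic)

    def test_common_mode_artifact_rejection(self, sensor):
        """Shared artifact is attenuated >= 10x vs single-channel dF/F."""
        k = op.KernelParams(
            onset_positive=Bump(96, 0.0, 30, 50),
            onset_negative=Bump(602, 0.0, 150, 200),
            intra_dip_z=0.0,
            offset_positive=Bump(549, 0.0, 150, 250),
        )
        noise = op.NoiseParams(white_sd_exc=0.0, white_sd_iso=0.0, artifact_sd=0.01)
        seq = op.gen_simple(6.0, 80.0, 3, 3.0)
        rec, _ = op.render_recording(seq, kernel=k, sensor=sensor, noise=noise, seed=3)
        dff = op.preprocess_recording(rec)
        single = (rec.excitation - rec.excitation.mean()) / rec.excitation.mean()
        assert single.std() / dff.dff.std() >= 10.0

    def test_drop_amplitude_monotone_in_decrement(self, kernel, sensor, noise_free):
        """Noise-free extracted drop-positive increases with |dB step|."""
        amps = []
        for db2 in (60.0, 40.0, 20.0):
            ev = op.StimulusEvent(
                onset=0, duration=6.0, intensity=80, intensity2=db2, change_time=3.0
            )
            y = op.event_response(kernel, sensor, ev, 100.0)
            t = np.arange(y.size) / 100.0
            amps.append(op.drop_positive(t, y, 3.0)[0])
        assert amps[0] < amps[1] < amps[2]
        r, _ = op.spearman(np.array([20.0, 40.0, 60.0]), np.array(amps))
        assert r == pytest.approx(1.0)

    def test_recording_io_round_trip(self, tmp_path, kernel, sensor, noise_free):
        seq = op.gen_simple(1.0, 80.0, 2, 1.0)
        rec, truth = op.render_recording(
            seq, kernel=kernel, sensor=sensor, noise=noise_free, seed=2
        )
        h5 = tmp_path / "rec.h5"
        rec.to_hdf5(h5)
        back = op.PhotometryRecording.from_hdf5(h5)
        assert np.allclose(back.excitation, rec.excitation)
        assert len(back.events.events) == 2
        truth.to_json(tmp_path / "truth.json")
        csv = tmp_path / "rec.csv"
        rec.to_csv(csv)
        back2 = op.PhotometryRecording.from_csv(csv)
        assert np.allclose(back2.isosbestic, rec.isosbestic)


class TestParameterRecovery:
    def test_median_errors_under_default_noise(self, kernel, sensor):
        """Over simulated animals at default noise, pooled median |latency
        error| < 2 samples and median baseline-corrected amplitude error
        < 10% (dF/F units via the stored normalization)."""
        lat_err, amp_err = [], []
        targets = {"onset_positive": 96.0, "onset_negative": 602.0,
                   "offset_positive": 549.0}
        n_subj = 100
        for s in range(n_subj):
            seq = op.gen_simple(6.0, 80.0, 10, 3.0)
            rec, truth = op.render_recording(seq, kernel=kernel, sensor=sensor,
                                             seed=5000 + s)
            dff = op.preprocess_recording(rec)
            zt = op.zscore(dff, "global_session")
            ep = op.extract_epochs(zt, rec.events, window=(-2.0, 8.0))
            f = op.component_features(ep.t_rel, ep.data.mean(axis=0), 6.0)
            inj = truth.events[0]["amplitudes_dff"]
            base = f.baseline_at_onset
            for comp in targets:
                a, lat = getattr(f, comp)
                lat_err.append(abs(lat - targets[comp]) * rec.sampling_rate / 1e3)
                amp_err.append(abs((a - base) * zt.sd / inj[comp] - 1.0))
            amp_err.append(abs((f.intra_dip - base) * zt.sd / inj["intra_dip"] - 1.0))
        assert np.median(lat_err) < 2.0
        assert np.median(amp_err) < 0.10


class TestBehaviorSimulation:
    def test_unbiased_walker_pi_near_zero(self):
        sessions = op.simulate_place_sessions(op.BehaviorSimParams(), 10000, seed=21)
        assert abs(op.preference_index(sessions, "noise")) < 0.02

    def test_zero_weight_condition_never_goal(self):
        p = op.BehaviorSimParams(weights={"x": 0.0, "y": 1.0})
        sessions = op.simulate_place_sessions(p, 2000, seed=3)
        assert all(s.goal_condition == "y" for s in sessions)
        assert op.preference_index(sessions, "x") <= 0.0

    def test_weighted_pi_matches_closed_form(self):
        """Weights (1, 3) on two conditions: Pr(goal in heavy) = 3/4
        independent of start, so PI = 3/4 - 1/4 = 1/2."""
        p = op.BehaviorSimParams(weights={"light": 1.0, "heavy": 3.0})
        sessions = op.simulate_place_sessions(p, 20000, seed=7)
        assert op.preference_index(sessions, "heavy") == pytest.approx(0.5, abs=0.02)

    def test_mapping_reshuffled_each_session(self):
        sessions = op.simulate_place_sessions(op.BehaviorSimParams(), 50, seed=0)
        assert len({s.mapping for s in sessions}) > 1
        # balanced mapping: each condition on half of the 8 fields
        for s in sessions:
            assert sorted(s.mapping).count("noise") == 4
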