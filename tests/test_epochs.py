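"""Epoch extraction, contraction detection, and amplitude summaries."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import orthosync as osy
from orthosync._time import US_PER_S
from orthosync.epochs import DetectorParams, moving_rms
from tests.conftest import compact_config, compact_schedule

EMG_CHANNELS = ["emg_left_Ch1_mV", "emg_left_Ch2_mV"]


class TestExtractEpochs:
    def test_four_epochs_of_thirty_seconds(self, compact_merged, compact_sim):
        epochs = osy.extract_epochs(
            compact_merged, compact_sim.config.schedule, EMG_CHANNELS
        )
        assert [e.label for e in epochs] == [
            "SQUEEZE_1", "SQUEEZE_2", "SQUEEZE_3", "SQUEEZE_4"
        ]
        for e in epochs:
            assert e.window_s == pytest.approx(30.0, abs=0)
            for rel, vals in e.channels.values():
                assert len(vals) == 30 * 1024  # fixed-rate channel: 30,720 samples
                assert rel[0] >= -10.0 and rel[-1] <= 20.0

    def test_epoch_samples_are_untouched_source_values(self, compact_merged, compact_sim):
        epochs = osy.extract_epochs(
            compact_merged, compact_sim.config.schedule, ["emg_left_Ch1_mV"]
        )
        src, local = compact_merged._find("emg_left_Ch1_mV")
        for e in epochs:
            rel, vals = e.channels["emg_left_Ch1_mV"]
            i0 = np.searchsorted(src.time_us, e.start_us, side="left")
            assert np.array_equal(vals, src.channels[local][i0 : i0 + len(vals)])

    def test_early_termination_drops_final_epoch(self):
        cfg = compact_config(seed=21)
        sq4 = cfg.schedule.event("SQUEEZE_4")
        cfg.early_stop_s = sq4.start_s - 30.0
        res = osy.simulate_assessment(cfg)
        merged = osy.sync_full(list(res.frames.values()), event=osy.ACTIVE_STAND)
        epochs = osy.extract_epochs(merged, cfg.schedule, ["emg_left_Ch1_mV"])
        assert len(epochs) == 3
        assert [e.label for e in epochs] == ["SQUEEZE_1", "SQUEEZE_2", "SQUEEZE_3"]

    def test_unknown_channel_raises(self, compact_merged, compact_sim):
        with pytest.raises(osy.ChannelError):
            osy.extract_epochs(compact_merged, compact_sim.config.schedule, ["nope"])

    def test_long_format_export(self, compact_merged, compact_sim):
        epochs = osy.extract_epochs(
            compact_merged, compact_sim.config.schedule, ["emg_left_Ch1_mV"]
        )
        df = epochs[0].to_long_dataframe(epoch_id=1)
        assert list(df.columns) == ["epoch_id", "label", "rel_time_s", "channel", "value"]
        assert len(df) == 30 * 1024


def synthetic_emg(
    rate=1024.0,
    duration_s=200.0,
    bursts=((100.0, 10.0),),
    noise_sd=0.01,
    ratio=10.0,
    seed=7,
):
    """Noise-modulated EMG with trapezoid bursts, mirroring the simulator shape."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    env = np.ones(n)
    for start, dur in bursts:
        x = (t - start)
        inside = (x >= 0) & (x <= dur)
        shape = np.minimum(np.clip(x / 0.5, 0, 1), np.clip((dur - x) / 0.5, 0, 1))
        env[inside] = 1.0 + (ratio - 1.0) * shape[inside]
    return rng.normal(0.0, noise_sd, n) * env, t


class TestDetectContractions:
    def test_flat_noise_yields_zero_detections(self):
        values, _ = synthetic_emg(bursts=(), duration_s=300.0)
        assert osy.detect_contractions(values, 1024.0) == []

    def test_bursts_detected_within_quarter_second(self):
        truth = [(100.0, 10.0), (150.0, 10.0)]
        values, _ = synthetic_emg(bursts=truth, duration_s=200.0)
        events = osy.detect_contractions(values, 1024.0)
        assert len(events) == len(truth)
        for ev, (start, dur) in zip(events, truth):
            assert abs(ev.onset_s - start) <= 0.25
            assert abs(ev.offset_s - (start + dur)) <= 0.6

    def test_prompted_classification_against_schedule(self):
        truth = [(100.0, 10.0), (150.0, 2.0)]
        values, _ = synthetic_emg(bursts=truth, duration_s=200.0)
        events = osy.detect_contractions(
            values, 1024.0, squeeze_times_s=[(100.0, "SQUEEZE_1")]
        )
        assert [ev.prompted for ev in events] == [True, False]
        assert events[0].matched_label == "SQUEEZE_1"

    def test_onsets_monotone_in_burst_start_times(self):
        starts = [40.0, 90.0, 140.0, 170.0]
        values, _ = synthetic_emg(bursts=[(s, 5.0) for s in starts], duration_s=200.0)
        events = osy.detect_contractions(values, 1024.0, params=DetectorParams(baseline_s=30.0))
        assert len(events) == 4
        onsets = [ev.onset_s for ev in events]
        assert onsets == sorted(onsets)

    def test_noiseless_bursts_always_detected(self):
        """Deterministic carrier on a silent baseline: detection probability 1."""
        rate = 512.0
        t = np.arange(int(120 * rate)) / rate
        sig = np.zeros_like(t)
        for start in (60.0, 90.0):
            inside = (t >= start) & (t < start + 2.0)
            sig[inside] = 0.2 * np.sin(2 * np.pi * 80.0 * t[inside])
        events = osy.detect_contractions(sig, rate)
        assert len(events) == 2
        assert all(abs(ev.onset_s - s) < 0.2 for ev, s in zip(events, (60.0, 90.0)))

    def test_short_excursions_discarded_and_gaps_merged(self):
        rate = 1024.0
        t = np.arange(int(120 * rate)) / rate
        sig = np.zeros_like(t)
        sig[(t >= 70.0) & (t < 70.1)] = 1.0  # 100 ms blip: below min duration
        sig[(t >= 80.0) & (t < 81.0)] = 1.0  # split burst with a 0.1 s gap
        sig[(t >= 81.1) & (t < 82.0)] = 1.0
        events = osy.detect_contractions(sig, rate)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(80.0, abs=0.1)
        assert events[0].offset_s == pytest.approx(82.0, abs=0.1)

    def test_series_shorter_than_window_raises(self):
        with pytest.raises(osy.InputError):
            osy.detect_contractions(np.zeros(10), 1024.0)

    def test_simulator_ground_truth_recovered(self, compact_sim):
        """All true bursts (4 prompted + 2 non-prompted) within 0.25 s."""
        frame = compact_sim.frames[osy.EMG_LEFT]
        shift = compact_sim.truth.stream_shift_s[osy.EMG_LEFT]
        values = frame.channels["Ch1_mV"]
        t0 = frame.time_us[0] / US_PER_S - shift  # assessment clock
        squeezes = [
            (e.start_s, e.label) for e in compact_sim.config.schedule.squeezes
        ]
        events = osy.detect_contractions(
            values, 1024.0, t0_s=t0, squeeze_times_s=squeezes
        )
        truth = sorted(compact_sim.truth.bursts, key=lambda b: b.onset_s)
        assert len(events) == len(truth) == 6
        for ev, b in zip(events, truth):
            assert abs(ev.onset_s - b.onset_s) <= 0.25
            assert ev.prompted == b.prompted


class TestAmplitudeSummary:
    def _epoch_from_signal(self, values, rate=1024.0, contraction_s=10.0):
        n = len(values)
        rel = np.arange(n) / rate - 10.0
        return osy.Epoch(
            label="SQUEEZE_1",
            t0_us=0,
            start_us=-10 * US_PER_S,
            end_us=20 * US_PER_S,
            contraction_s=contraction_s,
            channels={"emg_left_Ch1_mV": (rel, np.asarray(values, dtype=float))},
        )

    def test_constant_amplitude_burst_has_zero_slope(self):
        rate = 1024.0
        t = np.arange(int(30 * rate)) / rate - 10.0
        sig = np.where((t >= 0) & (t < 10), np.sin(2 * np.pi * 60 * t), 0.0)
        summary = osy.epoch_amplitude_summary(self._epoch_from_signal(sig))
        assert summary.slope_mv_per_s == pytest.approx(0.0, abs=1e-6)
        assert summary.decay_fraction == pytest.approx(0.0, abs=1e-5)

    def test_linear_decay_recovered_within_ten_percent(self):
        rate = 1024.0
        rng = np.random.default_rng(5)
        t = np.arange(int(30 * rate)) / rate - 10.0
        decay = 0.5
        amp = np.where(
            (t >= 0) & (t < 10),
            1.0 - decay * np.clip((t - 0.5) / 9.0, 0.0, 1.0),
            0.0,
        )
        ramp = np.minimum(np.clip(t / 0.5, 0, 1), np.clip((10 - t) / 0.5, 0, 1))
        sig = rng.normal(0, 0.1, len(t)) * (1.0 + 99.0 * np.clip(ramp, 0, 1) * amp)
        summary = osy.epoch_amplitude_summary(self._epoch_from_signal(sig))
        assert summary.slope_mv_per_s < 0
        assert summary.decay_fraction == pytest.approx(decay, rel=0.10)

    def test_scaling_signal_scales_summary_linearly(self):
        rate = 1024.0
        rng = np.random.default_rng(6)
        t = np.arange(int(30 * rate)) / rate - 10.0
        base = rng.normal(0, 0.05, len(t)) * np.where((t >= 0) & (t < 10), 10.0, 1.0)
        s1 = osy.epoch_amplitude_summary(self._epoch_from_signal(base))
        s3 = osy.epoch_amplitude_summary(self._epoch_from_signal(3.0 * base))
        assert np.allclose(s3.per_second_mv, 3.0 * s1.per_second_mv)
        assert s3.slope_mv_per_s == pytest.approx(3.0 * s1.slope_mv_per_s)
        assert s3.decay_fraction == pytest.approx(s1.decay_fraction)

    def test_zero_signal_epoch_stays_at_noise_floor(self):
        rate = 1024.0
        rng = np.random.default_rng(8)
        sig = rng.normal(0, 0.01, int(30 * rate))
        summary = osy.epoch_amplitude_summary(self._epoch_from_signal(sig))
        assert np.all(summary.per_second_mv < 0.02)

    def test_fatigued_preset_distinguished_from_non_fatigued(self):
        """Simulator presets differ only in decay; summaries recover it."""
        results = {}
        for name, builder in (
            ("non_fatigued", osy.non_fatigued_preset),
            ("fatigued", osy.fatigued_preset),
        ):
            cfg = builder(schedule=compact_schedule(), seed=31)
            res = osy.simulate_assessment(cfg)
            merged = osy.sync_full(list(res.frames.values()), event=osy.ACTIVE_STAND)
            epochs = osy.extract_epochs(merged, cfg.schedule, ["emg_left_Ch1_mV"])
            summaries = [osy.epoch_amplitude_summary(e) for e in epochs]
            results[name] = np.mean([s.decay_fraction for s in summaries])
        assert abs(results["non_fatigued"]) < 0.05
        assert results["fatigued"] == pytest.approx(0.5, rel=0.10)

    def test_missing_channel_raises(self):
        epoch = self._epoch_from_signal(np.zeros(1024))
        with pytest.raises(osy.ChannelError):
            osy.epoch_amplitude_summary(epoch, channel="absent")


def test_moving_rms_of_constant_signal_is_its_magnitude():
    x = np.full(2048, -0.3)
    env = moving_rms(x, 1024.0)
    assert np.allclose(env, 0.3)
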