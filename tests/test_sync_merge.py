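"""Marker-based syncing and the union-of-timestamps merge."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import orthosync as osy
from orthosync._time import US_PER_S
from tests.conftest import make_fixed_rate_frame


def nova_pair(marker_s: float = 5.0, n: int = 40, seed: int = 3):
    """A NOVA_BASIC / NOVA_ADV pair on one true clock."""
    rng = np.random.default_rng(seed)
    time_us = np.cumsum(rng.integers(700_000, 1_100_000, n)).astype(np.int64)
    manifest = osy.default_manifest()
    frames = []
    for sid in (osy.NOVA_BASIC, osy.NOVA_ADV):
        channels = {nm: rng.normal(size=n) for nm in manifest.local_names(sid)}
        frames.append(
            osy.StreamFrame(sid, time_us.copy(), channels, osy.BEAT,
                            {"ACTIVE_STAND": int(marker_s * US_PER_S)})
        )
    return frames


class TestSyncInstrument:
    def test_single_frame_is_identity(self):
        frame = nova_pair()[0]
        synced, report = osy.sync_instrument([frame], "ACTIVE_STAND")
        assert report.offsets_s == {"NOVA_BASIC": 0.0}
        assert np.array_equal(synced[0].time_us, frame.time_us)

    @pytest.mark.parametrize("offset_s", [1.3, -1.3, 2.0, -2.0, 0.000001])
    def test_injected_offset_recovered_exactly(self, offset_s):
        basic, adv = nova_pair()
        adv = adv.shifted(int(round(offset_s * US_PER_S)))
        synced, report = osy.sync_instrument([basic, adv], "ACTIVE_STAND")
        assert report.offsets_s["NOVA_ADV"] == pytest.approx(-offset_s, abs=0)
        assert report.residuals_s["NOVA_ADV"] == 0.0
        assert synced[1].markers["ACTIVE_STAND"] == basic.markers["ACTIVE_STAND"]

    def test_missing_marker_names_the_frame(self):
        basic, adv = nova_pair()
        adv.markers.clear()
        with pytest.raises(osy.SyncError, match="NOVA_ADV"):
            osy.sync_instrument([basic, adv], "ACTIVE_STAND")

    def test_sync_is_idempotent(self):
        basic, adv = nova_pair()
        adv = adv.shifted(777_777)
        once, _ = osy.sync_instrument([basic, adv], "ACTIVE_STAND")
        twice, report = osy.sync_instrument(once, "ACTIVE_STAND")
        assert all(off == 0.0 for off in report.offsets_s.values())
        assert np.array_equal(once[1].time_us, twice[1].time_us)


class TestMergeStreams:
    def test_union_of_50_and_1024_hz_over_one_second(self):
        """Brute-force union oracle: {k/50} | {k/1024} over [0,1) has 1072 times."""
        a = make_fixed_rate_frame("NIRS", 50.0, 1.0, ["head_TSI"])
        b = make_fixed_rate_frame("EMG_LEFT", 1024.0, 1.0, ["Ch1_mV"])
        oracle = {round(k / 50 * 1e6) for k in range(50)} | {
            round(k / 1024 * 1e6) for k in range(1024)
        }
        assert len(oracle) == 1072
        merged = osy.merge_streams([a, b])
        assert merged.n_rows == len(oracle)
        assert set(merged.master_time_us.tolist()) == oracle

    @given(
        r1=st.integers(min_value=1, max_value=200),
        r2=st.integers(min_value=1, max_value=1200),
        duration=st.floats(min_value=0.1, max_value=3.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_union_count_matches_brute_force_for_any_rates(self, r1, r2, duration):
        a = make_fixed_rate_frame("NIRS", r1, duration, ["head_TSI"])
        b = make_fixed_rate_frame("EMG_LEFT", r2, duration, ["Ch1_mV"])
        oracle = {round(k / r1 * 1e6) for k in range(a.n_samples)} | {
            round(k / r2 * 1e6) for k in range(b.n_samples)
        }
        merged = osy.merge_streams([a, b])
        assert merged.n_rows == len(oracle)

    def test_merge_conserves_every_sample(self):
        a = make_fixed_rate_frame("NIRS", 50.0, 2.0, ["head_TSI", "leg_TSI"])
        b = make_fixed_rate_frame("EMG_LEFT", 1024.0, 2.0, ["Ch1_mV"])
        merged = osy.merge_streams([a, b])
        assert merged.n_values == 2 * a.n_samples + b.n_samples
        # placement: each channel's dense column holds its own values at its
        # own timestamps and NaN elsewhere
        col = merged.column("nirs_head_TSI")
        pos = np.searchsorted(merged.master_time_us, a.time_us)
        assert np.array_equal(col[pos], a.channels["head_TSI"])
        assert np.isnan(col).sum() == merged.n_rows - a.n_samples

    def test_self_merge_with_renamed_channels_has_no_missing_cells(self):
        a = make_fixed_rate_frame("NIRS", 50.0, 1.0, ["head_TSI"])
        b = make_fixed_rate_frame("NIRS", 50.0, 1.0, ["leg_TSI"])
        merged = osy.merge_streams([a, b])
        assert merged.n_rows == a.n_samples
        assert not merged.missing_mask("nirs_head_TSI").any()
        assert not merged.missing_mask("nirs_leg_TSI").any()

    def test_duplicate_channel_names_rejected(self):
        a = make_fixed_rate_frame("NIRS", 50.0, 1.0, ["head_TSI"])
        b = make_fixed_rate_frame("NIRS", 25.0, 1.0, ["head_TSI"])
        with pytest.raises(osy.ManifestError):
            osy.merge_streams([a, b])

    def test_merge_is_order_invariant(self):
        frames = [
            make_fixed_rate_frame("NIRS", 50.0, 1.0, ["head_TSI"]),
            make_fixed_rate_frame("EMG_LEFT", 1024.0, 1.0, ["Ch1_mV"]),
            make_fixed_rate_frame("EMG_RIGHT", 512.0, 1.0, ["Ch2_mV"]),
        ]
        m1 = osy.merge_streams(frames)
        m2 = osy.merge_streams(frames[::-1])
        assert np.array_equal(m1.master_time_us, m2.master_time_us)
        assert m1.channel_columns == m2.channel_columns
        for c in m1.channel_columns:
            assert np.array_equal(m1.column(c), m2.column(c), equal_nan=True)


class TestSyncFull:
    def _assessment(self, offsets):
        """NOVA pair + NIRS + EMG pair sharing two events, with group shifts."""
        frames = nova_pair(marker_s=5.0)
        nirs = make_fixed_rate_frame(
            "NIRS", 50.0, 40.0, ["head_TSI"], markers={"ACTIVE_STAND": 5.0, "SQUEEZE_1": 20.0}
        )
        emg_l = make_fixed_rate_frame(
            "EMG_LEFT", 1024.0, 40.0, ["Ch1_mV"], markers={"ACTIVE_STAND": 5.0, "SQUEEZE_1": 20.0}
        )
        emg_r = make_fixed_rate_frame(
            "EMG_RIGHT", 1024.0, 40.0, ["Ch2_mV"], markers={"ACTIVE_STAND": 5.0, "SQUEEZE_1": 20.0}
        )
        for f in frames:
            f.markers["SQUEEZE_1"] = int(20.0 * US_PER_S)
        out = []
        for f in frames + [nirs, emg_l, emg_r]:
            out.append(f.shifted(int(round(offsets.get(f.stream_id, 0.0) * US_PER_S))))
        return out

    def test_group_offsets_recovered_exactly(self):
        offsets = {"NIRS": -0.8, "EMG_LEFT": 1.1, "EMG_RIGHT": 1.1}
        merged = osy.sync_full(self._assessment(offsets), event="ACTIVE_STAND")
        rep = merged.alignment
        assert rep.offsets_s["NIRS"] == pytest.approx(0.8, abs=0)
        assert rep.offsets_s["EMG_LEFT"] == pytest.approx(-1.1, abs=0)
        assert rep.max_abs_residual_s == 0.0
        assert set(rep.offsets_s) == {
            "NOVA_BASIC", "NOVA_ADV", "NIRS", "EMG_LEFT", "EMG_RIGHT"
        }

    def test_zero_offsets_equal_plain_merge(self):
        frames = self._assessment({})
        merged = osy.sync_full(frames, event="ACTIVE_STAND")
        plain = osy.merge_streams(frames)
        assert np.array_equal(merged.master_time_us, plain.master_time_us)
        assert all(off == 0.0 for off in merged.alignment.offsets_s.values())

    def test_any_shared_event_gives_identical_alignment(self):
        offsets = {"NIRS": 1.25, "EMG_LEFT": -0.4, "EMG_RIGHT": 0.9, "NOVA_ADV": 2.0}
        by_as = osy.sync_full(self._assessment(offsets), event="ACTIVE_STAND")
        by_sq = osy.sync_full(self._assessment(offsets), event="SQUEEZE_1")
        assert by_as.alignment.offsets_s == by_sq.alignment.offsets_s
        assert np.array_equal(by_as.master_time_us, by_sq.master_time_us)

    def test_default_event_is_earliest_shared(self):
        merged = osy.sync_full(self._assessment({}))
        assert merged.alignment.event == "ACTIVE_STAND"

    def test_two_marker_columns_regardless_of_frame_count(self):
        merged = osy.sync_full(self._assessment({}), event="ACTIVE_STAND")
        marker_cols = [c for c in merged.data_columns if c.startswith("marker")]
        assert marker_cols == ["marker_ref", "marker_other"]


class TestSyncCrossGroup:
    def _participant(self, shift_s=0.0, seed=3):
        frames = [f.shifted(int(shift_s * US_PER_S)) for f in nova_pair(seed=seed)]
        return osy.sync_full(frames, event="ACTIVE_STAND")

    def test_event_markers_coincide_on_master_timeline(self):
        a = self._participant(0.0)
        b = self._participant(12.5, seed=4)
        merged = osy.sync_cross_group([a, b], "ACTIVE_STAND", ["p1", "p2"])
        assert merged.alignment.residuals_s == {"p1": 0.0, "p2": 0.0}
        assert merged.marker_time_us("ACTIVE_STAND") == a.marker_time_us("ACTIVE_STAND")

    def test_participant_merged_with_itself_is_pairwise_identical(self):
        a = self._participant()
        merged = osy.sync_cross_group([a, a], "ACTIVE_STAND", ["x", "y"])
        for col in a.channel_columns:
            cx = merged.column(f"{col}_x")
            cy = merged.column(f"{col}_y")
            assert np.array_equal(cx, cy, equal_nan=True)

    def test_three_way_merge_is_associative(self):
        a, b, c = (self._participant(s, seed=5 + i) for i, s in enumerate((0.0, 3.0, -2.0)))
        left = osy.sync_cross_group(
            [osy.sync_cross_group([a, b], "ACTIVE_STAND", ["pa", "pb"]), c],
            "ACTIVE_STAND",
            [None, "pc"],
        )
        right = osy.sync_cross_group(
            [a, osy.sync_cross_group([b, c], "ACTIVE_STAND", ["pb", "pc"])],
            "ACTIVE_STAND",
            ["pa", None],
        )
        assert np.array_equal(left.master_time_us, right.master_time_us)
        assert set(left.channel_columns) == set(right.channel_columns)
        for col in left.channel_columns:
            assert np.array_equal(left.column(col), right.column(col), equal_nan=True)

    def test_suffix_collision_rejected(self):
        a = self._participant()
        with pytest.raises(osy.ManifestError, match="collision"):
            osy.sync_cross_group([a, a], "ACTIVE_STAND", ["p1", "p1"])


class TestMergedFrameExport:
    def test_wide_csv_round_trip_of_values(self, tmp_path):
        frames = [
            make_fixed_rate_frame("NIRS", 50.0, 1.0, ["head_TSI"],
                                  markers={"ACTIVE_STAND": 0.5}),
            make_fixed_rate_frame("EMG_LEFT", 256.0, 1.0, ["Ch1_mV"],
                                  markers={"ACTIVE_STAND": 0.5}),
        ]
        merged = osy.sync_full(frames, event="ACTIVE_STAND")
        path = tmp_path / "merged.csv"
        merged.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        assert len(df) == merged.n_rows
        assert list(df.columns) == ["time_s"] + merged.data_columns
        col = df["nirs_head_TSI"].to_numpy()
        assert np.array_equal(col, merged.column("nirs_head_TSI"), equal_nan=True)
        assert (df["marker_ref"] == "ACTIVE_STAND").sum() == 1
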