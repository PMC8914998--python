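"""Shared fixtures: compact simulated assessments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import orthosync as osy


def compact_schedule() -> osy.ProtocolSchedule:
    """A shortened six-event schedule for fast simulations.

    Same structure as the default protocol (two rests with mid-rest squeezes,
    active stand, break, tilt, two post-stand squeezes); only phase lengths
    shrink.
    """
    return osy.build_default_schedule(
        rest1_s=130.0,
        active_stand_s=60.0,
        break_s=60.0,
        rest2_s=120.0,
        tilt_s=120.0,
        post_stand_gap_s=15.0,
        tail_s=20.0,
    )


def compact_config(seed: int = 11, **overrides) -> osy.SimConfig:
    cfg = osy.SimConfig(schedule=compact_schedule(), seed=seed, **overrides)
    return cfg


@pytest.fixture(scope="session")
def compact_sim() -> osy.SimResult:
    """One compact assessment with two non-prompted bursts during the tilt."""
    import dataclasses

    cfg = compact_config(seed=11)
    cfg.emg = dataclasses.replace(cfg.emg, n_nonprompted=2)
    return osy.simulate_assessment(cfg)


@pytest.fixture(scope="session")
def compact_merged(compact_sim) -> osy.MergedFrame:
    return osy.sync_full(list(compact_sim.frames.values()), event=osy.ACTIVE_STAND)


@pytest.fixture(scope="session")
def export_dir(tmp_path_factory, compact_sim):
    d = tmp_path_factory.mktemp("exports")
    return compact_sim.write(d)


def make_fixed_rate_frame(
    stream_id: str,
    rate_hz: float,
    duration_s: float,
    channel_names: list[str],
    markers: dict[str, float] | None = None,
    seed: int = 0,
) -> osy.StreamFrame:
    """Hand-built fixed-rate frame with samples at k/rate over [0, duration)."""
    n = int(round(duration_s * rate_hz))
    time_us = np.round(np.arange(n) * (1e6 / rate_hz)).astype(np.int64)
    rng = np.random.default_rng(seed)
    channels = {name: rng.normal(0.0, 1.0, n) for name in channel_names}
    markers_us = {k: int(round(v * 1e6)) for k, v in (markers or {}).items()}
    return osy.StreamFrame(stream_id, time_us, channels, rate_hz, markers_us)
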