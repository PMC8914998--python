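"""Synthetic orthostatic assessments with ground truth.

The simulator emits the five instrument export files of one assessment —
beat-to-beat hemodynamics (two files on slightly different clocks), 50 Hz
dual-optode NIRS, and two 1024 Hz surface-EMG loggers — together with the
ground truth needed to test the pipeline end to end: true per-stream clock
offsets, true key-press marker times, true burst timings and the programmed
within-burst amplitude decay.

Waveform shapes are deliberately minimal phenomenology, not mechanistic
cardiovascular modelling: the active stand produces a transient systolic and
diastolic pressure drop with exponential recovery and a baseline overshoot,
an immediate heart-rate rise peaking within ~20 s, and step-like tissue
oxygenation reductions; the tilt produces a gradual sustained heart-rate
rise; prompted squeezes are trapezoid-enveloped Gaussian EMG bursts with an
optional linear within-burst amplitude decay (the "fatigued" preset) and
small transient dips in thigh oxygenation.

Logistics are simulated too: independent per-stream clock offsets of up to
+/-2 s, per-stream per-event key-press jitter, a ~3 min pause of the
beat-to-beat recording between stand and tilt, missing finger-pressure
samples during cuff-calibration windows, and optional independent packet
drop.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._time import US_PER_S, to_us
from .errors import ConfigError
from .io_formats import (
    BEAT,
    EMG_RATE_HZ,
    NIRS_RATE_HZ,
    StreamFrame,
    write_stream,
)
from .manifest import EMG_LEFT, EMG_RIGHT, NIRS, NOVA_ADV, NOVA_BASIC, STREAMS
from .protocol import ACTIVE_STAND, HEAD_UP_TILT, ProtocolSchedule, build_default_schedule


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class HemoParams:
    """Baselines and orthostatic-response magnitudes for the hemodynamics."""

    sbp_mmHg: float = 120.0
    dbp_mmHg: float = 70.0
    hr_bpm: float = 70.0
    co_lmin: float = 5.0
    bsa_m2: float = 1.8
    # active-stand response
    stand_sbp_drop_mmHg: float = 30.0
    stand_dbp_drop_mmHg: float = 15.0
    nadir_s: float = 10.0
    recovery_tau_s: float = 8.0
    overshoot_frac: float = 0.10
    overshoot_tau_s: float = 60.0
    hr_rise_bpm: float = 30.0
    hr_time_to_peak_s: float = 20.0
    hr_sustained_bpm: float = 15.0
    # head-up-tilt response
    tilt_hr_rise_bpm: float = 20.0
    tilt_tau_s: float = 120.0
    tilt_dbp_rise_mmHg: float = 5.0
    # squeeze coupling (skeletal muscle pump)
    squeeze_sbp_bump_mmHg: float = 4.0
    squeeze_co_bump_lmin: float = 0.4
    # noise
    bp_noise_sd_mmHg: float = 2.0
    co_noise_sd_lmin: float = 0.15
    ibi_jitter_frac: float = 0.02


@dataclass
class NirsParams:
    """Tissue-oxygenation baselines and responses for the two optodes."""

    head_tsi_pct: float = 70.0
    leg_tsi_pct: float = 68.0
    # post-stand reductions; magnitudes are order-of-magnitude choices, no
    # quantitative values are established for this protocol
    head_drop_pct: float = 5.0
    leg_drop_pct: float = 3.0
    head_drop_tau_s: float = 2.0  # sudden
    leg_drop_tau_s: float = 30.0  # gradual
    squeeze_dip_pct: float = 2.0
    thb_umol: float = 60.0
    noise_sd_pct: float = 0.4
    tsiq_pct: float = 95.0


@dataclass
class EmgParams:
    """Surface-EMG noise floor, burst shape and within-burst decay."""

    noise_sd_mv: float = 0.01
    burst_ratio: float = 10.0  # burst envelope SD relative to baseline SD
    burst_decay_frac: float = 0.0  # linear amplitude loss across the 10 s burst
    rise_s: float = 0.5
    ch2_scale: float = 0.8
    n_nonprompted: int = 0
    nonprompted_ratio: float = 6.0
    nonprompted_duration_s: tuple[float, float] = (1.0, 3.0)


@dataclass
class LogisticsParams:
    """Clocks, key presses, pauses and packet loss."""

    offset_range_s: float = 2.0  # per-stream clock offset ~ U(-range, +range)
    start_pad_s: float = 2.5  # recordings start this long before assessment t=0
    jitter_sd_s: float = 0.15  # key-press reaction jitter per stream per event
    jitter_max_s: float = 0.5
    nova_pause: bool = True  # pause beat-to-beat recording during the break
    pause_margin_s: float = 5.0
    physiocal_gaps: bool = True
    physiocal_windows_s: tuple[tuple[float, float], ...] = ((60.0, 90.0), (150.0, 180.0))
    packet_drop_p: float = 0.0


@dataclass
class SimConfig:
    """Every knob of one simulated assessment; the seed fixes all draws."""

    schedule: ProtocolSchedule = field(default_factory=build_default_schedule)
    nirs_rate_hz: float = NIRS_RATE_HZ
    emg_rate_hz: float = EMG_RATE_HZ
    hemo: HemoParams = field(default_factory=HemoParams)
    nirs: NirsParams = field(default_factory=NirsParams)
    emg: EmgParams = field(default_factory=EmgParams)
    logistics: LogisticsParams = field(default_factory=LogisticsParams)
    streams: tuple[str, ...] = STREAMS
    early_stop_s: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.nirs_rate_hz <= 0 or self.emg_rate_hz <= 0:
            raise ConfigError("sampling rates must be positive")
        if not 0.0 <= self.logistics.packet_drop_p < 1.0:
            raise ConfigError(
                f"packet_drop_p must be in [0, 1), got {self.logistics.packet_drop_p}"
            )
        if self.logistics.offset_range_s < 0 or self.logistics.jitter_sd_s < 0:
            raise ConfigError("offset range and jitter SD must be >= 0")
        if self.emg.burst_ratio < 1:
            raise ConfigError("burst_ratio must be >= 1")
        if not 0.0 <= self.emg.burst_decay_frac <= 1.0:
            raise ConfigError("burst_decay_frac must be in [0, 1]")
        unknown = set(self.streams) - set(STREAMS)
        if unknown:
            raise ConfigError(f"unknown streams: {sorted(unknown)}")
        total = self.schedule.total_duration_s
        for t0, t1 in self.logistics.physiocal_windows_s:
            if not 0 <= t0 < t1 <= total:
                raise ConfigError(f"physiocal window ({t0}, {t1}) outside recording")
        if self.early_stop_s is not None and self.early_stop_s <= 0:
            raise ConfigError("early_stop_s must be positive")

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic amplitude set to zero (offsets kept)."""
        c = dataclasses.replace(
            self,
            hemo=dataclasses.replace(
                self.hemo, bp_noise_sd_mmHg=0.0, co_noise_sd_lmin=0.0, ibi_jitter_frac=0.0
            ),
            nirs=dataclasses.replace(self.nirs, noise_sd_pct=0.0),
            emg=dataclasses.replace(self.emg, noise_sd_mv=0.0),
            logistics=dataclasses.replace(self.logistics, jitter_sd_s=0.0),
        )
        return c


def non_fatigued_preset(**overrides) -> SimConfig:
    """Participant without within-burst amplitude decay."""
    cfg = SimConfig(**overrides)
    cfg.emg = dataclasses.replace(cfg.emg, burst_decay_frac=0.0)
    return cfg


def fatigued_preset(**overrides) -> SimConfig:
    """Identical to :func:`non_fatigued_preset` except 50% within-burst decay."""
    cfg = SimConfig(**overrides)
    cfg.emg = dataclasses.replace(cfg.emg, burst_decay_frac=0.5)
    return cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class BurstTruth:
    onset_s: float
    offset_s: float
    amplitude_ratio: float
    decay_frac: float
    prompted: bool
    label: str | None = None


@dataclass
class GroundTruth:
    """What the emitted files actually contain, by construction."""

    stream_shift_s: dict[str, float]  # local clock = assessment clock + shift
    marker_times_s: dict[str, dict[str, float]]  # per-stream local press times
    event_times_s: dict[str, float]  # true event starts on the assessment clock
    bursts: list[BurstTruth]
    n_beats: int
    hemo: dict

    def relative_offset_s(self, stream: str, reference: str = NOVA_BASIC) -> float:
        """Shift a synced pipeline should apply to ``stream`` (vs reference)."""
        return self.stream_shift_s[reference] - self.stream_shift_s[stream]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=float))


# ---------------------------------------------------------------------------
# waveforms (assessment-clock truth functions)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Waveforms:
    """Deterministic physiological truth as vectorized functions of time.

    Shared by the sample generator and by tests that integrate or probe the
    truth directly (e.g. beat-count consistency).
    """

    def __init__(self, config: SimConfig):
        self.cfg = config
        sched = config.schedule
        self.t_as = sched.event(ACTIVE_STAND).start_s
        self.as_end = sched.event(ACTIVE_STAND).end_s
        self.t_tilt = sched.event(HEAD_UP_TILT).start_s
        self.tilt_end = sched.event(HEAD_UP_TILT).end_s
        self.squeezes = [(e.start_s, e.duration_s, e.label) for e in sched.squeezes]

    # heart rate -----------------------------------------------------------
    def hr(self, t):
        t = np.asarray(t, dtype=float)
        p = self.cfg.hemo
        tau = t - self.t_as
        rise = _sigmoid((tau - p.hr_time_to_peak_s * 0.4) / (p.hr_time_to_peak_s * 0.1))
        persist = np.exp(-np.maximum(0.0, tau - p.hr_time_to_peak_s * 0.9) / 90.0)
        stand = rise * (p.hr_sustained_bpm + (p.hr_rise_bpm - p.hr_sustained_bpm) * persist)
        stand = stand * np.exp(-np.maximum(0.0, t - self.as_end) / 30.0)
        tau2 = t - self.t_tilt
        tilt = p.tilt_hr_rise_bpm * (1.0 - np.exp(-np.maximum(0.0, tau2) / p.tilt_tau_s))
        tilt = tilt * (tau2 > 0) * np.exp(-np.maximum(0.0, t - self.tilt_end) / 60.0)
        return p.hr_bpm + stand + tilt + 3.0 * self._squeeze_gate(t)

    def _squeeze_gate(self, t):
        t = np.asarray(t, dtype=float)
        g = np.zeros_like(t)
        for start, dur, _ in self.squeezes:
            g += ((t >= start) & (t < start + dur)).astype(float)
        return g

    def _stand_bp_response(self, t, drop):
        """Drop to a nadir, exponential recovery, overshoot above baseline."""
        p = self.cfg.hemo
        tau = np.asarray(t, dtype=float) - self.t_as
        falling = np.clip(tau / p.nadir_s, 0.0, 1.0)
        resp = -drop * falling
        rec = np.maximum(0.0, tau - p.nadir_s)
        recovered = np.where(
            tau > p.nadir_s,
            -drop * np.exp(-rec / p.recovery_tau_s)
            + p.overshoot_frac
            * drop
            * (1.0 - np.exp(-rec / p.recovery_tau_s))
            * np.exp(-rec / p.overshoot_tau_s),
            resp,
        )
        out = np.where(tau > p.nadir_s, recovered, resp)
        return out * np.exp(-np.maximum(0.0, t - self.as_end) / 20.0)

    def sbp(self, t):
        p = self.cfg.hemo
        t = np.asarray(t, dtype=float)
        tilt_var = 3.0 * np.sin(2 * np.pi * (t - self.t_tilt) / 25.0)
        tilt_var = tilt_var * ((t > self.t_tilt) & (t < self.tilt_end))
        return (
            p.sbp_mmHg
            + self._stand_bp_response(t, p.stand_sbp_drop_mmHg)
            + tilt_var
            + p.squeeze_sbp_bump_mmHg * self._squeeze_gate(t)
        )

    def dbp(self, t):
        p = self.cfg.hemo
        t = np.asarray(t, dtype=float)
        tau2 = np.maximum(0.0, t - self.t_tilt)
        tilt = p.tilt_dbp_rise_mmHg * (1.0 - np.exp(-tau2 / 60.0))
        tilt = tilt * (t > self.t_tilt) * np.exp(-np.maximum(0.0, t - self.tilt_end) / 60.0)
        return (
            p.dbp_mmHg
            + self._stand_bp_response(t, p.stand_dbp_drop_mmHg)
            + tilt
            + 0.5 * p.squeeze_sbp_bump_mmHg * self._squeeze_gate(t)
        )

    def co(self, t):
        """Cardiac output: opposite transient to the pressure drop."""
        p = self.cfg.hemo
        resp = self._stand_bp_response(np.asarray(t, dtype=float), p.stand_sbp_drop_mmHg)
        return (
            p.co_lmin
            - 0.03 * resp
            + p.squeeze_co_bump_lmin * self._squeeze_gate(t)
        )

    # NIRS -----------------------------------------------------------------
    def _orthostatic_drop(self, t, drop, tau):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for start, end in ((self.t_as, self.as_end), (self.t_tilt, self.tilt_end)):
            x = np.maximum(0.0, t - start)
            d = drop * (1.0 - np.exp(-x / tau)) * (t > start)
            d = d * np.exp(-np.maximum(0.0, t - end) / 30.0)
            out += d
        return out

    def tsi_head(self, t):
        p = self.cfg.nirs
        return p.head_tsi_pct - self._orthostatic_drop(t, p.head_drop_pct, p.head_drop_tau_s)

    def tsi_leg(self, t):
        p = self.cfg.nirs
        return (
            p.leg_tsi_pct
            - self._orthostatic_drop(t, p.leg_drop_pct, p.leg_drop_tau_s)
            - p.squeeze_dip_pct * self._squeeze_gate(t)
        )

    # beats ----------------------------------------------------------------
    def beat_times(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Systolic upstroke times over the whole recording.

        Midpoint stepping of dt = 60/HR keeps the cumulative beat count
        within a couple of beats of the integral of HR.
        """
        p = self.cfg.hemo
        total = self.cfg.schedule.total_duration_s
        times = []
        t = 0.0
        while t < total:
            h = float(self.hr(t))
            dt = 60.0 / float(self.hr(t + 30.0 / h))
            if rng is not None and p.ibi_jitter_frac > 0:
                dt *= max(0.2, 1.0 + p.ibi_jitter_frac * rng.standard_normal())
            t += dt
            if t < total:
                times.append(t)
        return np.array(times)


# ---------------------------------------------------------------------------
# assessment synthesis
# ---------------------------------------------------------------------------

class SimResult:
    """Frames plus ground truth; :meth:`write` emits the five export files."""

    def __init__(self, frames: dict[str, StreamFrame], truth: GroundTruth, config: SimConfig):
        self.frames = frames
        self.truth = truth
        self.config = config

    _FILENAMES = {
        NOVA_BASIC: "nova_basic.csv",
        NOVA_ADV: "nova_advanced.csv",
        NIRS: "nirs.csv",
        EMG_LEFT: "emg_left.csv",
        EMG_RIGHT: "emg_right.csv",
    }

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths: dict[str, str] = {}
        for stream, frame in self.frames.items():
            paths[stream] = write_stream(frame, os.path.join(out_dir, self._FILENAMES[stream]))
        truth_path = os.path.join(out_dir, "truth.json")
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1)
        paths["truth"] = truth_path
        return paths


def _truncated_normal(rng, sd, bound):
    if sd == 0:
        return 0.0
    x = rng.normal(0.0, sd)
    while abs(x) > bound:
        x = rng.normal(0.0, sd)
    return x


def simulate_assessment(config: SimConfig | None = None) -> SimResult:
    """Generate one full synthetic assessment.

    Returns the five stream frames (already carrying their clock offsets and
    jittered key-press markers) and the ground truth. The same seed yields
    byte-identical exports; different seeds differ in every stochastic
    component. The configuration is validated before any work is done.
    """
    config = config or SimConfig()
    config.validate()
    log = config.logistics
    sched = config.schedule
    total = sched.total_duration_s
    wf = Waveforms(config)

    root = np.random.SeedSequence(config.seed)
    keys = (
        "offsets",
        "jitter",
        "beats",
        "nova",
        "nirs",
        "emg_left",
        "emg_right",
        "nonprompted",
        "drop_left",
        "drop_right",
    )
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}

    # per-stream clock shifts: local clock = assessment clock + shift
    shifts: dict[str, float] = {}
    for stream in STREAMS:
        delta = rngs["offsets"].uniform(-log.offset_range_s, log.offset_range_s)
        shifts[stream] = log.start_pad_s + delta

    # per-stream, per-event key presses
    event_truth = {e.label: e.start_s for e in sched.events}
    marker_truth: dict[str, dict[str, float]] = {s: {} for s in STREAMS}
    markers_us: dict[str, dict[str, int]] = {s: {} for s in STREAMS}
    for e in sched.events:
        for stream in STREAMS:
            jit = _truncated_normal(rngs["jitter"], log.jitter_sd_s, log.jitter_max_s)
            t_local = e.start_s + shifts[stream] + jit
            marker_truth[stream][e.label] = t_local
            markers_us[stream][e.label] = int(to_us(t_local))

    # non-prompted bursts during the tilt (truth shared by both legs)
    bursts: list[BurstTruth] = [
        BurstTruth(s, s + d, config.emg.burst_ratio, config.emg.burst_decay_frac, True, lbl)
        for s, d, lbl in wf.squeezes
    ]
    tilt = sched.event(HEAD_UP_TILT)
    placed: list[tuple[float, float]] = []
    for _ in range(config.emg.n_nonprompted):
        lo, hi = config.emg.nonprompted_duration_s
        for _attempt in range(100):
            start = rngs["nonprompted"].uniform(tilt.start_s + 30.0, tilt.end_s - 30.0)
            dur = rngs["nonprompted"].uniform(lo, hi)
            clear_of_squeezes = all(abs(start - s) > 15.0 for s, _, _ in wf.squeezes)
            clear_of_others = all(
                start + dur + 5.0 < a or start > a + d + 5.0 for a, d in placed
            )
            if clear_of_squeezes and clear_of_others:
                break
        placed.append((start, dur))
        bursts.append(
            BurstTruth(start, start + dur, config.emg.nonprompted_ratio, 0.0, False)
        )

    beats = wf.beat_times(rngs["beats"])
    frames: dict[str, StreamFrame] = {}
    if NOVA_BASIC in config.streams:
        frames[NOVA_BASIC] = _nova_basic_frame(config, wf, beats, shifts[NOVA_BASIC],
                                               markers_us[NOVA_BASIC], rngs["nova"])
    if NOVA_ADV in config.streams:
        frames[NOVA_ADV] = _nova_adv_frame(config, wf, beats, shifts[NOVA_ADV],
                                           markers_us[NOVA_ADV], rngs["nova"])
    if NIRS in config.streams:
        frames[NIRS] = _nirs_frame(config, wf, shifts[NIRS], markers_us[NIRS], rngs["nirs"])
    for stream, rng_key, drop_key in (
        (EMG_LEFT, "emg_left", "drop_left"),
        (EMG_RIGHT, "emg_right", "drop_right"),
    ):
        if stream in config.streams:
            frame = _emg_frame(config, wf, bursts, shifts[stream], markers_us[stream],
                               rngs[rng_key], stream)
            if log.packet_drop_p > 0:
                frame, _ = apply_packet_drop(
                    frame, log.packet_drop_p,
                    int(rngs[drop_key].integers(0, 2**31 - 1)),
                )
            frames[stream] = frame

    if config.early_stop_s is not None:
        for stream, frame in frames.items():
            frames[stream] = _truncate(frame, config.early_stop_s + shifts[stream])

    truth = GroundTruth(
        stream_shift_s=shifts,
        marker_times_s=marker_truth,
        event_times_s=event_truth,
        bursts=bursts,
        n_beats=len(beats),
        hemo=dataclasses.asdict(config.hemo),
    )
    return SimResult(frames, truth, config)


def _truncate(frame: StreamFrame, local_cutoff_s: float) -> StreamFrame:
    cutoff = int(to_us(local_cutoff_s))
    keep = frame.time_us <= cutoff
    return StreamFrame(
        stream_id=frame.stream_id,
        time_us=frame.time_us[keep],
        channels={k: v[keep] for k, v in frame.channels.items()},
        nominal_rate_hz=frame.nominal_rate_hz,
        markers={k: v for k, v in frame.markers.items() if v <= cutoff},
    )


def _round6(x: np.ndarray) -> np.ndarray:
    # emulate export precision; keeps CSVs compact and round trips exact
    return np.round(x, 6)


def _nova_mask(config: SimConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rows to keep, rows inside calibration windows) on the assessment clock."""
    log = config.logistics
    keep = np.ones(len(t), dtype=bool)
    if log.nova_pause:
        brk = config.schedule.phases.get("break")
        if brk:
            keep &= ~((t > brk[0] + log.pause_margin_s) & (t < brk[1] - log.pause_margin_s))
    calib = np.zeros(len(t), dtype=bool)
    if log.physiocal_gaps:
        for a, b in log.physiocal_windows_s:
            calib |= (t >= a) & (t < b)
    return keep, calib


def _nova_basic_frame(config, wf, beats, shift, markers, rng) -> StreamFrame:
    keep, calib = _nova_mask(config, beats)
    t = beats[keep]
    calib = calib[keep]
    p = config.hemo
    ibi = np.diff(np.concatenate([[0.0], beats]))[keep]
    noise = lambda sd: rng.normal(0.0, sd, len(t)) if sd > 0 else 0.0

    sbp = wf.sbp(t) + noise(p.bp_noise_sd_mmHg)
    dbp = wf.dbp(t) + noise(p.bp_noise_sd_mmHg * 0.7)
    chans = {
        "SBP_mmHg": sbp,
        "DBP_mmHg": dbp,
        "MAP_mmHg": (sbp + 2.0 * dbp) / 3.0,
        "HR_bpm": 60.0 / ibi,
        "IBI_s": ibi,
        "fingerP_mmHg": sbp - 5.0 + noise(1.0),
        "reBAP_mmHg": sbp - 3.0 + noise(1.0),
        "heightcorr_mmHg": noise(0.5) + np.zeros(len(t)),
        "physiocal_on": calib.astype(float),
    }
    for name in ("SBP_mmHg", "DBP_mmHg", "MAP_mmHg", "fingerP_mmHg", "reBAP_mmHg"):
        chans[name] = np.where(calib, np.nan, chans[name])
    chans = {k: _round6(np.asarray(v, dtype=float)) for k, v in chans.items()}
    return StreamFrame(NOVA_BASIC, to_us(t + shift), chans, BEAT, markers)


def _nova_adv_frame(config, wf, beats, shift, markers, rng) -> StreamFrame:
    keep, _ = _nova_mask(config, beats)
    t = beats[keep]
    p = config.hemo
    ibi = np.diff(np.concatenate([[0.0], beats]))[keep]
    hr = 60.0 / ibi
    noise = lambda sd: rng.normal(0.0, sd, len(t)) if sd > 0 else 0.0

    co = wf.co(t) + noise(p.co_noise_sd_lmin)
    sv = co / hr * 1000.0
    map_ = (wf.sbp(t) + 2.0 * wf.dbp(t)) / 3.0
    pp = wf.sbp(t) - wf.dbp(t)
    lvet = 300.0 - 0.8 * (hr - p.hr_bpm)
    chans = {
        "CO_lmin": co,
        "CI_lminm2": co / p.bsa_m2,
        "SV_ml": sv,
        "SVI_mlm2": sv / p.bsa_m2,
        "TPR_mmHgsl": map_ / co * 60.0,
        "TPRI_mmHgslm2": map_ / co * 60.0 * p.bsa_m2,
        "LVET_ms": lvet,
        "PP_mmHg": pp,
        "dPdt_mmHgs": pp / 0.08 + noise(20.0),
        "ZAo_mmHgsml": 0.065 + noise(0.003) + np.zeros(len(t)),
        "Cwk_mlmmHg": 1.4 + noise(0.05) + np.zeros(len(t)),
        "BRS_msmmHg": 15.0 + noise(1.0) + np.zeros(len(t)),
        "AoFlow_mls": sv / (lvet / 1000.0),
    }
    chans = {k: _round6(np.asarray(v, dtype=float)) for k, v in chans.items()}
    return StreamFrame(NOVA_ADV, to_us(t + shift), chans, BEAT, markers)


def _nirs_frame(config, wf, shift, markers, rng) -> StreamFrame:
    rate = config.nirs_rate_hz
    total = config.schedule.total_duration_s
    n = int(np.floor((total + shift) * rate)) + 1
    t_local = np.arange(n) / rate
    t = t_local - shift
    p = config.nirs
    noise = lambda sd, m=1.0: rng.normal(0.0, sd * m, n) if sd > 0 else 0.0

    chans: dict[str, np.ndarray] = {}
    for dev, tsi_fn in (("head", wf.tsi_head), ("leg", wf.tsi_leg)):
        tsi = tsi_fn(np.maximum(t, 0.0))
        for scale, d in zip((0.9, 1.0, 1.1), ("d1", "d2", "d3")):
            thb = p.thb_umol * scale
            o2hb = tsi / 100.0 * thb + noise(p.noise_sd_pct, scale)
            chans[f"{dev}_{d}_O2Hb"] = o2hb
            chans[f"{dev}_{d}_HHb"] = thb - o2hb
            chans[f"{dev}_{d}_tHb"] = np.full(n, thb)
        chans[f"{dev}_TSI"] = tsi + noise(p.noise_sd_pct)
        chans[f"{dev}_TSIq"] = np.clip(p.tsiq_pct + noise(1.0) + np.zeros(n), 0, 100)
    chans = {k: _round6(np.asarray(v, dtype=float)) for k, v in chans.items()}
    period_us = US_PER_S / rate
    return StreamFrame(NIRS, np.round(np.arange(n) * period_us).astype(np.int64),
                       chans, rate, markers)


def _burst_envelope(t: np.ndarray, bursts: list[BurstTruth], rise_s: float) -> np.ndarray:
    """Multiplicative SD envelope: 1 at rest, `ratio` (decaying) inside bursts."""
    env = np.ones_like(t)
    for b in bursts:
        dur = b.offset_s - b.onset_s
        tau = t - b.onset_s
        inside = (tau >= 0) & (tau <= dur)
        if not inside.any():
            continue
        x = tau[inside]
        ramp_up = np.clip(x / rise_s, 0.0, 1.0)
        ramp_down = np.clip((dur - x) / rise_s, 0.0, 1.0)
        plateau_span = max(dur - 2.0 * rise_s, 1e-9)
        decay = 1.0 - b.decay_frac * np.clip((x - rise_s) / plateau_span, 0.0, 1.0)
        shape = np.minimum(ramp_up, ramp_down) * decay
        # burst SD = ratio * shape, floored at the resting noise level, so the
        # plateau envelope is exactly proportional to the programmed decay
        env[inside] = np.maximum(env[inside], np.maximum(1.0, b.amplitude_ratio * shape))
    return env


def _emg_frame(config, wf, bursts, shift, markers, rng, stream_id) -> StreamFrame:
    rate = config.emg_rate_hz
    total = config.schedule.total_duration_s
    n = int(np.floor((total + shift) * rate)) + 1
    period_us = US_PER_S / rate
    time_us = np.round(np.arange(n) * period_us).astype(np.int64)
    t = np.arange(n) / rate - shift
    p = config.emg

    env = _burst_envelope(t, bursts, p.rise_s)
    ch1 = rng.normal(0.0, 1.0, n) * p.noise_sd_mv * env
    ch2 = rng.normal(0.0, 1.0, n) * p.noise_sd_mv * p.ch2_scale * env

    sched = config.schedule
    upright = np.zeros(n)
    for ph in ("active_stand", "tilt"):
        a, b = sched.phases[ph]
        upright += np.clip((t - a) / 10.0, 0.0, 1.0) * np.clip((b + 20.0 - t) / 20.0, 0.0, 1.0)
    upright = np.clip(upright, 0.0, 1.0)
    tilt_angle = np.sin(np.deg2rad(70.0))

    noise = lambda sd: rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    chans = {
        "Ch1_mV": ch1,
        "Ch2_mV": ch2,
        "accX_g": tilt_angle * upright + noise(0.02),
        "accY_g": noise(0.02),
        "accZ_g": 1.0 - (1.0 - np.cos(np.deg2rad(70.0))) * upright + noise(0.02),
        "gyroX_dps": noise(1.0) + 40.0 * np.abs(np.gradient(upright)) * rate / 10.0,
        "gyroY_dps": noise(1.0),
        "gyroZ_dps": noise(1.0),
        "magX_gauss": 0.4 + noise(0.01),
        "magY_gauss": -0.1 + noise(0.01),
        "magZ_gauss": 0.25 + noise(0.01),
        "battery_V": 4.15 - 1e-5 * np.arange(n) / rate + noise(0.002),
    }
    chans = {k: _round6(np.asarray(v, dtype=float)) for k, v in chans.items()}
    return StreamFrame(stream_id, time_us, chans, rate, markers)


# ---------------------------------------------------------------------------
# packet drop
# ---------------------------------------------------------------------------

@dataclass
class PacketDropReport:
    n_input: int
    n_surviving: int

    @property
    def surviving_fraction(self) -> float:
        return self.n_surviving / self.n_input if self.n_input else 1.0


def apply_packet_drop(series, drop_probability: float, seed: int):
    """Remove samples independently with the given probability.

    ``series`` may be a 1-D array (entries dropped) or a :class:`StreamFrame`
    (rows dropped across all channels; markers kept). Returns
    ``(series, PacketDropReport)``; the removal set is fully determined by
    ``seed``.
    """
    if not 0.0 <= drop_probability < 1.0:
        raise ConfigError(f"drop probability must be in [0, 1), got {drop_probability}")
    if isinstance(series, StreamFrame):
        n = series.n_samples
        keep = np.random.default_rng(seed).random(n) >= drop_probability
        out = StreamFrame(
            stream_id=series.stream_id,
            time_us=series.time_us[keep],
            channels={k: v[keep] for k, v in series.channels.items()},
            nominal_rate_hz=series.nominal_rate_hz,
            markers=dict(series.markers),
        )
        return out, PacketDropReport(n, int(keep.sum()))
    arr = np.asarray(series)
    keep = np.random.default_rng(seed).random(len(arr)) >= drop_probability
    return arr[keep], PacketDropReport(len(arr), int(keep.sum()))
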