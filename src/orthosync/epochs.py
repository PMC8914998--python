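"""Peri-contraction epochs and amplitude-based contraction detection.

Each prompted 10 s thigh squeeze is studied through a 30 s epoch: 10 s before
the prompt, the 10 s contraction, and 10 s after. Epochs are raw slices — no
filtering or normalization is applied to the stored samples; the rectified
moving-RMS envelope exists only inside the detector and the amplitude
summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._time import US_PER_S
from .errors import ChannelError, ConfigError, InputError
from .io_formats import BEAT
from .protocol import ProtocolSchedule

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    """A 30 s window around one prompted contraction.

    ``channels`` maps merged column name to ``(rel_time_s, values)`` where the
    relative axis has 0 at the contraction prompt. Values are unmodified
    copies of the source samples.
    """

    label: str
    t0_us: int  # prompt time on the master timeline
    start_us: int
    end_us: int
    contraction_s: float
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def window_s(self) -> float:
        return (self.end_us - self.start_us) / US_PER_S

    def to_long_dataframe(self, epoch_id: int = 0):
        """Long-format export: epoch_id,label,rel_time_s,channel,value."""
        import pandas as pd

        parts = []
        for name, (rel, vals) in self.channels.items():
            parts.append(
                pd.DataFrame(
                    {
                        "epoch_id": epoch_id,
                        "label": self.label,
                        "rel_time_s": rel,
                        "channel": name,
                        "value": vals,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


@dataclass
class ContractionEvent:
    """A detected burst of muscle activity."""

    onset_s: float
    offset_s: float
    peak_amplitude_mv: float
    prompted: bool = False
    matched_label: str | None = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class DetectorParams:
    """Envelope/threshold settings for amplitude-based burst detection.

    The envelope is a moving RMS of the full-wave rectified signal over
    ``env_window_s``. The threshold is baseline median + ``threshold_mads`` x
    MAD, with the baseline taken from the first ``baseline_s`` of the series
    (supine rest). Excursions shorter than ``min_duration_s`` are discarded
    after gaps shorter than ``merge_gap_s`` are bridged.
    """

    env_window_s: float = 0.1
    threshold_mads: float = 5.0
    baseline_s: float = 60.0
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.25
    prompt_tolerance_s: float = 5.0

    def validate(self) -> None:
        for name in ("env_window_s", "threshold_mads", "baseline_s", "min_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.merge_gap_s < 0 or self.prompt_tolerance_s < 0:
            raise ConfigError("merge_gap_s and prompt_tolerance_s must be >= 0")


def moving_rms(values: np.ndarray, rate_hz: float, window_s: float = 0.1) -> np.ndarray:
    """Centered moving-RMS envelope of a full-wave rectified signal."""
    win = max(int(round(window_s * rate_hz)), 1)
    if len(values) < win:
        raise InputError(
            f"series of {len(values)} samples is shorter than the "
            f"{window_s} s envelope window"
        )
    x = np.abs(np.asarray(values, dtype=float))
    return np.sqrt(uniform_filter1d(x * x, size=win, mode="nearest"))


def extract_epochs(
    frame,
    schedule: ProtocolSchedule,
    channels: list[str],
    pre_s: float = 10.0,
    post_s: float = 10.0,
    align: str = "prompt",
) -> list[Epoch]:
    """Extract one raw epoch per scheduled squeeze.

    The prompt anchor for each squeeze is its event marker on the master
    timeline (``align="onset"`` instead re-anchors on the detected burst onset
    near the prompt). Squeezes whose marker is absent or whose window is not
    fully covered by every requested channel (e.g. after early termination of
    the tilt) are skipped with a logged notice.

    For fixed-rate channels the epoch holds exactly ``round(window * rate)``
    consecutive samples starting at the first sample in the window, so the
    per-epoch sample count does not depend on the sub-sample phase of the
    jittered prompt marker.
    """
    for c in channels:
        frame._find(c)  # raises ChannelError early

    epochs: list[Epoch] = []
    for event in schedule.squeezes:
        try:
            t0 = frame.marker_time_us(event.label)
        except Exception:
            logger.info("skipping %s: no marker on the master timeline", event.label)
            continue
        if align == "onset":
            t0 = _refine_onset(frame, channels[0], t0, event.duration_s)
        start = t0 - int(round(pre_s * US_PER_S))
        end = t0 + int(round((event.duration_s + post_s) * US_PER_S))

        epoch = Epoch(
            label=event.label,
            t0_us=int(t0),
            start_us=int(start),
            end_us=int(end),
            contraction_s=event.duration_s,
        )
        ok = True
        for c in channels:
            src, local = frame._find(c)
            t = src.time_us
            if not (len(t) and t[0] <= start and t[-1] >= end - _period_us(src)):
                logger.info(
                    "skipping %s: window not covered by %s", event.label, c
                )
                ok = False
                break
            i0 = int(np.searchsorted(t, start, side="left"))
            if src.nominal_rate_hz != BEAT:
                n = int(round((pre_s + event.duration_s + post_s) * float(src.nominal_rate_hz)))
                i1 = i0 + n
                if i1 > len(t) or t[i1 - 1] >= end + _period_us(src):
                    logger.info("skipping %s: gap inside window of %s", event.label, c)
                    ok = False
                    break
            else:
                i1 = int(np.searchsorted(t, end, side="left"))
            rel = (t[i0:i1] - t0) / US_PER_S
            epoch.channels[c] = (rel, src.channels[local][i0:i1].copy())
        if ok:
            epochs.append(epoch)
    return epochs


def _period_us(src) -> int:
    if src.nominal_rate_hz == BEAT:
        return int(2 * US_PER_S)  # allow one slow beat of slack at the edges
    return int(np.ceil(US_PER_S / float(src.nominal_rate_hz)))


def _refine_onset(frame, channel: str, t0_us: int, duration_s: float) -> int:
    """Move the anchor to the detected envelope onset near the prompt."""
    src, local = frame._find(channel)
    if src.nominal_rate_hz == BEAT:
        return t0_us
    rate = float(src.nominal_rate_hz)
    t = src.time_us
    lo = int(np.searchsorted(t, t0_us - 5 * US_PER_S))
    hi = int(np.searchsorted(t, t0_us + int(duration_s * US_PER_S)))
    if hi - lo < rate:
        return t0_us
    seg = src.channels[local][lo:hi]
    env = moving_rms(seg, rate)
    thr = np.median(env[: int(rate)]) + 5 * _mad(env[: int(rate)])
    above = np.nonzero(env > thr)[0]
    if len(above) == 0:
        return t0_us
    return int(t[lo + above[0]])


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_contractions(
    values: np.ndarray,
    rate_hz: float,
    t0_s: float = 0.0,
    params: DetectorParams | None = None,
    squeeze_times_s: list[tuple[float, str]] | None = None,
) -> list[ContractionEvent]:
    """Detect muscle-activity bursts in a fixed-rate raw EMG series.

    Full-wave rectification, moving RMS, and a robust baseline threshold
    (median + k * MAD over the initial rest). Detected events whose onset
    falls within ``prompt_tolerance_s`` of a scheduled squeeze start are
    flagged as prompted.

    Parameters
    ----------
    values : raw EMG samples (mV) at ``rate_hz``.
    t0_s : time of the first sample, so returned events sit on the caller's
        timeline (e.g. the merged master clock).
    squeeze_times_s : optional ``(start_s, label)`` pairs of scheduled
        prompts on the same timeline.
    """
    params = params or DetectorParams()
    params.validate()
    env = moving_rms(values, rate_hz, params.env_window_s)

    n_base = min(int(params.baseline_s * rate_hz), len(env))
    base = env[:n_base]
    threshold = float(np.median(base)) + params.threshold_mads * _mad(base)
    # A silent baseline gives threshold 0. The running-sum moving average
    # leaves ~sqrt(eps)*peak residue in otherwise-zero stretches, so keep the
    # threshold above that (1e-6 of the peak envelope is never a real burst).
    threshold = max(threshold, 1e-6 * float(env.max()))

    above = env > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # half-open

    # bridge short gaps, then enforce the minimum duration
    merged: list[list[int]] = [[int(run_starts[0]), int(run_ends[0])]]
    max_gap = params.merge_gap_s * rate_hz
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    min_len = params.min_duration_s * rate_hz

    events: list[ContractionEvent] = []
    for s, e in merged:
        if e - s < min_len:
            continue
        onset = t0_s + s / rate_hz
        offset = t0_s + e / rate_hz
        peak = float(env[s:e].max())
        prompted, label = False, None
        for start_s, lbl in squeeze_times_s or []:
            if abs(onset - start_s) <= params.prompt_tolerance_s:
                prompted, label = True, lbl
                break
        events.append(ContractionEvent(onset, offset, peak, prompted, label))
    return events


@dataclass
class AmplitudeSummary:
    """Per-second contraction envelope amplitudes and their linear trend.

    ``per_second_mv`` holds the mean envelope over each of the 10 contraction
    seconds. ``slope_mv_per_s`` is fitted on the interior seconds only
    (excluding the first and last, which contain the prompt rise and release
    ramps). ``decay_fraction`` normalizes the fitted decline over the
    contraction to the fitted amplitude at 0.5 s, i.e. the fraction of
    initial amplitude lost across the contraction.
    """

    per_second_mv: np.ndarray
    slope_mv_per_s: float
    decay_fraction: float


def epoch_amplitude_summary(
    epoch: Epoch,
    channel: str | None = None,
    env_window_s: float = 0.1,
) -> AmplitudeSummary:
    """Summarize contraction amplitude within one epoch.

    Computes the moving-RMS envelope of the (raw, untouched) epoch samples,
    averages it per contraction second, and fits a linear trend for the
    within-contraction amplitude decline. The raw epoch data are not
    modified.
    """
    if channel is None:
        emg = [c for c in epoch.channels if "_Ch" in c]
        if not emg:
            raise ChannelError("epoch contains no EMG channel")
        channel = emg[0]
    if channel not in epoch.channels:
        raise ChannelError(f"epoch has no channel {channel!r}")
    rel, vals = epoch.channels[channel]
    if len(rel) < 2:
        raise InputError("epoch channel too short to summarize")
    rate = (len(rel) - 1) / (rel[-1] - rel[0])
    env = moving_rms(vals, rate, env_window_s)

    n_sec = int(round(epoch.contraction_s))
    per_second = np.empty(n_sec)
    for k in range(n_sec):
        m = (rel >= k) & (rel < k + 1)
        per_second[k] = env[m].mean() if m.any() else np.nan

    centers = np.arange(n_sec) + 0.5
    interior = slice(1, n_sec - 1)
    b, a = np.polyfit(centers[interior], per_second[interior], 1)
    amp0 = a + 0.5 * b  # fitted amplitude at plateau start (0.5 s)
    span = epoch.contraction_s - 1.0  # plateau length between the two edge ramps
    decay = float(-b * span / amp0) if amp0 > 0 else 0.0
    return AmplitudeSummary(per_second, float(b), decay)
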