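"""Reading and writing the instrument-export CSV dialects.

Each of the five streams is exported as a UTF-8 comma-separated file with one
header row, its own time variable counted from stream-local recording start,
and a trailing ``marker`` column. The NOVA dialects carry a ``time_s`` column
with one row per cardiac beat; the NIRS dialect carries a ``sample_n`` column
from which time is derived as ``n / rate`` (50 Hz by default); the EMG
dialects carry a fixed-rate ``time_s`` column at a nominal 1024 Hz.

Event markers are dedicated rows: the time column holds the key-press
timestamp, all data cells are empty and the ``marker`` cell holds the event
label. This preserves marker times at the 1 microsecond quantum in every
dialect (on NIRS marker rows the sample number is fractional, printed with 5
decimals, which is exactly the microsecond quantum at 50 Hz).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._time import US_PER_S, format_us, to_us
from .errors import DialectError, IntegrityError, ManifestError
from .manifest import (
    EMG_LEFT,
    EMG_RIGHT,
    NIRS,
    NOVA_ADV,
    NOVA_BASIC,
    ChannelManifest,
    default_manifest,
)

BEAT = "beat"  # nominal_rate_hz value for irregular beat-to-beat streams

NIRS_RATE_HZ = 50.0
EMG_RATE_HZ = 1024.0

#: time-column name and nominal rate per dialect
_DIALECTS = {
    NOVA_BASIC: ("time_s", BEAT),
    NOVA_ADV: ("time_s", BEAT),
    NIRS: ("sample_n", NIRS_RATE_HZ),
    EMG_LEFT: ("time_s", EMG_RATE_HZ),
    EMG_RIGHT: ("time_s", EMG_RATE_HZ),
}

MARKER_COLUMN = "marker"


@dataclass
class StreamFrame:
    """One instrument export held in memory.

    Attributes
    ----------
    stream_id:
        One of the five source streams.
    time_us:
        int64 microseconds from stream-local recording start, one entry per
        data row, monotone non-decreasing.
    channels:
        Mapping of local channel name to a value vector of the same length as
        ``time_us``. Missing samples (e.g. during finger-cuff calibration) are
        NaN.
    nominal_rate_hz:
        Positive sampling rate, or :data:`BEAT` for beat-to-beat data.
    markers:
        Mapping of event label to stream-local key-press time (microseconds).
    """

    stream_id: str
    time_us: np.ndarray
    channels: dict[str, np.ndarray]
    nominal_rate_hz: float | str
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_us = np.asarray(self.time_us, dtype=np.int64)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.markers = {k: int(v) for k, v in self.markers.items()}

    # -- accessors ---------------------------------------------------------
    @property
    def time_s(self) -> np.ndarray:
        return self.time_us / US_PER_S

    @property
    def n_samples(self) -> int:
        return len(self.time_us)

    def marker_s(self, label: str) -> float:
        return self.markers[label] / US_PER_S

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any violated frame invariant."""
        n = len(self.time_us)
        for name, vals in self.channels.items():
            if len(vals) != n:
                raise IntegrityError(
                    f"{self.stream_id}: channel {name!r} has {len(vals)} values "
                    f"for {n} timestamps"
                )
        if n and np.any(np.diff(self.time_us) < 0):
            raise IntegrityError(f"{self.stream_id}: time is not monotone non-decreasing")
        if self.nominal_rate_hz != BEAT and n > 1:
            period = US_PER_S / float(self.nominal_rate_hz)
            deltas = np.diff(self.time_us)
            # Tolerate dropped packets: every delta must sit within one
            # representation quantum of an integer number of sample periods.
            k = np.maximum(np.round(deltas / period), 1.0)
            if np.any(np.abs(deltas - k * period) > 1.0):
                raise IntegrityError(
                    f"{self.stream_id}: sample spacing inconsistent with "
                    f"{self.nominal_rate_hz} Hz"
                )
        if n:
            lo, hi = self.time_us[0] - 2 * US_PER_S, self.time_us[-1] + 2 * US_PER_S
            for label, t in self.markers.items():
                if not lo <= t <= hi:
                    raise IntegrityError(
                        f"{self.stream_id}: marker {label!r} at {t / US_PER_S:.6f} s "
                        f"lies outside the recording"
                    )

    # -- transforms --------------------------------------------------------
    def shifted(self, offset_us: int) -> "StreamFrame":
        """Return a copy with all timestamps (samples and markers) shifted."""
        offset_us = int(offset_us)
        return replace(
            self,
            time_us=self.time_us + offset_us,
            channels=dict(self.channels),  # shifting never touches values
            markers={k: v + offset_us for k, v in self.markers.items()},
        )

    def equals(self, other: "StreamFrame") -> bool:
        """Field-for-field equality (NaN-aware on channel values)."""
        if (
            self.stream_id != other.stream_id
            or self.nominal_rate_hz != other.nominal_rate_hz
            or self.markers != other.markers
            or list(self.channels) != list(other.channels)
            or not np.array_equal(self.time_us, other.time_us)
        ):
            return False
        return all(
            np.array_equal(self.channels[k], other.channels[k], equal_nan=True)
            for k in self.channels
        )


def expected_header(dialect: str, manifest: ChannelManifest | None = None) -> list[str]:
    """Full column list (time, data variables, marker) for a dialect."""
    if dialect not in _DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    manifest = manifest or default_manifest()
    time_col, _ = _DIALECTS[dialect]
    return [time_col] + manifest.local_names(dialect) + [MARKER_COLUMN]


def _nirs_sample_strings(time_us: np.ndarray) -> np.ndarray:
    """sample_n column: integers on the 50 Hz grid, 5-decimal fractions off it."""
    period_us = int(round(US_PER_S / NIRS_RATE_HZ))
    n = time_us / period_us
    on_grid = time_us % period_us == 0
    out = np.where(on_grid, "", np.char.mod("%.5f", n)).astype(object)
    idx = np.nonzero(on_grid)[0]
    out[idx] = np.char.mod("%d", (time_us[idx] // period_us))
    return out


def write_stream(
    frame: StreamFrame,
    path: str | os.PathLike,
    manifest: ChannelManifest | None = None,
    float_format: str | None = None,
) -> str:
    """Write ``frame`` to ``path`` in its dialect; returns the path.

    The channel set and order must match the manifest for the frame's
    dialect exactly, otherwise a :class:`ManifestError` is raised before
    anything is written. Two writes of the same frame are byte-identical.
    """
    manifest = manifest or default_manifest()
    if not frame.channels:
        raise ManifestError(f"{frame.stream_id}: refusing to write a frame with no channels")
    expected = manifest.local_names(frame.stream_id)
    if list(frame.channels) != expected:
        raise ManifestError(
            f"{frame.stream_id}: channels {list(frame.channels)} do not match "
            f"manifest {expected}"
        )
    frame.validate()

    labels = list(frame.markers)
    m_times = np.array([frame.markers[k] for k in labels], dtype=np.int64)
    order = np.argsort(m_times, kind="stable")
    m_times = m_times[order]
    m_labels = [labels[i] for i in order]
    pos = np.searchsorted(frame.time_us, m_times, side="right")

    time_all = np.insert(frame.time_us, pos, m_times)
    time_col, _ = _DIALECTS[frame.stream_id]
    if time_col == "sample_n":
        time_strs = _nirs_sample_strings(time_all)
    else:
        time_strs = format_us(time_all)

    data = {time_col: time_strs}
    for name, vals in frame.channels.items():
        data[name] = np.insert(vals, pos, np.nan)
    marker_col = np.full(len(frame.time_us), "", dtype=object)
    marker_col = np.insert(marker_col, pos, np.array(m_labels, dtype=object))
    data[MARKER_COLUMN] = marker_col

    if float_format is None and _six_decimal(frame):
        # 6-decimal data (instrument export precision) survives the fast
        # columnar writer exactly; arbitrary-precision frames take the
        # full-repr path below so read(write(frame)) stays an identity.
        import pyarrow as pa
        import pyarrow.csv as pacsv

        arrays = {
            k: pa.array(v, from_pandas=True) if v.dtype == float else pa.array(v.astype(str))
            for k, v in data.items()
        }
        pacsv.write_csv(pa.table(arrays), path)
        return str(path)

    df = pd.DataFrame(data)
    # %.17g guarantees bit-exact float64 round trips on the general path
    df.to_csv(path, index=False, float_format=float_format or "%.17g")
    return str(path)


def _six_decimal(frame: StreamFrame) -> bool:
    return all(
        np.array_equal(v, np.round(v, 6), equal_nan=True) for v in frame.channels.values()
    )


def read_stream(
    path: str | os.PathLike,
    dialect: str,
    manifest: ChannelManifest | None = None,
) -> StreamFrame:
    """Parse an instrument export into a :class:`StreamFrame`.

    For the NIRS dialect the time axis is derived from the sample-number
    column as ``n / 50`` s. Rows whose data cells are all empty and whose
    marker cell is non-empty are event-marker rows; every non-empty marker
    cell contributes an entry to ``markers`` (first occurrence wins).
    """
    manifest = manifest or default_manifest()
    header = expected_header(dialect, manifest)
    time_col, rate = _DIALECTS[dialect]

    # round_trip float parsing keeps read(write(frame)) an exact identity
    df = pd.read_csv(path, dtype={MARKER_COLUMN: "string"}, float_precision="round_trip")
    if list(df.columns) != header:
        missing = [c for c in header if c not in df.columns]
        if missing:
            raise DialectError(
                f"{path}: not a {dialect} export; missing column(s) {missing}"
            )
        raise DialectError(
            f"{path}: column order/extras do not match the {dialect} dialect: "
            f"{list(df.columns)}"
        )

    if time_col == "sample_n":
        period_us = US_PER_S / NIRS_RATE_HZ
        time_us = np.round(df[time_col].to_numpy(dtype=float) * period_us).astype(np.int64)
    else:
        time_us = to_us(df[time_col].to_numpy(dtype=float))
    if np.any(np.diff(time_us) < 0):
        raise IntegrityError(f"{path}: time column is not monotone non-decreasing")

    marker_raw = df[MARKER_COLUMN].fillna("").to_numpy(dtype=object)
    data_names = header[1:-1]
    values = df[data_names].to_numpy(dtype=float)
    is_marker_row = (marker_raw != "") & np.all(np.isnan(values), axis=1)

    markers: dict[str, int] = {}
    for i in np.nonzero(marker_raw != "")[0]:
        markers.setdefault(str(marker_raw[i]), int(time_us[i]))

    keep = ~is_marker_row
    frame = StreamFrame(
        stream_id=dialect,
        time_us=time_us[keep],
        channels={name: values[keep, j] for j, name in enumerate(data_names)},
        nominal_rate_hz=rate,
        markers=markers,
    )
    frame.validate()
    return frame


def sniff_dialect(path: str | os.PathLike, manifest: ChannelManifest | None = None) -> str:
    """Identify which dialect a CSV belongs to from its header row.

    The two EMG exports share one header (the per-leg loggers are identical
    devices), so the side is disambiguated by the filename: a basename
    containing ``right`` maps to ``EMG_RIGHT``, anything else to ``EMG_LEFT``.
    """
    manifest = manifest or default_manifest()
    with open(path, "r", encoding="utf-8") as fh:
        header = [c.strip('"') for c in fh.readline().strip().split(",")]
    matches = [d for d in _DIALECTS if header == expected_header(d, manifest)]
    if not matches:
        raise DialectError(f"{path}: header matches no known instrument dialect")
    if set(matches) == {EMG_LEFT, EMG_RIGHT}:
        name = os.path.basename(str(path)).lower()
        return EMG_RIGHT if "right" in name else EMG_LEFT
    return matches[0]
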