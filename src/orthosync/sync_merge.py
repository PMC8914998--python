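"""Three-stage event-marker syncing and multi-rate union merging.

The three instrument groups record on independent clocks, and even files
exported by a single instrument can disagree by up to a couple of seconds.
Alignment is anchored on shared event markers (manual key presses on each
acquisition computer): stage 1 aligns the files of one instrument to each
other, stage 2 aligns the instrument groups within one assessment, and
stage 3 aligns fully synced assessments of different participants.

Offsets are applied by shifting timestamps, quantized to 1 microsecond. No
resampling or interpolation ever occurs: the merged master timeline is the
exact set union of all (offset-corrected) sample timestamps, and a channel is
missing at every master row that its own stream did not sample. Marker-based
alignment removes clock offset exactly; what remains is the per-stream human
reaction-time jitter of the key presses, which no shift can remove.

A merged frame carries exactly two marker columns: ``marker_ref`` (the
reference frame's marker stream, by convention the hemodynamic timeline) and
``marker_other`` (all remaining marker streams consolidated). This rule
composes through the merge stages and keeps the default manifest at 70 data
variables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._time import US_PER_S, format_us
from .errors import ManifestError, SyncError
from .io_formats import BEAT, StreamFrame
from .manifest import (
    MARKER_OTHER,
    MARKER_REF,
    STREAM_GROUP,
    STREAM_PREFIX,
    STREAMS,
    ChannelManifest,
    default_manifest,
)


@dataclass
class AlignmentReport:
    """Per-frame offsets applied during syncing and the residuals that remain.

    ``offsets_s`` maps frame key (stream id, or participant-suffixed stream
    id) to the signed shift applied to it; the reference frame's offset is 0.
    ``residuals_s`` holds, per frame, the marker misalignment against the
    reference for the syncing event after shifting; it is 0 at the
    microsecond quantum by construction.
    """

    reference: str
    event: str
    offsets_s: dict[str, float] = field(default_factory=dict)
    residuals_s: dict[str, float] = field(default_factory=dict)

    @property
    def max_abs_residual_s(self) -> float:
        return max((abs(r) for r in self.residuals_s.values()), default=0.0)


@dataclass
class _Source:
    """One stream's samples placed on a master timeline."""

    stream_id: str
    prefix: str
    suffix: str  # participant suffix, "" for single-assessment frames
    time_us: np.ndarray  # shifted, absolute on the master clock
    channels: dict[str, np.ndarray]  # local name -> values
    markers: dict[str, int]
    nominal_rate_hz: float | str
    positions: np.ndarray | None = None  # indices into master_time_us

    def column_name(self, local: str) -> str:
        name = f"{self.prefix}_{local}"
        return f"{name}_{self.suffix}" if self.suffix else name

    @property
    def column_names(self) -> list[str]:
        return [self.column_name(c) for c in self.channels]


def _sorted_union(arrays: list[np.ndarray]) -> np.ndarray:
    """Sorted set union of int64 timestamp vectors (sort-based; multi-million
    element unions are much faster this way than via hashing)."""
    if not arrays:
        return np.empty(0, dtype=np.int64)
    allt = np.concatenate(arrays)
    allt.sort(kind="stable")
    if len(allt) == 0:
        return allt
    keep = np.empty(len(allt), dtype=bool)
    keep[0] = True
    np.not_equal(allt[1:], allt[:-1], out=keep[1:])
    return allt[keep]


def _canonical_key(source: _Source) -> tuple:
    try:
        rank = STREAMS.index(source.stream_id)
    except ValueError:
        rank = len(STREAMS)
    return (source.suffix, rank, source.prefix)


class MergedFrame:
    """Union-time master table over any number of synced sources.

    Samples are stored per source (timestamps + values) together with their
    row positions on the master timeline; wide columns with NaN at uncovered
    rows are materialized on demand. This keeps multi-million-row assessments
    cheap: the master index is a single int64 vector and each channel costs
    only its own samples.
    """

    def __init__(
        self,
        sources: list[_Source],
        marker_ref: dict[str, int],
        marker_other: list[tuple[int, str]],
        reference: str,
        alignment: AlignmentReport | None = None,
        manifest: ChannelManifest | None = None,
    ):
        self.manifest = manifest or default_manifest()
        self.sources = sorted(sources, key=_canonical_key)
        names = [c for s in self.sources for c in s.column_names]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ManifestError(f"duplicate channel names across frames: {dupes}")
        self.master_time_us = _sorted_union(
            [s.time_us for s in self.sources]
        )
        for s in self.sources:
            s.positions = np.searchsorted(self.master_time_us, s.time_us)
        self.marker_ref = dict(marker_ref)
        self.marker_other = sorted(marker_other)
        self.reference = reference
        self.alignment = alignment

    # -- basic shape -------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.master_time_us)

    @property
    def master_time_s(self) -> np.ndarray:
        return self.master_time_us / US_PER_S

    @property
    def channel_columns(self) -> list[str]:
        return [c for s in self.sources for c in s.column_names]

    @property
    def data_columns(self) -> list[str]:
        """All data variables: channel columns plus the two marker columns."""
        return self.channel_columns + [MARKER_REF, MARKER_OTHER]

    @property
    def n_data_variables(self) -> int:
        return len(self.data_columns)

    @property
    def n_values(self) -> int:
        """Total non-missing cells across all channel columns."""
        return sum(len(v) for s in self.sources for v in s.channels.values())

    # -- column access -----------------------------------------------------
    def _find(self, column: str) -> tuple[_Source, str]:
        for s in self.sources:
            for local in s.channels:
                if s.column_name(local) == column:
                    return s, local
        from .errors import ChannelError

        raise ChannelError(f"no channel named {column!r} in merged frame")

    def series(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """(time_s, values) of a channel at its own sample times only."""
        s, local = self._find(column)
        return s.time_us / US_PER_S, s.channels[local]

    def column(self, column: str) -> np.ndarray:
        """Dense column on the master timeline, NaN where not sampled."""
        if column == MARKER_REF:
            return self._marker_column(sorted(self.marker_ref.items(), key=lambda kv: kv[1]))
        if column == MARKER_OTHER:
            return self._marker_column([(lbl, t) for t, lbl in self.marker_other])
        s, local = self._find(column)
        out = np.full(self.n_rows, np.nan)
        out[s.positions] = s.channels[local]
        return out

    def _marker_column(self, items: list[tuple[str, int]]) -> np.ndarray:
        out = np.full(self.n_rows, "", dtype=object)
        for label, t in items:
            i = np.searchsorted(self.master_time_us, t)
            if i == self.n_rows or self.master_time_us[i] != t:
                # marker time not on the master grid (markers are not samples):
                # attach to the nearest master row for tabular export
                if i == self.n_rows or (
                    i > 0 and t - self.master_time_us[i - 1] <= self.master_time_us[i] - t
                ):
                    i = max(i - 1, 0)
            out[i] = label if out[i] == "" else f"{out[i]}|{label}"
        return out

    def missing_mask(self, column: str) -> np.ndarray:
        s, _ = self._find(column)
        mask = np.ones(self.n_rows, dtype=bool)
        mask[s.positions] = False
        return mask

    def marker_time_us(self, label: str) -> int:
        """Marker time on the master timeline (reference stream preferred)."""
        if label in self.marker_ref:
            return self.marker_ref[label]
        for t, lbl in self.marker_other:
            if lbl == label:
                return t
        raise SyncError(f"no marker {label!r} on the master timeline")

    @property
    def marker_labels(self) -> list[str]:
        labels = list(self.marker_ref)
        for _, lbl in self.marker_other:
            if lbl not in labels:
                labels.append(lbl)
        return labels

    # -- export ------------------------------------------------------------
    def to_dataframe(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else self.data_columns
        data: dict[str, np.ndarray] = {"time_s": self.master_time_s}
        for c in cols:
            data[c] = self.column(c)
        return pd.DataFrame(data)

    def to_csv(self, path: str | os.PathLike) -> str:
        """Wide CSV: master time + every data column, empty cells for missing."""
        df = self.to_dataframe()
        df["time_s"] = format_us(self.master_time_us)
        df.to_csv(path, index=False, float_format="%.17g")
        return str(path)

    def shifted(self, offset_us: int) -> "MergedFrame":
        offset_us = int(offset_us)
        sources = [
            replace(
                s,
                time_us=s.time_us + offset_us,
                markers={k: v + offset_us for k, v in s.markers.items()},
                positions=None,
            )
            for s in self.sources
        ]
        return MergedFrame(
            sources,
            {k: v + offset_us for k, v in self.marker_ref.items()},
            [(t + offset_us, lbl) for t, lbl in self.marker_other],
            self.reference,
            self.alignment,
            self.manifest,
        )


# ---------------------------------------------------------------------------
# stage 1: instrument-level syncing
# ---------------------------------------------------------------------------

def sync_instrument(
    frames: Sequence[StreamFrame], event: str
) -> tuple[list[StreamFrame], AlignmentReport]:
    """Align the files of one instrument on a shared event marker.

    The first frame is the reference (offset 0); every other frame is shifted
    so its marker for ``event`` coincides with the reference's at the
    microsecond quantum.
    """
    if not frames:
        raise SyncError("no frames to sync")
    for f in frames:
        if event not in f.markers:
            raise SyncError(f"frame {f.stream_id} has no {event!r} marker")
    ref = frames[0]
    report = AlignmentReport(reference=ref.stream_id, event=event)
    out: list[StreamFrame] = []
    for f in frames:
        offset = ref.markers[event] - f.markers[event]
        g = f.shifted(offset)
        report.offsets_s[f.stream_id] = offset / US_PER_S
        report.residuals_s[f.stream_id] = (ref.markers[event] - g.markers[event]) / US_PER_S
        out.append(g)
    return out, report


# ---------------------------------------------------------------------------
# union merge
# ---------------------------------------------------------------------------

def _frame_to_source(frame: StreamFrame, suffix: str = "") -> _Source:
    prefix = STREAM_PREFIX.get(frame.stream_id, frame.stream_id.lower())
    return _Source(
        stream_id=frame.stream_id,
        prefix=prefix,
        suffix=suffix,
        time_us=frame.time_us,
        channels=dict(frame.channels),  # values are never mutated by merging
        markers=dict(frame.markers),
        nominal_rate_hz=frame.nominal_rate_hz,
    )


def merge_streams(
    frames: Sequence[StreamFrame],
    manifest: ChannelManifest | None = None,
    alignment: AlignmentReport | None = None,
) -> MergedFrame:
    """Union-merge offset-corrected frames into one master table.

    The master timeline is the sorted set union of all sample timestamps.
    Every input sample appears exactly once, at its own timestamp, and no
    value is altered; cells not covered by any input sample are missing. The
    result is independent of the input order (sources and columns follow the
    canonical manifest order).
    """
    if not frames:
        raise ManifestError("nothing to merge")
    sources = [_frame_to_source(f) for f in frames]
    ref = min(sources, key=_canonical_key)
    marker_ref = dict(ref.markers)
    marker_other = [
        (t, lbl) for s in sources if s is not ref for lbl, t in s.markers.items()
    ]
    return MergedFrame(
        sources, marker_ref, marker_other, ref.stream_id, alignment, manifest
    )


# ---------------------------------------------------------------------------
# stage 2: full-frame syncing
# ---------------------------------------------------------------------------

def _default_event(frames: Sequence[StreamFrame], reference: StreamFrame) -> str:
    shared = set(frames[0].markers)
    for f in frames[1:]:
        shared &= set(f.markers)
    if not shared:
        raise SyncError("frames share no event marker to sync on")
    return min(shared, key=lambda lbl: reference.markers[lbl])


def sync_full(
    frames: Sequence[StreamFrame],
    event: str | None = None,
    manifest: ChannelManifest | None = None,
) -> MergedFrame:
    """Two-stage sync of one assessment's exports, then union-merge.

    Stage 1 aligns the frames of each instrument group (NOVA pair, EMG pair)
    on ``event``; stage 2 shifts each group so the event marker of its
    reference file lands on the global reference's (the beat-to-beat
    hemodynamic file when present — the clinical anchor timeline — else the
    canonically first stream supplied). When ``event`` is None the earliest
    marker shared by all frames is used; any shared event gives the same
    relative alignment up to the per-event key-press jitter.
    """
    if not frames:
        raise SyncError("no frames to sync")
    order = {sid: i for i, sid in enumerate(STREAMS)}
    frames = sorted(frames, key=lambda f: order.get(f.stream_id, len(order)))
    global_ref = frames[0]
    if event is None:
        event = _default_event(frames, global_ref)

    report = AlignmentReport(reference=global_ref.stream_id, event=event)
    groups: dict[str, list[StreamFrame]] = {}
    for f in frames:
        groups.setdefault(STREAM_GROUP.get(f.stream_id, f.stream_id), []).append(f)

    synced: list[StreamFrame] = []
    for members in groups.values():
        stage1, rep1 = sync_instrument(members, event)
        group_ref = stage1[0]
        group_offset = global_ref.markers[event] - group_ref.markers[event]
        for f0, g in zip(members, stage1):
            h = g.shifted(group_offset)
            report.offsets_s[f0.stream_id] = (h.markers[event] - f0.markers[event]) / US_PER_S
            report.residuals_s[f0.stream_id] = (
                global_ref.markers[event] - h.markers[event]
            ) / US_PER_S
            synced.append(h)
    return merge_streams(synced, manifest, alignment=report)


# ---------------------------------------------------------------------------
# stage 3: cross-group (multi-participant) syncing
# ---------------------------------------------------------------------------

def sync_cross_group(
    assessments: Sequence[MergedFrame],
    event: str,
    suffixes: Sequence[str | None],
) -> MergedFrame:
    """Merge fully synced assessments of several participants.

    Each assessment's columns gain its suffix (``None`` keeps the suffixes an
    already multi-participant frame carries). The first assessment is the
    reference: its master clock becomes the joint master clock and every other
    assessment is shifted so its ``event`` marker coincides with the
    reference's.
    """
    if len(assessments) != len(suffixes):
        raise ManifestError("one suffix per assessment required")
    flat = [s for s in suffixes if s is not None]
    if len(set(flat)) != len(flat):
        raise ManifestError(f"suffix collision: {sorted(flat)}")

    ref_frame = assessments[0]
    t_ref = ref_frame.marker_time_us(event)
    report = AlignmentReport(
        reference=(suffixes[0] or ref_frame.reference), event=event
    )

    sources: list[_Source] = []
    marker_ref: dict[str, int] = {}
    marker_other: list[tuple[int, str]] = []
    for i, (frame, suffix) in enumerate(zip(assessments, suffixes)):
        offset = t_ref - frame.marker_time_us(event)
        shifted = frame.shifted(offset)
        key = suffix if suffix is not None else f"assessment{i}"
        report.offsets_s[key] = offset / US_PER_S
        report.residuals_s[key] = (t_ref - shifted.marker_time_us(event)) / US_PER_S
        for s in shifted.sources:
            if suffix is not None:
                if s.suffix:
                    raise ManifestError(
                        f"frame already carries suffix {s.suffix!r}; pass None"
                    )
                s = replace(s, suffix=suffix, positions=None)
            sources.append(s)
        if i == 0:
            marker_ref = dict(shifted.marker_ref)
            marker_other.extend(shifted.marker_other)
        else:
            marker_other.extend((t, lbl) for lbl, t in shifted.marker_ref.items())
            marker_other.extend(shifted.marker_other)

    return MergedFrame(
        sources,
        marker_ref,
        marker_other,
        report.reference,
        report,
        ref_frame.manifest,
    )
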