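"""Channel manifest for the five instrument export streams.

The assessment records five CSV exports from three instrument groups:

* ``NOVA_BASIC`` / ``NOVA_ADV`` — beat-to-beat hemodynamics from a finger
  photoplethysmography monitor (irregular timestamps, one row per detected
  beat).
* ``NIRS`` — two near-infrared spectroscopy optodes (forehead and thigh) at a
  fixed 50 Hz, exported with a sample-number column.
* ``EMG_LEFT`` / ``EMG_RIGHT`` — one wearable surface-EMG logger per leg at
  1024 Hz, each with two EMG channels plus 9-axis inertial channels and a
  battery voltage.

The default manifest pins the fully merged frame at exactly 70 data variables
(excluding the master time index): 9 + 13 + 22 + 24 channel columns plus the
two merge-level event-marker columns ``marker_ref`` and ``marker_other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ManifestError

NOVA_BASIC = "NOVA_BASIC"
NOVA_ADV = "NOVA_ADV"
NIRS = "NIRS"
EMG_LEFT = "EMG_LEFT"
EMG_RIGHT = "EMG_RIGHT"
MERGED = "MERGED"

#: Canonical stream order; merged columns and merge references follow it.
STREAMS = (NOVA_BASIC, NOVA_ADV, NIRS, EMG_LEFT, EMG_RIGHT)

#: Column prefix applied to each stream's channels in a merged frame.
STREAM_PREFIX = {
    NOVA_BASIC: "nova_basic",
    NOVA_ADV: "nova_adv",
    NIRS: "nirs",
    EMG_LEFT: "emg_left",
    EMG_RIGHT: "emg_right",
}

#: Instrument group of each stream (stage-1 syncing operates within a group).
STREAM_GROUP = {
    NOVA_BASIC: "nova",
    NOVA_ADV: "nova",
    NIRS: "nirs",
    EMG_LEFT: "emg",
    EMG_RIGHT: "emg",
}

MARKER_REF = "marker_ref"
MARKER_OTHER = "marker_other"


@dataclass(frozen=True)
class ChannelSpec:
    """One data variable: local (in-file) name, units, origin and kind."""

    name: str
    units: str
    source_stream: str
    kind: str  # "continuous" | "beat_to_beat" | "marker"

    @property
    def column(self) -> str:
        """Stream-prefixed column name used in merged frames."""
        if self.source_stream == MERGED:
            return self.name
        return f"{STREAM_PREFIX[self.source_stream]}_{self.name}"


_NOVA_BASIC_CHANNELS = [
    ("SBP_mmHg", "mmHg"),
    ("DBP_mmHg", "mmHg"),
    ("MAP_mmHg", "mmHg"),
    ("HR_bpm", "bpm"),
    ("IBI_s", "s"),
    ("fingerP_mmHg", "mmHg"),
    ("reBAP_mmHg", "mmHg"),
    ("heightcorr_mmHg", "mmHg"),
    ("physiocal_on", "bool"),
]

_NOVA_ADV_CHANNELS = [
    ("CO_lmin", "L/min"),
    ("CI_lminm2", "L/min/m^2"),
    ("SV_ml", "mL"),
    ("SVI_mlm2", "mL/m^2"),
    ("TPR_mmHgsl", "mmHg.s/L"),
    ("TPRI_mmHgslm2", "mmHg.s/L/m^2"),
    ("LVET_ms", "ms"),
    ("PP_mmHg", "mmHg"),
    ("dPdt_mmHgs", "mmHg/s"),
    ("ZAo_mmHgsml", "mmHg.s/mL"),
    ("Cwk_mlmmHg", "mL/mmHg"),
    ("BRS_msmmHg", "ms/mmHg"),
    ("AoFlow_mls", "mL/s"),
]

_NIRS_DEVICES = ("head", "leg")
_NIRS_DISTANCES = ("d1", "d2", "d3")
_NIRS_HB = ("O2Hb", "HHb", "tHb")

_EMG_CHANNELS = [
    ("Ch1_mV", "mV"),
    ("Ch2_mV", "mV"),
    ("accX_g", "g"),
    ("accY_g", "g"),
    ("accZ_g", "g"),
    ("gyroX_dps", "deg/s"),
    ("gyroY_dps", "deg/s"),
    ("gyroZ_dps", "deg/s"),
    ("magX_gauss", "gauss"),
    ("magY_gauss", "gauss"),
    ("magZ_gauss", "gauss"),
    ("battery_V", "V"),
]


def _nirs_channels() -> list[tuple[str, str]]:
    out = []
    for dev in _NIRS_DEVICES:
        for d in _NIRS_DISTANCES:
            for hb in _NIRS_HB:
                out.append((f"{dev}_{d}_{hb}", "umol/L"))
        out.append((f"{dev}_TSI", "%"))
        out.append((f"{dev}_TSIq", "%"))
    return out


@dataclass(frozen=True)
class ChannelManifest:
    """Ordered collection of :class:`ChannelSpec` covering all streams."""

    entries: tuple[ChannelSpec, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = [e.column for e in self.entries]
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ManifestError(f"duplicate manifest column names: {dupes}")
        for e in self.entries:
            if e.kind != "marker" and not e.units:
                raise ManifestError(f"channel {e.name!r} has no units string")

    @property
    def counts(self) -> dict[str, int]:
        """Per-stream data-variable counts (marker columns under 'MERGED')."""
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.source_stream] = out.get(e.source_stream, 0) + 1
        return out

    @property
    def n_data_variables(self) -> int:
        return len(self.entries)

    def channels_for(self, stream_id: str) -> list[ChannelSpec]:
        return [e for e in self.entries if e.source_stream == stream_id]

    def local_names(self, stream_id: str) -> list[str]:
        return [e.name for e in self.channels_for(stream_id)]

    def columns(self) -> list[str]:
        return [e.column for e in self.entries]


def _specs(stream: str, pairs: Iterable[tuple[str, str]], kind: str):
    return [ChannelSpec(name, units, stream, kind) for name, units in pairs]


def default_manifest() -> ChannelManifest:
    """The pinned 70-variable manifest (9 + 13 + 22 + 24 channels + 2 markers)."""
    entries = (
        _specs(NOVA_BASIC, _NOVA_BASIC_CHANNELS, "beat_to_beat")
        + _specs(NOVA_ADV, _NOVA_ADV_CHANNELS, "beat_to_beat")
        + _specs(NIRS, _nirs_channels(), "continuous")
        + _specs(EMG_LEFT, _EMG_CHANNELS, "continuous")
        + _specs(EMG_RIGHT, _EMG_CHANNELS, "continuous")
        + [
            ChannelSpec(MARKER_REF, "", MERGED, "marker"),
            ChannelSpec(MARKER_OTHER, "", MERGED, "marker"),
        ]
    )
    return ChannelManifest(tuple(entries))
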