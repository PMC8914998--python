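"""Raw-data visualization: stacked assessment figure and epoch grids.

Plotted values are exactly the merged frame's values — no smoothing or
filtering. For very long channels an extrema-preserving min-max decimation
reduces the point count per pixel column while guaranteeing that every
per-window minimum and maximum (hence every transient artifact) survives
zooming out. Runs of missing data longer than a configurable gap are drawn
as line breaks, and instrument pauses can be shaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from ._time import US_PER_S
from .epochs import Epoch
from .errors import PlotSpecError
from .sync_merge import MergedFrame

EVENT_LINE_GID = "event-line"
PAUSE_SHADE_GID = "pause-shade"
BLANK_CELL_GID = "blank-cell"


@dataclass
class PanelSpec:
    """One stacked panel: a merged-frame column and its display metadata."""

    channel: str
    label: str | None = None
    units: str | None = None
    ylim: tuple[float, float] | None = None

    @property
    def axis_label(self) -> str:
        base = self.label or self.channel
        return f"{base}\n[{self.units}]" if self.units else base


@dataclass
class PlotSpec:
    """Figure layout: ordered panels, event lines, shading and decimation."""

    panels: list[PanelSpec]
    events: list[str] | None = None  # None = all markers on the frame
    shade: Sequence[tuple[float, float]] | str | None = "auto"
    gap_break_s: float = 1.0
    decimate_above: int = 200_000
    n_bins: int = 1500
    title: str | None = None
    output: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PlotSpec":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        panels = [
            PanelSpec(**p) if isinstance(p, dict) else PanelSpec(channel=p)
            for p in d.get("panels", [])
        ]
        kwargs = {k: v for k, v in d.items() if k != "panels"}
        if "shade" in kwargs and isinstance(kwargs["shade"], list):
            kwargs["shade"] = [tuple(iv) for iv in kwargs["shade"]]
        return cls(panels=panels, **kwargs)


def default_assessment_spec(output: str | None = None) -> PlotSpec:
    """The canonical stacked panel order: EMG, TSI, then hemodynamics."""
    panels = [
        PanelSpec("emg_left_Ch1_mV", "EMG_Left_Ch1", "mV"),
        PanelSpec("emg_left_Ch2_mV", "EMG_Left_Ch2", "mV"),
        PanelSpec("nirs_leg_TSI", "TSI_Leg", "%"),
        PanelSpec("nirs_head_TSI", "TSI_Head", "%"),
        PanelSpec("nova_basic_SBP_mmHg", "SBP", "mmHg"),
        PanelSpec("nova_basic_DBP_mmHg", "DBP", "mmHg"),
        PanelSpec("nova_adv_CO_lmin", "CO", "L/min"),
        PanelSpec("nova_basic_HR_bpm", "HR", "bpm"),
    ]
    return PlotSpec(panels=panels, output=output)


def minmax_decimate(
    t: np.ndarray, v: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only the per-bin extrema (plus bin edges' order) of a series.

    Bins are uniform in time. Within each bin the sample attaining the
    minimum and the one attaining the maximum are kept, in time order, so any
    rendering at up to ``n_bins`` horizontal pixels is indistinguishable from
    the full series.
    """
    if len(t) <= 2 * n_bins:
        return t, v
    edges = np.linspace(t[0], t[-1], n_bins + 1)
    bounds = np.searchsorted(t, edges)
    bounds[-1] = len(t)
    keep: list[int] = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 <= i0:
            continue
        seg = v[i0:i1]
        if np.all(np.isnan(seg)):
            keep.append(int(i0))
            continue
        a = i0 + int(np.nanargmin(seg))
        b = i0 + int(np.nanargmax(seg))
        keep.extend(sorted({a, b}))
    idx = np.array(sorted(set(keep)), dtype=int)
    return t[idx], v[idx]


def _with_gap_breaks(t: np.ndarray, v: np.ndarray, gap_s: float):
    """Insert NaN vertices where consecutive samples are further than gap_s."""
    if len(t) < 2:
        return t, v
    gaps = np.nonzero(np.diff(t) > gap_s)[0] + 1
    if len(gaps) == 0:
        return t, v
    t2 = np.insert(t, gaps, t[gaps - 1] + gap_s / 2.0)
    v2 = np.insert(v, gaps, np.nan)
    return t2, v2


def _auto_pauses(frame: MergedFrame, min_gap_s: float = 30.0):
    """Long gaps in the beat-to-beat reference channels = instrument pauses."""
    intervals = []
    for source in frame.sources:
        if source.nominal_rate_hz != "beat":
            continue
        t = source.time_us / US_PER_S
        big = np.nonzero(np.diff(t) > min_gap_s)[0]
        intervals.extend((float(t[i]), float(t[i + 1])) for i in big)
        break
    return intervals


def plot_assessment(frame: MergedFrame, spec: PlotSpec):
    """Render the stacked multimodal figure; returns the matplotlib Figure.

    One shared time axis; a vertical line per event at its synced master
    marker time in every panel; shaded pause intervals; NaN line breaks over
    missing-data runs longer than ``spec.gap_break_s``. Saves to
    ``spec.output`` when set.
    """
    if not spec.panels:
        raise PlotSpecError("panel list is empty")
    for p in spec.panels:
        frame._find(p.channel)  # raises ChannelError

    n = len(spec.panels)
    fig, axes = plt.subplots(
        n, 1, sharex=True, figsize=(12, max(1.1 * n, 3)), squeeze=False
    )
    axes = axes[:, 0]

    events = spec.events if spec.events is not None else frame.marker_labels
    event_times = {lbl: frame.marker_time_us(lbl) / US_PER_S for lbl in events}

    if spec.shade == "auto":
        shade = _auto_pauses(frame)
    else:
        shade = list(spec.shade or [])

    for ax, panel in zip(axes, spec.panels):
        t, v = frame.series(panel.channel)
        gap_s = spec.gap_break_s
        if len(t) > spec.decimate_above:
            t, v = minmax_decimate(t, v, spec.n_bins)
            # decimated samples are up to ~2 bins apart; don't mistake that for gaps
            gap_s = max(gap_s, 3.0 * (t[-1] - t[0]) / spec.n_bins)
        t, v = _with_gap_breaks(t, v, gap_s)
        ax.plot(t, v, lw=0.5, color="tab:blue")
        ax.set_ylabel(panel.axis_label, rotation=0, ha="right", va="center", fontsize=8)
        if panel.ylim:
            ax.set_ylim(*panel.ylim)
        for lbl, tx in event_times.items():
            line = ax.axvline(tx, color="tab:red", lw=0.8, alpha=0.7)
            line.set_gid(EVENT_LINE_GID)
        for a, b in shade:
            span = ax.axvspan(a, b, color="0.85", zorder=0)
            span.set_gid(PAUSE_SHADE_GID)

    for lbl, tx in event_times.items():
        axes[-1].annotate(
            lbl,
            xy=(tx, 0),
            xycoords=("data", "axes fraction"),
            xytext=(2, -28),
            textcoords="offset points",
            rotation=45,
            fontsize=7,
            ha="left",
            va="top",
            annotation_clip=False,
        )
    axes[-1].set_xlabel("time [s]")
    if spec.title:
        fig.suptitle(spec.title)
    fig.align_ylabels(axes)
    if spec.output:
        fig.savefig(spec.output, dpi=120, bbox_inches="tight")
    return fig


def plot_epoch_grid(
    epochs_by_participant: dict[str, list[Epoch]],
    channel: str | None = None,
    output: str | None = None,
):
    """Grid of raw contraction epochs: rows = participants, columns = squeezes.

    Cells for squeezes a participant did not perform (early termination) are
    left blank. All axes share the relative time axis of the 30 s epoch
    (-10 s to +20 s around the prompt).
    """
    if not epochs_by_participant or all(
        not eps for eps in epochs_by_participant.values()
    ):
        raise PlotSpecError("no epochs to plot")

    labels = sorted(
        {e.label for eps in epochs_by_participant.values() for e in eps}
    )
    rows = list(epochs_by_participant)
    fig, axes = plt.subplots(
        len(rows),
        len(labels),
        sharex=True,
        sharey="row",
        figsize=(3.0 * len(labels), 2.2 * len(rows)),
        squeeze=False,
    )
    for i, participant in enumerate(rows):
        by_label = {e.label: e for e in epochs_by_participant[participant]}
        for j, lbl in enumerate(labels):
            ax = axes[i, j]
            epoch = by_label.get(lbl)
            if epoch is None:
                ax.set_axis_off()
                ax.set_gid(BLANK_CELL_GID)
                continue
            ch = channel
            if ch is None:
                emg = [c for c in epoch.channels if "_Ch" in c]
                ch = emg[0] if emg else next(iter(epoch.channels))
            rel, vals = epoch.channels[ch]
            ax.plot(rel, vals, lw=0.4, color="tab:blue")
            ax.axvspan(0, epoch.contraction_s, color="tab:green", alpha=0.12)
            if i == 0:
                ax.set_title(lbl, fontsize=9)
            if j == 0:
                ax.set_ylabel(participant, fontsize=9)
            ax.set_xlim(-10, 20)
    for ax in axes[-1, :]:
        ax.set_xlabel("time from prompt [s]")
    fig.tight_layout()
    if output:
        fig.savefig(output, dpi=120)
    return fig
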