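"""Event-file reading and histogram construction.

The canonical interchange format is a plain CSV with an ``intensity``
column (one row per event), as written by the simulator's exporter.
FCS files are recognized by their magic bytes but not parsed; convert
to the CSV dialect upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intensity import DEFAULT_BINS, IntensityHistogram, log_bin_edges

__all__ = [
    "EventTable",
    "FormatError",
    "SchemaError",
    "read_events",
    "build_histogram",
]


class FormatError(ValueError):
    """The file is not in a supported event-file format."""


class SchemaError(ValueError):
    """The file parses but lacks the expected channel/column."""


@dataclass(frozen=True)
class EventTable:
    """Per-event fluorescence intensities from one acquisition."""

    intensities: np.ndarray
    channel_name: str = "intensity"
    source: str = ""
    acquisition_label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", x)
        if x.size == 0:
            raise ValueError("event table is empty")
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.intensities.size


def read_events(path, channel: str = "intensity",
                acquisition_label: str = "") -> EventTable:
    """Read an event file (CSV dialect with an ``intensity`` column).

    FCS files are detected and rejected with a pointer to the CSV
    dialect; unknown formats raise :class:`FormatError` and a missing
    column raises :class:`SchemaError` listing the available names.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(6)
    if head.startswith(b"FCS"):
        raise FormatError(
            f"{path} is an FCS file; export events to the CSV dialect "
            "(header 'cell_id,intensity') before loading")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to FormatError
        raise FormatError(f"{path} is not a readable CSV event file: {exc}") from exc
    if channel not in frame.columns:
        raise SchemaError(f"column {channel!r} not found in {path}; "
                          f"available: {list(frame.columns)}")
    return EventTable(intensities=frame[channel].to_numpy(dtype=float),
                      channel_name=channel, source=str(path),
                      acquisition_label=acquisition_label)


def build_histogram(events, n_bins: int = DEFAULT_BINS,
                    floor: float | None = None, ceiling: float | None = None,
                    bin_edges: np.ndarray | None = None) -> IntensityHistogram:
    """Log-binned, normalized intensity histogram.

    Events below the floor are clamped into the first bin (the
    autofluorescence bin) and events above the ceiling into the last,
    so the density always integrates to 1.  Pass ``bin_edges`` to reuse
    a previously chosen axis (e.g. the day-0 axis for chase samples).
    """
    x = np.asarray(events.intensities if isinstance(events, EventTable) else events,
                   dtype=float)
    if x.size == 0:
        raise ValueError("no events to histogram")
    if bin_edges is None:
        if ceiling is None:
            ceiling = float(np.quantile(x, 0.999))
        if floor is None:
            floor = min(0.01 * float(np.median(x)), ceiling / 2.0)
        bin_edges = log_bin_edges(floor, ceiling, n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.all(x < bin_edges[0]):
        raise ValueError("all events fall below the autofluorescence floor")
    log_edges = np.log(bin_edges)
    lx = np.clip(np.log(np.maximum(x, bin_edges[0])),
                 log_edges[0], np.nextafter(log_edges[-1], -np.inf))
    mass, _ = np.histogram(lx, bins=log_edges)
    density = mass / mass.sum() / np.diff(log_edges)
    return IntensityHistogram(bin_edges=bin_edges, density=density,
                              total_events=x.size)
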