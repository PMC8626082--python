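"""Domain types and file I/O for spike trains, event series and results.

All times are seconds as floating point. Spike files are either a single
column of times (one neuron) or delimited tables with ``neuron_id,time``
columns; event files are delimited tables with ``time`` and an optional
``label`` column. Results round-trip through JSON and TSV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "EventSeries",
    "AnalysisWindow",
    "ResultRecord",
    "read_spike_times",
    "read_event_times",
    "write_results",
    "read_results",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of a single neuron, sorted non-decreasing.

    Duplicate times are permitted (spike sorting can emit them); all times
    must be finite and non-negative.
    """

    times: np.ndarray
    neuron_id: Any = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size and not np.all(np.isfinite(times)):
            raise ValueError("spike times must be finite")
        if times.size and times.min() < 0:
            raise ValueError("spike times must be non-negative")
        if np.any(np.diff(times) < 0):
            warnings.warn("spike times were not sorted; sorting", stacklevel=2)
            times = np.sort(times, kind="stable")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EventSeries:
    """Event (stimulus-onset) times, strictly increasing, with optional labels."""

    onsets: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1:
            raise ValueError("event onsets must be one-dimensional")
        if onsets.size and not np.all(np.isfinite(onsets)):
            raise ValueError("event onsets must be finite")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != onsets.size:
                raise ValueError("labels must match the number of events")
            object.__setattr__(self, "labels", labels)

    @property
    def q(self) -> int:
        return self.onsets.size

    def median_interval(self) -> float:
        """Median onset-to-onset interval; the default analysis window."""
        if self.q < 2:
            raise ValueError("need at least 2 events for an onset interval")
        return float(np.median(np.diff(self.onsets)))


@dataclass(frozen=True)
class AnalysisWindow:
    """Post-event window [0, tau] over which spikes are pooled."""

    tau: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError("tau must be a finite positive duration")

    @classmethod
    def from_events(cls, events: EventSeries) -> "AnalysisWindow":
        return cls(events.median_interval())


def resolve_window(
    events: EventSeries, window: "AnalysisWindow | float | None"
) -> AnalysisWindow:
    """Coerce ``window`` to an AnalysisWindow, defaulting to the median
    onset-to-onset interval of ``events``."""
    if window is None:
        return AnalysisWindow.from_events(events)
    if isinstance(window, AnalysisWindow):
        return window
    return AnalysisWindow(float(window))


@dataclass
class ResultRecord:
    """One test outcome for one neuron.

    ``extras`` carries auxiliary quantities (latencies, zeta, bin width ...)
    keyed by name. An undefined statistic is stored as None and serialized
    as a JSON null.
    """

    neuron_id: Any
    test: str
    p: float
    statistic: float | None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.statistic is not None and not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite or None")

    def to_dict(self) -> dict[str, Any]:
        return {
            "neuron_id": self.neuron_id,
            "test": self.test,
            "p": self.p,
            "statistic": self.statistic,
            **self.extras,
        }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_spike_times(path: str | Path, format: str = "auto") -> list[SpikeTrain]:
    """Read spike trains from a text file.

    Supported dialects: ``single-column`` (one time per line, one neuron)
    and ``table`` (CSV/TSV with header columns ``neuron_id,time``).
    ``auto`` picks based on the header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty spike file")
    if format == "auto":
        first = text.lstrip().splitlines()[0]
        format = "table" if any(c.isalpha() for c in first) else "single-column"
    if format == "single-column":
        times = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {line!r} on line {lineno}"
                ) from None
        return [_make_train(np.array(times), 0)]
    if format == "table":
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        if "time" not in cols:
            raise ParseError(f"{path}: missing 'time' column")
        bad = pd.to_numeric(df[cols["time"]], errors="coerce").isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ParseError(f"{path}: non-numeric time on line {lineno}")
        df[cols["time"]] = df[cols["time"]].astype(float)
        if "neuron_id" in cols:
            trains = []
            for nid, grp in df.groupby(cols["neuron_id"], sort=True):
                trains.append(_make_train(grp[cols["time"]].to_numpy(), nid))
            return trains
        return [_make_train(df[cols["time"]].to_numpy(), 0)]
    raise ValueError(f"unknown spike file format {format!r}")


def _make_train(times: np.ndarray, neuron_id: Any) -> SpikeTrain:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SpikeTrain(np.sort(times, kind="stable"), neuron_id)


def read_event_times(path: str | Path) -> EventSeries:
    """Read an event series from a CSV/TSV file with columns ``time[,label]``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not path.read_text().strip():
        raise ParseError(f"{path}: empty event file")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    # Tolerate an optional header row.
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ParseError(f"{path}: no event rows")
    try:
        onsets = df[0].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric event time ({exc})") from None
    labels = None
    if df.shape[1] > 1 and df[1].notna().any():
        labels = tuple(df[1].astype(str))
    if onsets.size < 2:
        raise ParseError(f"{path}: insufficient events (need >= 2)")
    if np.any(np.diff(onsets) <= 0):
        raise ParseError(f"{path}: event times must be strictly increasing")
    return EventSeries(onsets, labels)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(
    records: Iterable[ResultRecord | Mapping[str, Any]],
    path: str | Path,
    format: str = "auto",
) -> None:
    """Write result records as JSON (machine) or TSV (tabular).

    JSON preserves full float precision; ``read_results(write_results(r))``
    reproduces all numeric fields exactly. Undefined statistics serialize
    as null (JSON) / empty field (TSV).
    """
    path = Path(path)
    rows = [r.to_dict() if isinstance(r, ResultRecord) else dict(r) for r in records]
    if format == "auto":
        format = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "json"
    if format == "json":
        path.write_text(json.dumps(rows, indent=1, default=str) + "\n")
    elif format == "tsv":
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path: str | Path) -> list[dict[str, Any]]:
    """Read back a JSON results document written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
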