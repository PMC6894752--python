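"""Scored behavioral events -> binary freezing series, epochs and summaries.

Freezing is scored as bouts (start/stop in seconds) by human observers in
ethogram software such as BORIS; the analyses downstream work on a 1 Hz
binary indicator (1 = freezing during that second).  A bout only counts as
freezing if it lasts at least ``min_bout_s`` seconds (default 3 s, the
conventional cutoff separating brief immobility from freezing), and a second
``t`` is marked frozen iff the union of retained bouts covers the whole
half-open interval ``[t, t+1)``.

Epochs are 710-s half-open windows: the baseline starts at the beginning of
the test and the shock epoch at the first foot shock (approximately 720 s
into a 24-minute test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BoutEvent",
    "FreezingSeries",
    "EpochWindow",
    "events_to_series",
    "series_to_bouts",
    "extract_epochs",
    "freezing_percent",
    "cpp_preference_ratio",
    "read_events_csv",
    "write_series_csv",
    "read_series_csv",
    "write_epoch_summary",
]

DEFAULT_EPOCH_LEN_S = 710
DEFAULT_MIN_BOUT_S = 3.0


@dataclass(frozen=True)
class BoutEvent:
    """One scored behavior bout."""

    subject_id: str
    behavior: str
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"bout start must be >= 0, got {self.start}")
        if self.stop <= self.start:
            raise ValueError(f"malformed bout: stop ({self.stop}) <= start ({self.start})")

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class FreezingSeries:
    """1 Hz binary freezing indicator; index 0 is the start of the test."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("freezing series must be one-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("freezing series values must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def duration_s(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EpochWindow:
    """Half-open window [start_s, start_s + length_s) in series time."""

    label: str
    start_s: int
    length_s: int = DEFAULT_EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError("epoch start must be >= 0")
        if self.length_s <= 0:
            raise ValueError("epoch length must be > 0")

    @property
    def stop_s(self) -> int:
        return self.start_s + self.length_s

    def slice(self) -> slice:
        return slice(self.start_s, self.stop_s)


def events_to_series(
    events: list[BoutEvent],
    duration_s: int,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
    subject_id: str = "",
) -> FreezingSeries:
    """Rasterize scored bouts to a 1 Hz binary series.

    Bouts shorter than ``min_bout_s`` are discarded before taking the union
    (the cutoff applies to raw scored bouts, matching the scoring workflow);
    second ``t`` is 1 iff ``[t, t+1)`` lies entirely inside the union of the
    retained bouts.  Overlapping bouts are allowed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    for ev in events:
        if ev.start < 0 or ev.stop > duration_s:
            raise ValueError(
                f"bout [{ev.start}, {ev.stop}] outside the recording [0, {duration_s}]"
            )
    kept = [(ev.start, ev.stop) for ev in events if ev.duration >= min_bout_s]
    values = np.zeros(duration_s, dtype=np.int8)
    if kept:
        # merge intervals, then mark fully covered seconds
        kept.sort()
        merged = [list(kept[0])]
        for start, stop in kept[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], stop)
            else:
                merged.append([start, stop])
        for start, stop in merged:
            lo = int(np.ceil(start))
            hi = int(np.floor(stop))
            if hi - lo >= 1:
                values[lo:hi] = 1
    return FreezingSeries(values=values, subject_id=subject_id)


def series_to_bouts(
    series: FreezingSeries, behavior: str = "freezing"
) -> list[BoutEvent]:
    """Runs of 1s as bout events with integer-second boundaries."""
    v = series.values
    edges = np.flatnonzero(np.diff(np.concatenate([[0], v, [0]])))
    starts, stops = edges[::2], edges[1::2]
    return [
        BoutEvent(series.subject_id, behavior, float(a), float(b))
        for a, b in zip(starts, stops)
    ]


def extract_epochs(
    series: FreezingSeries,
    first_shock_s: int,
    epoch_len_s: int = DEFAULT_EPOCH_LEN_S,
) -> tuple[EpochWindow, EpochWindow]:
    """Baseline = first ``epoch_len_s`` seconds; shock epoch starts at the
    first shock."""
    if first_shock_s < 0:
        raise ValueError("first_shock_s must be >= 0")
    if epoch_len_s > series.duration_s:
        raise ValueError(
            f"series of {series.duration_s}s too short for a {epoch_len_s}s baseline"
        )
    if first_shock_s + epoch_len_s > series.duration_s:
        raise ValueError(
            f"series of {series.duration_s}s too short for a {epoch_len_s}s shock epoch "
            f"starting at {first_shock_s}s"
        )
    return (
        EpochWindow("baseline", 0, epoch_len_s),
        EpochWindow("shock", first_shock_s, epoch_len_s),
    )


def freezing_percent(series: FreezingSeries, window: EpochWindow) -> float:
    """Percent of seconds spent freezing inside the window."""
    if window.stop_s > series.duration_s:
        raise ValueError("epoch window extends past the end of the series")
    seg = series.values[window.slice()]
    if seg.size == 0:
        raise ZeroDivisionError("empty epoch window: freezing percent undefined")
    return 100.0 * float(seg.sum()) / seg.size


def cpp_preference_ratio(t_same_s: float, t_diff_s: float) -> float:
    """Choice-preference ratio (t_same - t_diff) / (t_same + t_diff).

    ``t_same_s``/``t_diff_s`` are the times the observer spent in the
    proximal zone of the same-strain vs the different-strain demonstrator.
    """
    if t_same_s < 0 or t_diff_s < 0:
        raise ValueError("zone times must be >= 0")
    total = t_same_s + t_diff_s
    if total == 0:
        raise ZeroDivisionError("no proximal-zone time at all: ratio undefined")
    return (t_same_s - t_diff_s) / total


# ---------------------------------------------------------------------------
# text I/O (BORIS-style event exports mapped to subject/behavior/start/stop)

def read_events_csv(
    path, column_map: dict[str, str] | None = None, behavior: str | None = None
) -> list[BoutEvent]:
    """Read an ethogram event log (CSV with subject, behavior, start, stop).

    ``column_map`` renames export-dialect columns onto the required names,
    e.g. ``{"Subject": "subject", "Behavior": "behavior", ...}`` for raw
    BORIS exports.  ``behavior`` optionally filters to one behavior label.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"subject", "behavior", "start", "stop"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if behavior is not None:
        df = df[df["behavior"] == behavior]
    return [
        BoutEvent(str(r.subject), str(r.behavior), float(r.start), float(r.stop))
        for r in df.itertuples()
    ]


def write_series_csv(series: FreezingSeries, path) -> None:
    pd.DataFrame({"t": np.arange(series.duration_s), "value": series.values}).to_csv(
        path, index=False
    )


def read_series_csv(path, subject_id: str = "") -> FreezingSeries:
    df = pd.read_csv(path)
    return FreezingSeries(values=df["value"].to_numpy(), subject_id=subject_id)


def write_epoch_summary(summaries: list[dict], path) -> None:
    """Write epoch freezing summaries as CSV or JSON depending on suffix."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(summaries, indent=2))
    else:
        pd.DataFrame(summaries).to_csv(path, index=False)
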