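"""Reading, validation and windowing of beat-annotated RR-interval series.

The pipeline's raw input is a per-patient stream of annotated heartbeats:
for every beat, its time from the start of the recording, the RR interval
ending at it, and a beat label (``N`` sinus, ``V`` ventricular ectopic,
``S`` supraventricular ectopic, ``X`` artifact/unanalyzable).  The on-disk
dialect is plain comma-separated text with a ``# clock_start=HH:MM:SS``
header carrying the recorder's wall-clock start time, so nocturnal windows
can be cut by time of day.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

VALID_LABELS = frozenset("NVSX")

#: Seconds in a day; clock arithmetic is modular with this period.
DAY_S = 86400.0


class BeatSeriesError(ValueError):
    """Raised when a beat series violates its structural invariants."""


@dataclass(frozen=True)
class BeatSeries:
    """Time-stamped RR intervals with beat labels.

    ``rr_ms[i]`` is the interval *ending* at ``beat_times[i]``; for two
    consecutive annotated beats it equals their time difference.  After
    filtering (nocturnal windowing, NN selection) gaps may exist, in which
    case ``rr_ms[i]`` is shorter than the time since the previous retained
    beat -- downstream code treats those as discontinuities.
    """

    patient_id: str
    clock_start: float  # seconds from midnight
    beat_times: np.ndarray  # seconds from recording start, strictly increasing
    rr_ms: np.ndarray
    labels: np.ndarray  # unicode, one of N/V/S/X

    def __post_init__(self) -> None:
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))
        object.__setattr__(self, "rr_ms", np.asarray(self.rr_ms, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype="U1"))
        n = len(self.beat_times)
        if len(self.rr_ms) != n or len(self.labels) != n:
            raise BeatSeriesError("beat_times, rr_ms and labels must have equal length")
        if not 0 <= self.clock_start < DAY_S:
            raise BeatSeriesError("clock_start must lie in [0, 86400)")
        if n:
            if np.any(np.diff(self.beat_times) <= 0):
                i = int(np.argmax(np.diff(self.beat_times) <= 0)) + 1
                raise BeatSeriesError(f"beat_times not strictly increasing at row {i}")
            bad = np.flatnonzero(self.rr_ms <= 0)
            if bad.size:
                raise BeatSeriesError(f"non-positive RR at row {int(bad[0])}")
            unknown = ~np.isin(self.labels, list(VALID_LABELS))
            if unknown.any():
                i = int(np.argmax(unknown))
                raise BeatSeriesError(f"unknown beat label {self.labels[i]!r} at row {i}")

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def clock_times(self) -> np.ndarray:
        """Wall-clock time of each beat, seconds from midnight (mod 24 h)."""
        return (self.clock_start + self.beat_times) % DAY_S

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        out = {lab: 0 for lab in "NVSX"}
        out.update(dict(zip(labels.tolist(), (int(c) for c in counts))))
        return out

    def take(self, index: np.ndarray) -> "BeatSeries":
        return replace(
            self,
            beat_times=self.beat_times[index],
            rr_ms=self.rr_ms[index],
            labels=self.labels[index],
        )


@dataclass(frozen=True)
class NocturnalWindow:
    """Time-of-day window for the nocturnal analysis segment.

    Defaults to 00:00-06:00, the 6-h segment in which most patients are
    assumed asleep.  ``minimum_coverage_fraction`` is the analyzable-time
    fraction of the window below which a patient is flagged non-analyzable
    (distinct from having a flat tachogram).
    """

    start: float = 0.0
    end: float = 21600.0
    minimum_coverage_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end <= DAY_S:
            raise ValueError("need 0 <= start < end <= 86400")
        if not 0 <= self.minimum_coverage_fraction <= 1:
            raise ValueError("minimum_coverage_fraction must lie in [0, 1]")

    @property
    def length_s(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentResult:
    """Nocturnal extraction outcome: the windowed beats plus coverage."""

    series: BeatSeries
    coverage: float
    analyzable: bool
    window: NocturnalWindow = field(default_factory=NocturnalWindow)


def _parse_clock(text: str) -> float:
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise BeatSeriesError(f"cannot parse clock_start {text!r} (want HH:MM:SS)")
    h, m, s = (float(p) for p in parts)
    return (h * 3600 + m * 60 + s) % DAY_S


def _format_clock(seconds: float) -> str:
    seconds = seconds % DAY_S
    h, rem = divmod(int(round(seconds)), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def read_beat_series(
    path: Union[str, Path, io.TextIOBase], dialect: str = "csv", patient_id: str | None = None
) -> BeatSeries:
    """Read and validate a beat series from delimited text.

    Expected layout: a ``# clock_start=HH:MM:SS`` comment line, then a
    ``time_s,rr_ms,label`` header and one row per beat.  Artifact-labeled
    beats are retained (flagged ``X``); validation errors name the
    offending data row.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'csv' is implemented")
    if isinstance(path, (str, Path)):
        path = Path(path)
        pid = patient_id or path.stem
        text = path.read_text()
    else:
        pid = patient_id or "unknown"
        text = path.read()

    clock_start = 0.0
    header: list[str] | None = None
    times: list[float] = []
    rrs: list[float] = []
    labs: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("clock_start"):
                clock_start = _parse_clock(body.split("=", 1)[1])
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            header = fields
            missing = {"time_s", "rr_ms", "label"} - set(header)
            if missing:
                raise BeatSeriesError(f"missing column(s): {sorted(missing)}")
            continue
        row = dict(zip(header, fields))
        try:
            times.append(float(row["time_s"]))
            rrs.append(float(row["rr_ms"]))
            labs.append(row["label"])
        except (KeyError, ValueError) as exc:
            raise BeatSeriesError(f"malformed row at line {lineno}: {raw!r}") from exc

    if not times:
        raise BeatSeriesError("no beats")
    return BeatSeries(pid, clock_start, np.array(times), np.array(rrs), np.array(labs))


def write_beat_series(series: BeatSeries, path: Union[str, Path]) -> None:
    """Write a beat series in the same dialect :func:`read_beat_series` reads."""
    lines = [f"# clock_start={_format_clock(series.clock_start)}", "time_s,rr_ms,label"]
    for t, rr, lab in zip(series.beat_times, series.rr_ms, series.labels):
        lines.append(f"{t:.3f},{rr:.3f},{lab}")
    Path(path).write_text("\n".join(lines) + "\n")


def validation_report(series: BeatSeries) -> dict:
    """Per-patient JSON-serializable validation summary."""
    counts = series.label_counts()
    return {
        "patient_id": series.patient_id,
        "n_beats": len(series),
        "clock_start": _format_clock(series.clock_start),
        "duration_s": float(series.beat_times[-1] - series.beat_times[0]) if len(series) else 0.0,
        "label_counts": counts,
        "artifact_fraction": counts["X"] / max(len(series), 1),
    }


def write_validation_report(series: BeatSeries, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(validation_report(series), indent=2) + "\n")


def extract_nocturnal_segment(
    series: BeatSeries, window: NocturnalWindow | None = None
) -> SegmentResult:
    """Cut the beats whose wall-clock time falls in ``[start, end)``.

    Window membership is judged by each beat's end time (clock_start plus
    beat time, modulo 24 h), so recordings crossing midnight work without
    special-casing.  Coverage is the analyzable time inside the window
    (sum of in-window RR intervals) over the window length; a patient
    below the minimum is flagged non-analyzable.
    """
    window = window or NocturnalWindow()
    clock = series.clock_times
    inside = (clock >= window.start) & (clock < window.end)
    sub = series.take(np.flatnonzero(inside))
    covered_s = float(np.sum(sub.rr_ms) / 1000.0)
    coverage = min(covered_s / window.length_s, 1.0)
    return SegmentResult(
        series=sub,
        coverage=coverage,
        analyzable=coverage >= window.minimum_coverage_fraction,
        window=window,
    )


def nn_filter(series: BeatSeries) -> BeatSeries:
    """Keep only normal-to-normal intervals.

    An interval is NN when both bounding beats are sinus (``N``): the
    retained rows are beats labeled N whose predecessor is also N.  Gaps
    left by ectopy or artifact remain as discontinuities in the time axis;
    nothing is interpolated here.
    """
    if len(series) < 2 or int(np.sum(series.labels == "N")) < 2:
        warnings.warn(
            f"{series.patient_id}: fewer than 2 sinus beats; no NN intervals",
            stacklevel=2,
        )
        return series.take(np.array([], dtype=int))
    is_n = series.labels == "N"
    # interval i spans beat i-1 -> i; also require contiguity in time so
    # windowed-out stretches do not masquerade as NN intervals
    contiguous = np.isclose(
        np.diff(series.beat_times) * 1000.0, series.rr_ms[1:], rtol=0, atol=1.0
    )
    keep = np.flatnonzero(is_n[1:] & is_n[:-1] & contiguous) + 1
    return series.take(keep)
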