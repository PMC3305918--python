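"""Reading, validation and normal-beat filtering of RR-interval records.

An :class:`RRSeries` is one session's raw beat-to-beat interval sequence
with per-beat normal/non-normal labels.  Filtering to normal beats yields
an :class:`NNSeries`, which carries the NN/RR ratio used as the record
reliability criterion (records with a ratio below 90% are excluded).

Supported plain-text formats:

* ``two-column-csv`` — one beat per line, ``interval_seconds,label``
* ``single-column-text`` — one interval per line; labels default to normal
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import DegenerateSeriesError, RRParseError, ValidationError

NORMAL_LABEL = "N"

Session = Literal["rest", "stress"]
RRFormat = Literal["two-column-csv", "single-column-text", "auto"]


@dataclass(frozen=True)
class RRSeries:
    """One session's beat-interval sequence with per-beat labels (seconds)."""

    intervals: np.ndarray
    labels: np.ndarray
    subject_id: str = ""
    session: str = "rest"

    def __post_init__(self):
        intervals = np.asarray(self.intervals, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "labels", labels)
        if intervals.ndim != 1 or labels.ndim != 1:
            raise ValidationError("intervals and labels must be 1-D sequences")
        if len(intervals) != len(labels):
            raise ValidationError(
                f"intervals ({len(intervals)}) and labels ({len(labels)}) "
                "must have equal length"
            )
        if len(intervals) < 2:
            raise ValidationError("an RR series needs at least 2 intervals")
        if not np.all(np.isfinite(intervals)) or np.any(intervals <= 0):
            raise ValidationError("every RR interval must be finite and > 0")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def is_normal(self) -> np.ndarray:
        return np.asarray([lab == NORMAL_LABEL for lab in self.labels])


@dataclass(frozen=True)
class NNSeries:
    """Normal-to-normal intervals (seconds) with the NN/RR reliability ratio."""

    intervals: np.ndarray
    nn_rr_ratio: float
    subject_id: str = ""
    session: str = "rest"

    def __post_init__(self):
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if not 0.0 <= self.nn_rr_ratio <= 1.0:
            raise ValidationError("nn_rr_ratio must lie in [0, 1]")
        if len(intervals) < 2:
            raise DegenerateSeriesError(
                "fewer than 2 normal intervals after filtering"
            )
        if np.any(intervals <= 0):
            raise ValidationError("every NN interval must be > 0")

    def __len__(self) -> int:
        return len(self.intervals)


def _parse_line(raw: str, lineno: int, unit_scale: float) -> tuple[float, str] | None:
    line = raw.strip()
    if not line or line.startswith("#"):
        return None
    parts = [p.strip() for p in line.split(",")]
    if len(parts) == 1:
        value_str, label = parts[0], NORMAL_LABEL
    elif len(parts) == 2:
        value_str, label = parts
        label = label or NORMAL_LABEL
    else:
        raise RRParseError(f"expected 1 or 2 fields, got {len(parts)}", lineno)
    try:
        value = float(value_str)
    except ValueError:
        raise RRParseError(f"cannot parse duration {value_str!r}", lineno) from None
    if not np.isfinite(value) or value <= 0:
        raise ValidationError(
            f"line {lineno}: non-positive or non-finite duration {value!r}"
        )
    return value * unit_scale, label


def read_rr(
    path: str | Path,
    format: RRFormat = "auto",
    subject_id: str = "",
    session: str = "rest",
    unit: Literal["s", "ms"] = "s",
) -> RRSeries:
    """Read one RR record from a plain-text file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"two-column-csv"`` (interval,label per line), ``"single-column-text"``
        (interval per line, all beats labelled normal) or ``"auto"``
        (detected from the first data line).
    unit
        ``"ms"`` divides durations by 1000; internal unit is always seconds.

    Raises
    ------
    RRParseError
        Malformed line (the message names the 1-based line number).
    ValidationError
        Non-positive duration, or a labelled line in single-column mode.
    """
    path = Path(path)
    unit_scale = 1.0 if unit == "s" else 1e-3
    if unit not in ("s", "ms"):
        raise ValidationError(f"unknown unit {unit!r}")
    intervals: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parsed = _parse_line(raw, lineno, unit_scale)
            if parsed is None:
                continue
            value, label = parsed
            if format == "single-column-text" and "," in raw:
                raise RRParseError("single-column file contains a comma", lineno)
            intervals.append(value)
            labels.append(label)
    if len(intervals) < 2:
        raise DegenerateSeriesError(f"{path}: fewer than 2 intervals")
    return RRSeries(np.asarray(intervals), np.asarray(labels, dtype=object),
                    subject_id=subject_id, session=session)


def write_rr(rr: RRSeries, path: str | Path) -> None:
    """Write an RRSeries as two-column CSV (round-trips with read_rr)."""
    with open(path, "w") as fh:
        for value, label in zip(rr.intervals, rr.labels):
            fh.write(f"{float(value)!r},{label}\n")


def to_nn(rr: RRSeries) -> NNSeries:
    """Restrict an RR series to its normal beats, preserving order.

    The NN/RR ratio is the fraction of beats labelled normal.  Non-normal
    beats are removed, not interpolated.
    """
    mask = rr.is_normal
    nn = rr.intervals[mask]
    ratio = float(mask.sum()) / len(rr)
    if len(nn) < 2:
        raise DegenerateSeriesError(
            f"record {rr.subject_id}/{rr.session}: only {len(nn)} normal "
            "interval(s); at least 2 required"
        )
    return NNSeries(nn, ratio, subject_id=rr.subject_id, session=rr.session)


def reliability_check(nn: NNSeries, threshold: float = 0.90) -> bool:
    """True iff the NN/RR ratio is at least ``threshold``.

    Exclusion applies to records whose ratio is *less than* the threshold,
    so a ratio exactly at the boundary is retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    return nn.nn_rr_ratio >= threshold


def write_nn(nn: NNSeries, csv_path: str | Path,
             sidecar_path: str | Path | None = None) -> None:
    """Write NN intervals as single-column CSV plus a JSON metadata sidecar."""
    with open(csv_path, "w") as fh:
        for value in nn.intervals:
            fh.write(f"{float(value)!r}\n")
    if sidecar_path is not None:
        meta = {
            "subject_id": nn.subject_id,
            "session": nn.session,
            "nn_rr_ratio": nn.nn_rr_ratio,
            "n_intervals": len(nn),
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")
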