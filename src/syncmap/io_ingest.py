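"""Ingest of transcripts and physiological CSV series.

Transcripts are UTF-8 plain text, optionally turn-annotated with speaker
labels at line starts. Physiological series are two-column CSV
(``time_s,value``) with a header row; timestamps must be non-decreasing,
exact duplicates are collapsed by mean, and internal NaN gaps are
linearly interpolated up to a configurable maximum gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptDoc",
    "PhysioSeries",
    "read_transcript",
    "read_physio",
    "align_channels",
    "write_physio",
]

#: Longest NaN gap (seconds) bridged by linear interpolation.
DEFAULT_MAX_GAP_S = 2.0


@dataclass
class TranscriptDoc:
    """A single speaker's transcript with optional turn boundaries."""

    speaker_id: str
    raw_text: str
    turn_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError("transcript text is empty")
        offs = self.turn_boundaries
        if any(b > a for a, b in zip(offs[1:], offs[:-1])) or any(
            o > len(self.raw_text) for o in offs
        ):
            raise ValueError("turn boundaries must be ascending and within text")

    @property
    def n_turns(self) -> int:
        return len(self.turn_boundaries)

    def turns(self) -> list[str]:
        """Slice the raw text into per-turn strings."""
        bounds = list(self.turn_boundaries) + [len(self.raw_text)]
        return [self.raw_text[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class PhysioSeries:
    """A validated physiological time series (GSR, HR, ...)."""

    subject_id: str
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size < 2:
            raise ValueError("series needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.v))):
            raise ValueError("series contains non-finite values after ingest")

    @property
    def rate_hz(self) -> float:
        """Mean sampling rate derived from the time support."""
        return (self.t.size - 1) / (self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


def read_transcript(
    path: str | Path,
    turn_regex: str | None = None,
    speaker_id: str | None = None,
) -> TranscriptDoc:
    """Read a UTF-8 transcript file.

    If ``turn_regex`` is given, every match anchored at a line start opens
    a new turn; otherwise the whole document is one turn.
    """
    path = Path(path)
    data = path.read_bytes()
    if not data:
        raise ValueError(f"empty transcript file: {path}")
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise ValueError(
            f"transcript {path} is not valid UTF-8 at byte offset {exc.start}"
        ) from exc
    if not text.strip():
        raise ValueError(f"transcript {path} contains only whitespace")

    boundaries = [0]
    if turn_regex is not None:
        pat = re.compile(turn_regex, flags=re.MULTILINE)
        starts = [m.start() for m in pat.finditer(text)]
        if starts:
            if starts[0] != 0:
                starts.insert(0, 0)
            boundaries = starts
    return TranscriptDoc(
        speaker_id=speaker_id or path.stem,
        raw_text=text,
        turn_boundaries=boundaries,
    )


def read_physio(
    path: str | Path,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    subject_id: str | None = None,
) -> PhysioSeries:
    """Read a two-column (time_s, value) CSV with header.

    Duplicate timestamps are collapsed by mean. NaN values are linearly
    interpolated when the surrounding time gap is at most ``max_gap_s``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    t = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    v = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: series needs at least 2 rows")
    if np.any(np.isnan(t)):
        raise ValueError(f"{path}: missing timestamps")
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: time column is not monotonically non-decreasing")

    # collapse exact duplicate timestamps by mean (order-preserving; time is
    # already non-decreasing so groupby-sort is a no-op)
    if np.any(np.diff(t) == 0):
        g = pd.DataFrame({"t": t, "v": v}).groupby("t", sort=True)["v"].mean()
        t = g.index.to_numpy(dtype=float)
        v = g.to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: non-monotonic time after deduplication")

    # bridge NaN gaps
    bad = ~np.isfinite(v)
    if bad.all():
        raise ValueError(f"{path}: no finite values")
    if bad.any():
        good = ~bad
        # check each contiguous NaN run's time span against max_gap_s
        runs = np.split(np.flatnonzero(bad), np.flatnonzero(np.diff(np.flatnonzero(bad)) > 1) + 1)
        for run in runs:
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= t.size:
                raise ValueError(f"{path}: NaN run at series edge cannot be interpolated")
            if t[hi] - t[lo] > max_gap_s:
                raise ValueError(
                    f"{path}: gap of {t[hi] - t[lo]:.3f}s exceeds max interpolatable "
                    f"gap {max_gap_s}s"
                )
        v = v.copy()
        v[bad] = np.interp(t[bad], t[good], v[good])

    # sampling gaps beyond the maximum are data loss, not interpolable
    dts = np.diff(t)
    if np.any(dts > max_gap_s):
        i = int(np.argmax(dts))
        raise ValueError(
            f"{path}: sampling gap of {dts[i]:.3f}s at t={t[i]:.3f} exceeds "
            f"max gap {max_gap_s}s"
        )
    return PhysioSeries(subject_id=subject_id or path.stem, t=t, v=v)


def write_physio(series: PhysioSeries, path: str | Path) -> None:
    """Write a series back to the two-column CSV interchange format."""
    pd.DataFrame({"time_s": series.t, "value": series.v}).to_csv(
        path, index=False, float_format="%.10g"
    )


def align_channels(
    a: PhysioSeries, b: PhysioSeries, rate_hz: float = 4.0
) -> tuple[PhysioSeries, PhysioSeries]:
    """Resample two series onto a common grid over their overlapping support."""
    start = max(a.t[0], b.t[0])
    end = min(a.t[-1], b.t[-1])
    if end - start <= 0:
        raise ValueError(
            f"series {a.subject_id!r} and {b.subject_id!r} have no overlapping support"
        )
    n = int(np.floor((end - start) * rate_hz + 1e-9)) + 1
    grid = start + np.arange(n) / rate_hz
    va = np.interp(grid, a.t, a.v)
    vb = np.interp(grid, b.t, b.v)
    return (
        PhysioSeries(subject_id=a.subject_id, t=grid, v=va),
        PhysioSeries(subject_id=b.subject_id, t=grid.copy(), v=vb),
    )
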