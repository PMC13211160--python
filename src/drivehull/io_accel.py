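"""Reading, validating, aligning and writing triaxial accelerometry series.

Wrist-worn and vehicle-mounted loggers export a simple delimited time series
(timestamp plus X/Y/Z acceleration in units of g).  This module normalises
those exports into :class:`AccelSeries` — a uniformly sampled trace on a
seconds-since-start time base — and provides the pairing step that puts a
wrist and a vehicle recording on a common clock.

Timestamps may be numeric seconds, a single ISO-8601 datetime column, or
separate date and time columns; all are normalised to seconds since the
first valid sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AccelIOError,
    CorruptTimelineError,
    DisjointRecordingsError,
    EmptySeriesError,
)

#: Device dynamic-range sanity bound, in g.  Samples outside are discarded.
MAX_ABS_G = 16.0

#: Tolerated relative jitter of the median inter-sample interval.
RATE_JITTER_TOL = 0.20


@dataclass(frozen=True)
class CsvDialect:
    """Column naming and delimiter of an accelerometry export."""

    delimiter: str = ","
    timestamp_col: str = "timestamp"
    date_col: str = "date"
    time_col: str = "time"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"


@dataclass
class LoadReport:
    """Accounting of a single file load: rows in, rows kept, rows dropped."""

    path: str
    n_rows_in: int
    n_rows_kept: int
    n_dropped: int
    inferred_rate_hz: float

    def __post_init__(self) -> None:
        assert self.n_rows_kept + self.n_dropped == self.n_rows_in


@dataclass
class AccelSeries:
    """A uniformly sampled triaxial acceleration trace for one device.

    Attributes
    ----------
    device_role:
        ``"wrist"`` or ``"vehicle"``.
    participant_id:
        Identifier carried through to all downstream tables.
    sample_rate_hz:
        Nominal sampling rate (10 Hz for the loggers this models).
    t:
        Sample times in seconds since recording start, strictly increasing.
    xyz:
        ``(n, 3)`` float array of accelerations in g.
    """

    device_role: str
    participant_id: str
    sample_rate_hz: float
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")

    # -- accessors ---------------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    # -- validation --------------------------------------------------------
    def validate(self) -> "AccelSeries":
        """Check the series invariants; return self for chaining."""
        if self.device_role not in ("wrist", "vehicle"):
            raise ValueError(f"unknown device_role {self.device_role!r}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_samples < 2:
            raise EmptySeriesError(
                f"series for {self.participant_id!r} has "
                f"{self.n_samples} sample(s); need at least 2"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite acceleration values")
        if np.max(np.abs(self.xyz)) >= MAX_ABS_G:
            raise ValueError(f"acceleration outside ±{MAX_ABS_G} g range")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise CorruptTimelineError("timestamps not strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        med = float(np.median(dt))
        if abs(med - nominal) > RATE_JITTER_TOL * nominal:
            raise ValueError(
                f"median interval {med:.4f}s deviates >"
                f"{RATE_JITTER_TOL:.0%} from nominal {nominal:.4f}s"
            )
        return self

    # -- manipulation ------------------------------------------------------
    def crop(self, start_s: float, end_s: float) -> "AccelSeries":
        """Sub-series with ``start_s <= t <= end_s`` (same clock)."""
        mask = (self.t >= start_s) & (self.t <= end_s)
        return dataclasses.replace(self, t=self.t[mask], xyz=self.xyz[mask])

    def with_xyz(self, xyz: np.ndarray) -> "AccelSeries":
        return dataclasses.replace(self, xyz=np.asarray(xyz, dtype=float))


@dataclass
class AlignedPair:
    """A wrist and a vehicle series on the vehicle's time base."""

    wrist: AccelSeries
    vehicle: AccelSeries
    overlap_s: float
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        assert self.wrist.n_samples == self.vehicle.n_samples


# ---------------------------------------------------------------------------
# reading


def _parse_timestamps(frame: pd.DataFrame, dialect: CsvDialect) -> pd.Series:
    """Timestamp column → float seconds (NaN where unparseable)."""
    cols = frame.columns
    if dialect.timestamp_col in cols:
        raw = frame[dialect.timestamp_col]
    elif dialect.date_col in cols and dialect.time_col in cols:
        raw = (
            frame[dialect.date_col].astype(str).str.strip()
            + " "
            + frame[dialect.time_col].astype(str).str.strip()
        )
    else:
        raise AccelIOError(
            f"no timestamp column(s) found; expected {dialect.timestamp_col!r} "
            f"or {dialect.date_col!r}+{dialect.time_col!r}, got {list(cols)}"
        )
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().any():
        return numeric.astype(float)
    stamps = pd.to_datetime(raw, errors="coerce", format="mixed")
    origin = stamps.dropna().min()
    return (stamps - origin).dt.total_seconds()


def read_accel_csv(
    path: str | Path,
    device_role: str,
    participant_id: str,
    dialect: CsvDialect | None = None,
    sample_rate_hz: float | None = None,
) -> tuple[AccelSeries, LoadReport]:
    """Read a delimited accelerometry export.

    Rows with unparseable or out-of-range values are dropped and counted in
    the returned :class:`LoadReport`.  Timestamps are sorted, normalised to
    seconds since the first sample, and must be strictly increasing after
    the sort (duplicates are a corrupt timeline).

    Parameters
    ----------
    sample_rate_hz:
        Nominal rate; inferred from the median inter-sample interval when
        omitted.

    Returns
    -------
    (series, report)
    """
    path = Path(path)
    if not path.is_file():
        raise AccelIOError(f"input file not found: {path}")
    dialect = dialect or CsvDialect()
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise AccelIOError(f"cannot parse {path}: {exc}") from exc
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    n_in = len(frame)

    t = _parse_timestamps(frame, dialect)
    axes = []
    for col in (dialect.x_col, dialect.y_col, dialect.z_col):
        if col not in frame.columns:
            raise AccelIOError(f"missing axis column {col!r} in {path}")
        axes.append(pd.to_numeric(frame[col], errors="coerce"))
    xyz = np.column_stack([a.to_numpy(dtype=float) for a in axes])

    valid = (
        np.isfinite(t.to_numpy(dtype=float))
        & np.all(np.isfinite(xyz), axis=1)
        & np.all(np.abs(xyz) < MAX_ABS_G, axis=1)
    )
    t_arr = t.to_numpy(dtype=float)[valid]
    xyz = xyz[valid]
    if len(t_arr) < 2:
        raise EmptySeriesError(
            f"{path}: only {len(t_arr)} valid row(s) after filtering"
        )

    order = np.argsort(t_arr, kind="stable")
    t_arr, xyz = t_arr[order], xyz[order]
    if np.any(np.diff(t_arr) <= 0):
        raise CorruptTimelineError(
            f"{path}: duplicate timestamps remain after sorting"
        )
    t_arr = t_arr - t_arr[0]

    rate = (
        float(sample_rate_hz)
        if sample_rate_hz
        else 1.0 / float(np.median(np.diff(t_arr)))
    )
    series = AccelSeries(
        device_role=device_role,
        participant_id=participant_id,
        sample_rate_hz=rate,
        t=t_arr,
        xyz=xyz,
    ).validate()
    report = LoadReport(
        path=str(path),
        n_rows_in=n_in,
        n_rows_kept=int(valid.sum()),
        n_dropped=int(n_in - valid.sum()),
        inferred_rate_hz=rate,
    )
    return series, report


def write_accel_csv(series: AccelSeries, path: str | Path) -> None:
    """Write ``timestamp,x,y,z`` with 6-decimal precision (round-trip safe)."""
    series.validate()
    path = Path(path)
    frame = pd.DataFrame(
        {
            "timestamp": series.t,
            "x": series.x,
            "y": series.y,
            "z": series.z,
        }
    )
    try:
        frame.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise AccelIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# alignment and gap handling


def align_pair(
    wrist: AccelSeries,
    vehicle: AccelSeries,
    offset_s: float = 0.0,
) -> AlignedPair:
    """Put a wrist/vehicle pair on the vehicle's time grid.

    ``offset_s`` is added to the wrist clock (a single constant correction;
    device clocks are otherwise assumed synchronised).  Both series are
    cropped to their overlapping span and the wrist signal is resampled to
    the vehicle timestamps by nearest neighbour; vehicle samples with no
    wrist sample within half a sample period are dropped and counted.
    """
    wt = wrist.t + offset_s
    lo = max(wt[0], vehicle.t[0])
    hi = min(wt[-1], vehicle.t[-1])
    if hi <= lo:
        raise DisjointRecordingsError(
            f"no overlap: wrist [{wt[0]:.1f}, {wt[-1]:.1f}]s vs "
            f"vehicle [{vehicle.t[0]:.1f}, {vehicle.t[-1]:.1f}]s"
        )
    # lenient crop by half a sample period: a vehicle sample just outside
    # the nominal overlap still has a wrist neighbour within tolerance
    half = 0.5 / vehicle.sample_rate_hz
    veh = vehicle.crop(lo - half, hi + half)

    # nearest wrist sample for every vehicle timestamp
    idx = np.searchsorted(wt, veh.t)
    idx = np.clip(idx, 1, len(wt) - 1)
    left, right = wt[idx - 1], wt[idx]
    use_left = (veh.t - left) <= (right - veh.t)
    nearest = np.where(use_left, idx - 1, idx)
    dist = np.abs(wt[nearest] - veh.t)
    ok = dist <= 0.5 / vehicle.sample_rate_hz

    n_unmatched = int((~ok).sum())
    veh = dataclasses.replace(veh, t=veh.t[ok], xyz=veh.xyz[ok])
    wr = dataclasses.replace(
        wrist, t=veh.t.copy(), xyz=wrist.xyz[nearest[ok]]
    )
    overlap = float(veh.t[-1] - veh.t[0]) if veh.n_samples else 0.0
    return AlignedPair(wrist=wr, vehicle=veh, overlap_s=overlap,
                       n_unmatched=n_unmatched)


def split_on_gaps(series: AccelSeries, max_gap_s: float = 1.0) -> list[AccelSeries]:
    """Split a series into contiguous blocks wherever a gap exceeds ``max_gap_s``."""
    breaks = np.flatnonzero(np.diff(series.t) > max_gap_s)
    if len(breaks) == 0:
        return [series]
    blocks = []
    start = 0
    for b in list(breaks + 1) + [series.n_samples]:
        if b - start >= 2:
            blocks.append(
                dataclasses.replace(
                    series, t=series.t[start:b], xyz=series.xyz[start:b]
                )
            )
        start = b
    return blocks
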