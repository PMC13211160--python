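"""Detection of active driving periods from a vehicle-mounted accelerometer.

The vehicle signal is gravity-detrended (per-axis median removal), an
amplitude envelope of the longitudinal axis is computed as the smoothed
modulus of the analytic signal (Hilbert transform), and sustained
supra-threshold envelope runs become candidate drive segments.  Candidates
are then screened against naturalistic-driving event criteria: a segment is
retained as active driving if it contains a longitudinal acceleration event
>= 0.35 g, a longitudinal deceleration event >= 0.45 g, or a lateral event
with |a| >= 0.5 g.  Wrist sub-series matched in time to the retained
segments feed the movement-volume analysis.

Axis convention (configurable): longitudinal = x (fore/aft), lateral = y
(left/right), vertical = z (up/down; carries gravity, ~ -1 g when the
logger sits flat in the vehicle).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import SegmentMismatchError, SeriesTooShortError
from .io_accel import AccelSeries

AXIS_INDEX = {"longitudinal": 0, "lateral": 1, "vertical": 2}


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of drive detection.

    The three event thresholds (0.35 g acceleration, 0.45 g deceleration,
    0.5 g lateral) follow established naturalistic-driving criteria.  The
    envelope activity threshold, minimum duration and merge gap control the
    run-detection stage and are deployment tunables.
    """

    envelope_smooth_window_s: float = 5.0
    activity_envelope_threshold_g: float = 0.03
    min_drive_duration_s: float = 60.0
    merge_gap_s: float = 30.0
    long_accel_threshold_g: float = 0.35
    long_decel_threshold_g: float = 0.45
    lateral_threshold_g: float = 0.5
    #: axis remap for non-standard mountings: (longitudinal, lateral, vertical)
    axis_map: tuple[int, int, int] = (0, 1, 2)
    #: alternative reading of the event criteria: keep every active period
    #: and merely annotate event peaks.
    retain_all_active: bool = False

    def __post_init__(self) -> None:
        for name in (
            "envelope_smooth_window_s",
            "activity_envelope_threshold_g",
            "min_drive_duration_s",
            "long_accel_threshold_g",
            "long_decel_threshold_g",
            "lateral_threshold_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_gap_s < 0:
            raise ValueError("merge_gap_s must be non-negative")
        if self.merge_gap_s >= self.min_drive_duration_s:
            raise ValueError("merge_gap_s must be < min_drive_duration_s")
        if sorted(self.axis_map) != [0, 1, 2]:
            raise ValueError("axis_map must be a permutation of (0, 1, 2)")


@dataclass
class EnvelopeSeries:
    """Non-negative amplitude envelope of one axis of a series."""

    t: np.ndarray
    value: np.ndarray
    source_axis: str

    def __post_init__(self) -> None:
        assert len(self.t) == len(self.value)


@dataclass
class DriveSegment:
    """One candidate/confirmed drive interval with its event peak magnitudes."""

    participant_id: str
    drive_id: int
    start_s: float
    end_s: float
    peak_long_accel_g: float = float("nan")
    peak_long_decel_g: float = float("nan")
    peak_lateral_abs_g: float = float("nan")
    retained: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detrend_gravity(vehicle: AccelSeries) -> tuple[AccelSeries, np.ndarray]:
    """Remove the static gravity component from each axis.

    The per-axis median over the whole recording is subtracted, so a
    stationary logger reads ~(0, 0, 0) afterwards.  The median is used
    rather than the mean because drive episodes are a minority of the
    recording and event pulses are one-sided.

    Returns the detrended series and the removed per-axis offsets (g).
    """
    offsets = np.median(vehicle.xyz, axis=0)
    return vehicle.with_xyz(vehicle.xyz - offsets), offsets


def _axis_signal(series: AccelSeries, axis: str, config: DetectionConfig) -> np.ndarray:
    if axis == "magnitude":
        return np.linalg.norm(series.xyz, axis=1)
    try:
        mapped = config.axis_map[AXIS_INDEX[axis]]
    except KeyError:
        raise ValueError(
            f"axis must be one of {list(AXIS_INDEX)} or 'magnitude', got {axis!r}"
        ) from None
    return series.xyz[:, mapped]


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if width <= 1:
        return values.astype(float, copy=True)
    kernel = np.ones(width)
    return np.convolve(values, kernel, mode="same") / np.convolve(
        np.ones_like(values), kernel, mode="same"
    )


def compute_envelope(
    series: AccelSeries,
    axis: str = "longitudinal",
    config: DetectionConfig | None = None,
) -> EnvelopeSeries:
    """Smoothed Hilbert envelope of one axis of a (detrended) series.

    The envelope is the modulus of the analytic signal, then smoothed by a
    centred moving average of ``envelope_smooth_window_s``.  Pass a config
    with window 0 to obtain the raw analytic-signal modulus.
    """
    config = config or DetectionConfig()
    width = int(round(config.envelope_smooth_window_s * series.sample_rate_hz))
    if series.n_samples < max(width, 2):
        raise SeriesTooShortError(
            f"{series.n_samples} samples < smoothing window of {width}"
        )
    signal = _axis_signal(series, axis, config)
    env = np.abs(hilbert(signal))
    env = moving_average(env, width)
    return EnvelopeSeries(t=series.t, value=env, source_axis=axis)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_active_periods(
    envelope: EnvelopeSeries,
    config: DetectionConfig | None = None,
    participant_id: str = "",
) -> list[DriveSegment]:
    """Candidate drive segments from supra-threshold envelope runs.

    Maximal runs with envelope above ``activity_envelope_threshold_g`` are
    found, runs separated by gaps <= ``merge_gap_s`` are merged, and merged
    runs shorter than ``min_drive_duration_s`` are discarded.  Returned
    segments are disjoint, time-ordered, and have the retained flag unset.
    """
    config = config or DetectionConfig()
    runs = _runs_above(envelope.value > config.activity_envelope_threshold_g)
    t = envelope.t
    intervals = [(t[a], t[b - 1]) for a, b in runs]

    merged: list[list[float]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] <= config.merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    segments = [
        DriveSegment(
            participant_id=participant_id,
            drive_id=i,
            start_s=float(a),
            end_s=float(b),
        )
        for i, (a, b) in enumerate(
            (a, b) for a, b in merged if b - a >= config.min_drive_duration_s
        )
    ]
    return segments


def apply_event_criteria(
    vehicle: AccelSeries,
    segments: list[DriveSegment],
    config: DetectionConfig | None = None,
) -> list[DriveSegment]:
    """Fill event peak magnitudes and set the retained flag per segment.

    ``vehicle`` must be the gravity-detrended series.  Peaks: acceleration =
    max(+longitudinal), deceleration = max(-longitudinal), lateral =
    max(|lateral|), each clipped at 0.  A segment is retained iff any peak
    meets its threshold (OR of the three); with ``retain_all_active`` every
    segment is retained and peaks are annotations only.  Boundaries are
    never modified.
    """
    config = config or DetectionConfig()
    long_sig = _axis_signal(vehicle, "longitudinal", config)
    lat_sig = _axis_signal(vehicle, "lateral", config)
    out = []
    for seg in segments:
        if seg.start_s < vehicle.t[0] - 1e-9 or seg.end_s > vehicle.t[-1] + 1e-9:
            raise SegmentMismatchError(
                f"segment [{seg.start_s}, {seg.end_s}]s outside series "
                f"range [{vehicle.t[0]}, {vehicle.t[-1]}]s"
            )
        mask = (vehicle.t >= seg.start_s) & (vehicle.t <= seg.end_s)
        if not mask.any():
            raise SegmentMismatchError(
                f"segment [{seg.start_s}, {seg.end_s}]s contains no samples"
            )
        accel = max(float(np.max(long_sig[mask])), 0.0)
        decel = max(float(np.max(-long_sig[mask])), 0.0)
        lateral = float(np.max(np.abs(lat_sig[mask])))
        retained = config.retain_all_active or (
            accel >= config.long_accel_threshold_g
            or decel >= config.long_decel_threshold_g
            or lateral >= config.lateral_threshold_g
        )
        out.append(
            dataclasses.replace(
                seg,
                peak_long_accel_g=accel,
                peak_long_decel_g=decel,
                peak_lateral_abs_g=lateral,
                retained=retained,
            )
        )
    return out


def extract_wrist_segments(
    wrist: AccelSeries,
    segments: list[DriveSegment],
) -> tuple[list[AccelSeries], list[DriveSegment]]:
    """Wrist sub-series for each retained segment (aligned pair assumed).

    Returns the list of wrist sub-series and the retained segments they
    correspond to.  Retained segments with no overlapping wrist samples are
    skipped (and absent from the second list).
    """
    out_series, out_segments = [], []
    for seg in segments:
        if not seg.retained:
            continue
        sub = wrist.crop(seg.start_s, seg.end_s)
        if sub.n_samples == 0:
            continue
        out_series.append(sub)
        out_segments.append(seg)
    return out_series, out_segments


def detect_drives(
    vehicle: AccelSeries,
    config: DetectionConfig | None = None,
) -> tuple[list[DriveSegment], AccelSeries, np.ndarray]:
    """Convenience chain: detrend → envelope → runs → event criteria.

    Returns (segments with peaks and retained flags, detrended vehicle
    series, removed gravity offsets).
    """
    config = config or DetectionConfig()
    detrended, offsets = detrend_gravity(vehicle)
    envelope = compute_envelope(detrended, "longitudinal", config)
    candidates = detect_active_periods(
        envelope, config, participant_id=vehicle.participant_id
    )
    segments = apply_event_criteria(detrended, candidates, config)
    return segments, detrended, offsets
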