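"""Convex-hull volumes of 3-D acceleration point clouds.

Each driving period yields a cloud of (x, y, z) acceleration samples; the
volume of its convex hull — the smallest polyhedron enclosing every sample —
summarises the spatial envelope the signal explored, in units of g^3.
An optional per-axis centile trim (default 1st–99th) excludes extreme
outlier points before hull construction.  Gravity is deliberately left in
the coordinates: the hull is computed on raw trimmed accelerations for both
devices, so a stationary vehicle cloud sits near (0, 0, -1) with volume
close to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import NoDrivesError, NoPointsError

#: Relative singular-value tolerance below which a cloud counts as
#: affinely degenerate (collinear/coplanar) and gets volume 0.
DEGENERACY_TOL = 1e-12


@dataclass(frozen=True)
class TrimConfig:
    """Per-axis centile window applied before hull construction."""

    lower_centile: float = 1.0
    upper_centile: float = 99.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.lower_centile < 50):
            raise ValueError("lower_centile must be in [0, 50)")
        if not (50 < self.upper_centile <= 100):
            raise ValueError("upper_centile must be in (50, 100]")


@dataclass
class HullResult:
    """Convex-hull volume of one point cloud.

    ``degenerate`` marks clouds with fewer than four affinely independent
    points; their 3-D volume is 0 by convention so that stationary periods
    remain representable.
    """

    volume_g3: float
    n_points_in: int
    n_points_after_trim: int
    n_hull_vertices: int
    degenerate: bool
    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        assert self.volume_g3 >= 0
        assert self.degenerate == (self.volume_g3 == 0.0)


@dataclass
class ParticipantVolume:
    """Wrist and vehicle movement volumes for one participant."""

    participant_id: str
    wrist_volume_g3: float
    vehicle_volume_g3: float
    n_drives: int
    per_drive_volumes: list[tuple[int, float, float]]
    aggregation: str

    def __post_init__(self) -> None:
        assert self.n_drives == len(self.per_drive_volumes)


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    return pts


def trim_centiles(points: np.ndarray, config: TrimConfig | None = None) -> np.ndarray:
    """Keep points whose every coordinate lies within its axis centile window.

    Centiles are computed on the input cloud per axis with linear
    interpolation between order statistics.  Disabled configs return the
    input unchanged.
    """
    config = config or TrimConfig()
    pts = _as_points(points)
    if len(pts) == 0:
        raise NoPointsError("cannot trim an empty cloud")
    if not config.enabled:
        return pts
    lo = np.percentile(pts, config.lower_centile, axis=0)
    hi = np.percentile(pts, config.upper_centile, axis=0)
    keep = np.all((pts >= lo) & (pts <= hi), axis=1)
    return pts[keep]


def _is_degenerate(pts: np.ndarray) -> bool:
    if len(pts) < 4:
        return True
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    return bool(sv[-1] <= DEGENERACY_TOL * max(sv[0], 1.0))


def hull_volume(points: np.ndarray, keep_vertices: bool = True) -> HullResult:
    """Volume of the convex hull of a 3-D cloud (Qhull).

    Clouds with fewer than four points, or affinely degenerate within
    tolerance, get volume 0 and ``degenerate=True`` rather than an error.
    """
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        raise NoPointsError("hull of an empty cloud is undefined")
    if _is_degenerate(pts):
        return HullResult(
            volume_g3=0.0,
            n_points_in=n,
            n_points_after_trim=n,
            n_hull_vertices=0,
            degenerate=True,
        )
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return HullResult(
            volume_g3=0.0,
            n_points_in=n,
            n_points_after_trim=n,
            n_hull_vertices=0,
            degenerate=True,
        )
    return HullResult(
        volume_g3=float(hull.volume),
        n_points_in=n,
        n_points_after_trim=n,
        n_hull_vertices=len(hull.vertices),
        degenerate=False,
        vertices=pts[hull.vertices] if keep_vertices else None,
    )


def hull_evolution(
    points: np.ndarray,
    n_slices: int,
    t: np.ndarray | None = None,
) -> list[HullResult]:
    """Cumulative hull volumes over ``n_slices`` equal spans of a drive.

    Result ``k`` is the hull of all points from the start through the end of
    slice ``k``; volumes are therefore non-decreasing and the last equals
    the full-drive volume.  Spans are equal in time when ``t`` is given,
    equal in point count otherwise (identical on a uniform sampling grid).
    """
    pts = _as_points(points)
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if len(pts) == 0:
        raise NoPointsError("hull evolution of an empty cloud is undefined")
    if t is not None:
        t = np.asarray(t, dtype=float)
        bounds = np.linspace(t[0], t[-1], n_slices + 1)[1:]
        ends = [int(np.searchsorted(t, b, side="right")) for b in bounds]
    else:
        ends = [
            int(round(len(pts) * (k + 1) / n_slices)) for k in range(n_slices)
        ]
    ends[-1] = len(pts)
    return [hull_volume(pts[: max(e, 1)], keep_vertices=False) for e in ends]


def participant_volume(
    participant_id: str,
    wrist_clouds: list[np.ndarray],
    vehicle_clouds: list[np.ndarray],
    drive_ids: list[int] | None = None,
    aggregation: str = "pooled",
    trim: TrimConfig | None = None,
) -> ParticipantVolume:
    """Per-participant movement volume from drive-matched wrist/vehicle clouds.

    Each drive's cloud is centile-trimmed independently, then:

    - ``pooled`` (default): the participant's volume is the hull of the
      union of all trimmed drive clouds — the overall envelope explored
      across every retained drive;
    - ``mean_per_drive``: the arithmetic mean of per-drive hull volumes.
    """
    if len(wrist_clouds) != len(vehicle_clouds):
        raise ValueError("wrist and vehicle drive lists must be drive-matched")
    if len(wrist_clouds) == 0:
        raise NoDrivesError(f"participant {participant_id!r} has no drives")
    if aggregation not in ("pooled", "mean_per_drive"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    trim = trim or TrimConfig()
    drive_ids = drive_ids if drive_ids is not None else list(range(len(wrist_clouds)))

    trimmed_w = [trim_centiles(c, trim) for c in wrist_clouds]
    trimmed_v = [trim_centiles(c, trim) for c in vehicle_clouds]
    per_drive = [
        (
            int(d),
            hull_volume(w, keep_vertices=False).volume_g3,
            hull_volume(v, keep_vertices=False).volume_g3,
        )
        for d, w, v in zip(drive_ids, trimmed_w, trimmed_v)
    ]
    if aggregation == "pooled":
        wrist_vol = hull_volume(np.vstack(trimmed_w), keep_vertices=False).volume_g3
        vehicle_vol = hull_volume(np.vstack(trimmed_v), keep_vertices=False).volume_g3
    else:
        wrist_vol = float(np.mean([v[1] for v in per_drive]))
        vehicle_vol = float(np.mean([v[2] for v in per_drive]))
    return ParticipantVolume(
        participant_id=participant_id,
        wrist_volume_g3=wrist_vol,
        vehicle_volume_g3=vehicle_vol,
        n_drives=len(per_drive),
        per_drive_volumes=per_drive,
        aggregation=aggregation,
    )
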