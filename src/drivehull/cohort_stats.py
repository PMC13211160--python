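"""Cohort descriptive statistics, outlier flagging and normality diagnostics.

Movement volumes across a cohort are typically right-skewed: most drivers
occupy a consistent mid-range with a small subset of much larger envelopes.
This module produces the descriptive summary (mean, median, SD, quartiles,
IQR), flags atypically high volumes with the Tukey upper fence
Q3 + 1.5*IQR, tests normality (Shapiro–Wilk, sample skewness), and compares
raw against log10-transformed summaries — a monotone transform, so the
participant ranking is unchanged by construction and is asserted.

Conventions: quartiles use linear interpolation between order statistics;
SD is the sample (n-1) estimate; skewness is the adjusted Fisher–Pearson
sample coefficient.  Only the upper fence is computed — low movement is not
an outlier condition here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientCohortError, NonPositiveVolumeError

#: Tukey fence multiplier.
IQR_FENCE = 1.5

#: Shapiro–Wilk sample-size validity range.
SHAPIRO_N_RANGE = (4, 5000)


@dataclass
class CohortSummary:
    """Descriptive statistics of one device role's cohort volumes."""

    device_role: str
    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    q1: float
    q3: float
    iqr: float
    upper_outlier_threshold: float
    n_outliers: int
    pct_outliers: float
    skewness: float
    shapiro_w: float
    shapiro_p: float
    transform: str = "raw"

    def __post_init__(self) -> None:
        assert self.min <= self.q1 <= self.median <= self.q3 <= self.max
        assert math.isclose(self.iqr, self.q3 - self.q1, abs_tol=1e-9)
        assert 0.0 <= self.pct_outliers <= 100.0


def _check_n(n: int) -> None:
    if n < 4:
        raise InsufficientCohortError(f"need at least 4 values, got {n}")


def summarize(
    volumes: np.ndarray,
    device_role: str = "wrist",
    transform: str = "raw",
) -> CohortSummary:
    """Full descriptive summary of a cohort of movement volumes.

    The upper outlier threshold is Q3 + 1.5*IQR; ``n_outliers`` counts
    strictly greater values and ``pct_outliers`` is reported in percent.
    """
    values = np.asarray(volumes, dtype=float)
    _check_n(len(values))
    if not np.all(np.isfinite(values)):
        raise ValueError("volumes must be finite")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    fence = q3 + IQR_FENCE * iqr
    n_out = int(np.sum(values > fence))
    skew, w, p = normality_report(values)
    return CohortSummary(
        device_role=device_role,
        n=len(values),
        mean=float(np.mean(values)),
        median=float(med),
        sd=float(np.std(values, ddof=1)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        upper_outlier_threshold=float(fence),
        n_outliers=n_out,
        pct_outliers=round(100.0 * n_out / len(values), 2),
        skewness=skew,
        shapiro_w=w,
        shapiro_p=p,
        transform=transform,
    )


def flag_outliers(
    volumes: list[tuple[str, float]],
    summary: CohortSummary,
) -> list[tuple[str, bool]]:
    """Flag participants whose volume exceeds the summary's upper fence.

    Only the upper tail is flagged (atypically *high* movement); a value
    exactly on the fence is not an outlier.
    """
    return [
        (pid, bool(vol > summary.upper_outlier_threshold))
        for pid, vol in volumes
    ]


def normality_report(volumes: np.ndarray) -> tuple[float, float, float]:
    """(skewness, Shapiro–Wilk W, Shapiro–Wilk p) for a cohort.

    Constant input is degenerate for both statistics: skewness is reported
    as 0.0 and the Shapiro–Wilk pair as NaN.
    """
    values = np.asarray(volumes, dtype=float)
    lo, hi = SHAPIRO_N_RANGE
    if not lo <= len(values) <= hi:
        raise InsufficientCohortError(
            f"normality diagnostics need {lo} <= n <= {hi}, got {len(values)}"
        )
    if np.ptp(values) == 0.0:
        return 0.0, float("nan"), float("nan")
    skew = float(stats.skew(values, bias=False))
    w, p = stats.shapiro(values)
    return skew, float(w), float(p)


def log10_compare(
    volumes: np.ndarray,
    device_role: str = "wrist",
) -> tuple[CohortSummary, CohortSummary]:
    """Raw vs log10 summaries of the same cohort.

    Requires strictly positive volumes.  As a guard against upstream
    pairing mistakes the participant rank order under the two scales is
    asserted identical (log10 is strictly monotone).
    """
    values = np.asarray(volumes, dtype=float)
    if np.any(values <= 0):
        raise NonPositiveVolumeError("log10 requires strictly positive volumes")
    raw = summarize(values, device_role, transform="raw")
    logged = summarize(np.log10(values), device_role, transform="log10")
    if np.ptp(values) > 0:
        rho = stats.spearmanr(values, np.log10(values)).statistic
        assert math.isclose(float(rho), 1.0), "monotone transform changed ranking"
    return raw, logged


def histogram_export(
    volumes: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_edges, counts) for plotting the cohort volume distribution."""
    values = np.asarray(volumes, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts
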