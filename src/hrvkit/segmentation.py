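"""Selection of analyzable RR segments and ectopic-beat handling.

A segment qualifies for analysis when it is stationary (no significant
linear trend of practical size) and contains at least ``min_intervals``
usable intervals after ectopic masking.  Ectopic intervals are those
deviating from the candidate window's mean by more than ``outlier_sd``
standard deviations; they are removed for time-domain and nonlinear
metrics and replaced with 0 for spectral analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import RRSeries

logger = logging.getLogger(__name__)

CLEANING_MODES = ("remove", "zero_replace", "none")


@dataclass
class SegmentCriteria:
    """Selection thresholds for analyzable RR segments.

    min_intervals : minimum usable intervals per segment (spectral
        stage consumes exactly this many; default 2048).
    outlier_sd : ectopic threshold in SD multiples (default 2.0).
    stationarity_alpha : significance level of the trend-slope test.
    max_relative_drift : largest tolerated fitted drift over the
        segment, as a fraction of the mean RR.
    """

    min_intervals: int = 2048
    outlier_sd: float = 2.0
    stationarity_alpha: float = 0.05
    max_relative_drift: float = 0.05

    def __post_init__(self) -> None:
        if self.min_intervals < 16:
            raise ValueError("min_intervals must be >= 16")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if not 0 < self.stationarity_alpha < 1:
            raise ValueError("stationarity_alpha must be in (0, 1)")


@dataclass
class StationarityResult:
    passed: bool
    slope: float          # ms per beat
    p_value: float
    drift_fraction: float  # |slope|*(n-1) / mean(rr)


@dataclass
class CleanSegment:
    """A selected RR window with its ectopic mask and cleaning applied.

    ``rr`` holds the post-cleaning intervals: with ``mode="remove"`` the
    masked positions are gone; with ``mode="zero_replace"`` they hold
    exactly 0; with ``mode="none"`` the raw window.  ``ectopic_mask``
    always refers to the raw window.
    """

    rr: np.ndarray
    ectopic_mask: np.ndarray
    cleaning_mode: str
    criteria: SegmentCriteria
    provenance: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.ectopic_mask = np.asarray(self.ectopic_mask, dtype=bool)
        if self.cleaning_mode not in CLEANING_MODES:
            raise ValueError(f"unknown cleaning mode {self.cleaning_mode!r}")

    def __len__(self) -> int:
        return self.rr.size


def detect_ectopics(rr: np.ndarray | RRSeries, k: float = 2.0) -> np.ndarray:
    """Flag intervals deviating more than ``k`` SD from the window mean.

    Statistics are computed once over the whole candidate window (no
    re-estimation after removal); sample SD (n-1).  A constant series
    (SD = 0) yields an all-false mask.
    """
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals to detect ectopics")
    if k <= 0:
        raise ValueError("k must be > 0")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd <= 1e-12 * max(abs(mu), 1.0):  # constant up to float rounding
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - mu) > k * sd


def assess_stationarity(
    rr: np.ndarray | RRSeries, criteria: SegmentCriteria | None = None
) -> StationarityResult:
    """Linear-trend stationarity check.

    Fits RR against beat index by least squares.  The window fails only
    when the slope is statistically significant at
    ``stationarity_alpha`` AND the fitted drift across the window
    exceeds ``max_relative_drift`` of the mean RR — a trend must be both
    detectable and practically large to disqualify a window.
    """
    criteria = criteria or SegmentCriteria()
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 intervals to assess stationarity")
    idx = np.arange(x.size, dtype=float)
    if np.ptp(x) == 0:
        return StationarityResult(True, 0.0, 1.0, 0.0)
    fit = sps.linregress(idx, x)
    drift = abs(fit.slope) * (x.size - 1) / x.mean()
    significant = fit.pvalue < criteria.stationarity_alpha
    failed = significant and drift > criteria.max_relative_drift
    return StationarityResult(not failed, float(fit.slope), float(fit.pvalue), float(drift))


def clean_window(
    window: np.ndarray,
    mask: np.ndarray,
    mode: str,
    n_keep: int,
) -> np.ndarray | None:
    """Apply a cleaning mode and truncate to the required length.

    remove: drop masked intervals, keep the first ``n_keep`` clean ones.
    zero_replace: zero the masked positions, keep the first ``n_keep``
    positions (zeros included) — the spectral stage consumes a
    fixed-length vector.  none: first ``n_keep`` raw positions.
    """
    if mode == "remove":
        clean = window[~mask]
        return clean[:n_keep] if clean.size >= n_keep else None
    if mode == "zero_replace":
        out = window.copy()
        out[mask] = 0.0
        return out[:n_keep] if out.size >= n_keep else None
    if mode == "none":
        return window[:n_keep] if window.size >= n_keep else None
    raise ValueError(f"unknown cleaning mode {mode!r}")


def select_segments(
    rr: RRSeries,
    criteria: SegmentCriteria | None = None,
    mode: str = "remove",
    window_size: int | None = None,
) -> list[CleanSegment]:
    """Scan non-overlapping candidate windows left-to-right and keep the
    stationary ones with enough usable intervals.

    Candidate windows are ``window_size`` raw intervals long (default:
    ``criteria.min_intervals``).  A window is kept when it passes the
    stationarity check and holds at least ``min_intervals`` non-ectopic
    intervals; kept windows are truncated so every segment carries the
    same analysis length (see :func:`clean_window`).  Rejected windows
    are logged with the reason.
    """
    criteria = criteria or SegmentCriteria()
    if mode not in CLEANING_MODES:
        raise ValueError(f"unknown cleaning mode {mode!r}")
    w = window_size or criteria.min_intervals
    if w < criteria.min_intervals:
        raise ValueError("window_size must be >= min_intervals")
    x = rr.rr
    if x.size < criteria.min_intervals:
        raise ValueError(
            f"series has {x.size} intervals; need >= {criteria.min_intervals}"
        )
    segments: list[CleanSegment] = []
    for start in range(0, x.size - w + 1, w):
        window = x[start : start + w]
        stat = assess_stationarity(window, criteria)
        if not stat.passed:
            logger.info(
                "window %d-%d rejected: trend slope %.4g ms/beat (p=%.3g, drift %.1f%%)",
                start, start + w, stat.slope, stat.p_value, 100 * stat.drift_fraction,
            )
            continue
        mask = detect_ectopics(window, criteria.outlier_sd)
        n_clean = int((~mask).sum())
        if n_clean < criteria.min_intervals:
            logger.info(
                "window %d-%d rejected: %d clean intervals < %d required",
                start, start + w, n_clean, criteria.min_intervals,
            )
            continue
        cleaned = clean_window(window, mask, mode, criteria.min_intervals)
        if cleaned is None:  # pragma: no cover - guarded by n_clean test
            continue
        segments.append(
            CleanSegment(
                rr=cleaned,
                ectopic_mask=mask,
                cleaning_mode=mode,
                criteria=criteria,
                provenance=f"{rr.animal_id}/{rr.condition}",
                offset=start,
            )
        )
    return segments
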