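"""RR-interval preprocessing and short-term HRV metrics.

The pipeline mirrors common HRV practice: artifact beats are detected against
a local median and replaced by spline interpolation; the series is detrended
with the smoothness-priors estimator (a regularized time-varying high-pass,
lambda = 500 by default); RMSSD is computed on the detrended series while the
mean RR interval is taken from the corrected, un-detrended series (the
detrended series is zero-mean, so its mean carries no information).

RMSSD = sqrt( 1/(N-1) * sum_{n=1}^{N-1} (RR_{n+1} - RR_n)^2 )   [ms]
ChangeRate = Post / Pre * 100                                   [percent]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.sparse.linalg import spsolve

__all__ = ["RRSeries", "HRVMetrics", "detrend_smoothness_priors",
           "correct_artifacts_medium", "rmssd", "change_rate", "hrv_pipeline"]

MEDIUM_THRESHOLD_S = 0.25   # Kubios "medium" preset deviation threshold
MEDIUM_WINDOW = 11          # beats in the local-median window
QUALITY_WARN_FRACTION = 0.05


@dataclass
class RRSeries:
    """RR intervals in ms with cumulative time stamps in s.

    ``split_time_s`` separates the pre phase (baseline, 15 min) from the post
    phase (30 min after the stimulus).
    """

    intervals: np.ndarray
    split_time_s: float = 900.0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size < 2:
            raise ValueError("RR series needs at least 2 intervals")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def times(self) -> np.ndarray:
        """Cumulative beat times in seconds (strictly increasing)."""
        return np.cumsum(self.intervals) / 1000.0

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(pre, post) interval arrays split at ``split_time_s``."""
        t = self.times
        pre = self.intervals[t <= self.split_time_s]
        post = self.intervals[t > self.split_time_s]
        return pre, post


@dataclass
class HRVMetrics:
    mean_rr: float           # ms
    rmssd: float             # ms
    phase: str               # "pre" or "post"
    n_corrected: int = 0
    quality_warning: bool = False


def detrend_smoothness_priors(intervals: np.ndarray, lam: float = 500.0) -> np.ndarray:
    """Smoothness-priors detrending of an RR series.

    Returns ``z - (I + lam^2 D2' D2)^-1 z`` where D2 is the second-difference
    operator — the trend is the ridge-regularized smooth component, and the
    residual is the detrended (near zero-mean) series.
    """
    z = np.asarray(intervals, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("detrending needs at least 3 intervals")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    d2 = sparse.diags_array([np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
                            offsets=[0, 1, 2], shape=(n - 2, n), format="csc")
    a = sparse.eye_array(n, format="csc") + lam ** 2 * (d2.T @ d2)
    trend = spsolve(a, z)
    return z - trend


def correct_artifacts_medium(intervals: np.ndarray,
                             threshold_s: float = MEDIUM_THRESHOLD_S,
                             window: int = MEDIUM_WINDOW
                             ) -> tuple[np.ndarray, int, bool]:
    """Median-based artifact correction (the "medium" filter preset).

    A beat deviating from the local ``window``-beat median by more than
    ``threshold_s`` is replaced by cubic-spline interpolation over the
    surrounding accepted beats.  Returns (corrected, n_corrected, warn) where
    ``warn`` flags runs with more than 5% of beats corrected.
    """
    z = np.asarray(intervals, dtype=float)
    if z.size < 5:
        raise ValueError("artifact correction needs at least 5 intervals")
    local_med = median_filter(z, size=window, mode="nearest")
    bad = np.abs(z - local_med) > threshold_s * 1000.0
    n_bad = int(bad.sum())
    warn = n_bad > QUALITY_WARN_FRACTION * z.size
    if n_bad == 0:
        return z.copy(), 0, warn
    good = ~bad
    out = z.copy()
    if good.sum() >= 2:
        idx = np.arange(z.size)
        if good.sum() >= 4:
            spl = CubicSpline(idx[good], z[good])
            out[bad] = spl(idx[bad])
        else:
            out[bad] = np.interp(idx[bad], idx[good], z[good])
    else:
        out[bad] = local_med[bad]
    return out, n_bad, warn


def rmssd(intervals: np.ndarray) -> float:
    """Root mean square of successive RR differences, in ms."""
    z = np.asarray(intervals, dtype=float)
    if z.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(z)
    return float(np.sqrt(np.sum(d ** 2) / (z.size - 1)))


def change_rate(pre_value: float, post_value: float) -> tuple[float, bool]:
    """Post/Pre * 100 in percent; (nan, False) when the pre value is zero."""
    if pre_value == 0:
        return float("nan"), False
    return post_value / pre_value * 100.0, True


def hrv_pipeline(rr: RRSeries, lam: float = 500.0,
                 detrend_for_rmssd: bool = True,
                 threshold_s: float = MEDIUM_THRESHOLD_S,
                 window: int = MEDIUM_WINDOW) -> dict:
    """Full per-subject HRV analysis.

    Per phase: artifact correction, then mean RR on the corrected intervals
    and RMSSD on the (optionally) detrended corrected intervals; finally the
    post/pre change rates in percent.
    """
    metrics = {}
    for phase, chunk in zip(("pre", "post"), rr.split()):
        if chunk.size < 5:
            raise ValueError(f"{phase} phase has too few beats ({chunk.size})")
        corrected, n_corr, warn = correct_artifacts_medium(chunk, threshold_s, window)
        series_for_rmssd = (detrend_smoothness_priors(corrected, lam)
                            if detrend_for_rmssd else corrected)
        metrics[phase] = HRVMetrics(mean_rr=float(corrected.mean()),
                                    rmssd=rmssd(series_for_rmssd),
                                    phase=phase, n_corrected=n_corr,
                                    quality_warning=warn)
    cr_rr, ok_rr = change_rate(metrics["pre"].mean_rr, metrics["post"].mean_rr)
    cr_rm, ok_rm = change_rate(metrics["pre"].rmssd, metrics["post"].rmssd)
    return {
        "pre": metrics["pre"],
        "post": metrics["post"],
        "change_rate_mean_rr": cr_rr,
        "change_rate_rmssd": cr_rm,
        "change_rates_defined": bool(ok_rr and ok_rm),
    }
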