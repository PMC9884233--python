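"""The laterality-index statistic for bilateral perfusion.

The index compares the mean absolute left-right perfusion difference after a
stimulus with the same quantity before it::

    LI = mean(|Post_L - Post_R|) / mean(|Pre_L - Pre_R|) * 100

100 means the left-right asymmetry is unchanged; values above 100 mean the
asymmetry grew after the stimulus.  The index is unsigned by construction
(it does not say which side changed).

It is computed per 10-min post window, on the raw perfusion samples and on
each wavelet band component.  In band mode the "mean" collapses to a single
absolute difference of scalar band values per window; a time-resolved
alternative differences the band-averaged amplitude series sample-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import wavelet_bands as wb
from .signal_io import BilateralSession, segment_windows

__all__ = ["LateralityResult", "laterality_index", "laterality_by_window",
           "laterality_full_span", "RAW_CHANNEL"]

RAW_CHANNEL = "raw"


@dataclass
class LateralityResult:
    subject_id: str
    group: str
    window: str            # Post1 / Post2 / Post3 (or "Post" for full span)
    channel: str           # "raw" or a band id
    index: float           # percent; NaN when undefined
    defined: bool = True
    reliable: bool = True  # band reliability flag propagated from the CWT


def laterality_index(pre_left, pre_right, post_left, post_right) -> tuple[float, bool]:
    """Laterality index in percent, with a definedness flag.

    Accepts equal-length sample vectors or scalar band values.  A zero
    denominator (identical sides pre-stimulus) yields ``(nan, False)`` rather
    than an exception, so degenerate synthetic inputs do not abort batch runs.
    """
    pre_l = np.atleast_1d(np.asarray(pre_left, dtype=float))
    pre_r = np.atleast_1d(np.asarray(pre_right, dtype=float))
    post_l = np.atleast_1d(np.asarray(post_left, dtype=float))
    post_r = np.atleast_1d(np.asarray(post_right, dtype=float))
    if pre_l.shape != pre_r.shape or post_l.shape != post_r.shape:
        raise ValueError("left/right vectors must have equal length per phase")
    for arr in (pre_l, pre_r, post_l, post_r):
        if not np.all(np.isfinite(arr)):
            raise ValueError("laterality inputs must be finite")
    denom = float(np.mean(np.abs(pre_l - pre_r)))
    numer = float(np.mean(np.abs(post_l - post_r)))
    if denom == 0.0:
        return float("nan"), False
    return numer / denom * 100.0, True


def laterality_by_window(session: BilateralSession, mode: str = "raw",
                         registry: dict | None = None,
                         band_statistic: str = "scalar",
                         **cwt_kwargs) -> list[LateralityResult]:
    """Laterality indices for each post window of a session.

    mode "raw": the index on the 600-s sample vectors, one result per post
    window.  mode "bands": one result per band per post window, computed on
    band components (``band_statistic="scalar"``, the default) or on the
    band-averaged amplitude time series (``band_statistic="series"``).
    """
    if mode not in ("raw", "bands"):
        raise ValueError("mode must be 'raw' or 'bands'")
    if band_statistic not in ("scalar", "series"):
        raise ValueError("band_statistic must be 'scalar' or 'series'")
    segments = segment_windows(session)
    (_, pre_l, pre_r) = segments[0]
    results: list[LateralityResult] = []

    if mode == "raw":
        for win, seg_l, seg_r in segments[1:]:
            idx, ok = laterality_index(pre_l, pre_r, seg_l, seg_r)
            results.append(LateralityResult(session.subject_id, session.group,
                                            win.name, RAW_CHANNEL, idx, ok))
        return results

    registry = registry or wb.BAND_REGISTRY
    if band_statistic == "scalar":
        pre_bands_l = wb.decompose_bands(pre_l, session.fs, registry, **cwt_kwargs)
        pre_bands_r = wb.decompose_bands(pre_r, session.fs, registry, **cwt_kwargs)
        for win, seg_l, seg_r in segments[1:]:
            post_l = wb.decompose_bands(seg_l, session.fs, registry, **cwt_kwargs)
            post_r = wb.decompose_bands(seg_r, session.fs, registry, **cwt_kwargs)
            for bid in registry:
                idx, ok = laterality_index(pre_bands_l[bid].value,
                                           pre_bands_r[bid].value,
                                           post_l[bid].value, post_r[bid].value)
                reliable = (pre_bands_l[bid].reliable and pre_bands_r[bid].reliable
                            and post_l[bid].reliable and post_r[bid].reliable)
                results.append(LateralityResult(session.subject_id, session.group,
                                                win.name, bid, idx, ok, reliable))
        return results

    # time-resolved band series variant
    def band_series(seg):
        scal = _window_scalogram(seg, session.fs, registry, **cwt_kwargs)
        return {bid: wb.band_time_series(scal, bid, lo, hi)
                for bid, (lo, hi) in registry.items()}

    pre_series_l, pre_series_r = band_series(pre_l), band_series(pre_r)
    for win, seg_l, seg_r in segments[1:]:
        ser_l, ser_r = band_series(seg_l), band_series(seg_r)
        for bid in registry:
            _, sl, vl = ser_l[bid]
            _, sr, _ = ser_r[bid]
            _, pl, vp = pre_series_l[bid]
            _, pr, _ = pre_series_r[bid]
            idx, ok = laterality_index(pl[vp], pr[vp], sl[vl], sr[vl])
            results.append(LateralityResult(session.subject_id, session.group,
                                            win.name, bid, idx, ok))
    return results


def _window_scalogram(seg, fs, registry, omega0=wb.DEFAULT_OMEGA0,
                      voices_per_octave=16, work_fs=16.0):
    x = np.asarray(seg, dtype=float)
    f_max = max(hi for _, hi in registry.values())
    if work_fs is not None and fs > work_fs and (fs / work_fs) == int(fs / work_fs) \
            and work_fs >= 4.0 * f_max:
        from scipy.signal import resample_poly
        x = resample_poly(x, 1, int(fs / work_fs), padtype="mean")
        fs = work_fs
    f_min = min(lo for lo, _ in registry.values())
    grid = wb.default_freq_grid(f_min, f_max, voices_per_octave)
    return wb.morlet_cwt(x, fs, grid, omega0)


def laterality_full_span(session: BilateralSession, mode: str = "raw",
                         registry: dict | None = None,
                         **cwt_kwargs) -> list[LateralityResult]:
    """Laterality on the unsegmented spans: full baseline vs full 30-min post.

    Used for the correlation stage, where HRV and EGG endpoints are also
    computed on unsegmented 15-min pre / 30-min post records.
    """
    fs = session.fs
    n = session.left.samples.size
    i_stim = int(round(session.stimulus_time * fs))
    i_pre0 = max(0, i_stim - int(round(900 * fs)))
    i_post1 = min(n, i_stim + int(round(1800 * fs)))
    pre_l, pre_r = session.left.samples[i_pre0:i_stim], session.right.samples[i_pre0:i_stim]
    post_l, post_r = session.left.samples[i_stim:i_post1], session.right.samples[i_stim:i_post1]

    results = []
    if mode == "raw":
        idx, ok = laterality_index(pre_l, pre_r, post_l, post_r)
        results.append(LateralityResult(session.subject_id, session.group,
                                        "Post", RAW_CHANNEL, idx, ok))
        return results
    registry = registry or wb.BAND_REGISTRY
    pb_l = wb.decompose_bands(pre_l, fs, registry, **cwt_kwargs)
    pb_r = wb.decompose_bands(pre_r, fs, registry, **cwt_kwargs)
    qb_l = wb.decompose_bands(post_l, fs, registry, **cwt_kwargs)
    qb_r = wb.decompose_bands(post_r, fs, registry, **cwt_kwargs)
    for bid in registry:
        idx, ok = laterality_index(pb_l[bid].value, pb_r[bid].value,
                                   qb_l[bid].value, qb_r[bid].value)
        reliable = all(c[bid].reliable for c in (pb_l, pb_r, qb_l, qb_r))
        results.append(LateralityResult(session.subject_id, session.group,
                                        "Post", bid, idx, ok, reliable))
    return results
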