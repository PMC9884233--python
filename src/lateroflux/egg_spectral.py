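"""EGG power spectra and gastric dominant-frequency extraction.

The gastric slow wave sits near 3 cycles per minute (0.05 Hz).  Each of the
8 abdominal channels is band-passed, downsampled to a working rate, and its
power spectrum estimated with a single Hann-tapered periodogram of the
mean-removed signal.  The per-channel peak in the 2-4 cpm window
(0.033-0.066 Hz) gives eight candidate peaks; the subject's dominant
frequency (DF) is the frequency of the largest of them.  When no in-band
peak clears a noise floor (3x the median out-of-band power by default), the
DF is flagged undefined rather than reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import EGGRecording

__all__ = ["ChannelSpectrum", "DominantFrequency", "channel_spectrum",
           "dominant_frequency", "egg_dominant_frequency", "DF_BAND"]

DF_BAND = (0.033, 0.066)           # Hz, 2-4 cpm
DEFAULT_BANDPASS = (0.01, 0.25)    # Hz; suppresses drift and respiration
DEFAULT_WORK_FS = 10.0             # Hz working rate before the FFT
NOISE_FLOOR_FACTOR = 3.0
MIN_DURATION_S = 300.0


@dataclass
class ChannelSpectrum:
    freqs: np.ndarray   # Hz
    power: np.ndarray   # arbitrary units^2
    channel: int        # 1-based channel index


@dataclass
class DominantFrequency:
    df_hz: float
    source_channel: int
    peak_power: float
    defined: bool

    @property
    def df_cpm(self) -> float:
        return self.df_hz * 60.0


def _downsample(x: np.ndarray, fs: float, work_fs: float) -> tuple[np.ndarray, float]:
    if work_fs is None or fs <= work_fs:
        return x, fs
    ratio = Fraction(fs / work_fs).limit_denominator(10000)
    if ratio.denominator == 1:
        q = ratio.numerator
        while q > 1:  # cascade in steps of <=10 to keep FIR lengths short
            step = 10 if q % 10 == 0 else q
            x = sps.resample_poly(x, 1, step)
            q //= step
        return x, work_fs
    x = sps.resample_poly(x, ratio.denominator, ratio.numerator)
    return x, fs * ratio.denominator / ratio.numerator


def channel_spectrum(samples: np.ndarray, fs: float, channel: int = 1,
                     band_pass: tuple[float, float] | None = DEFAULT_BANDPASS,
                     work_fs: float | None = DEFAULT_WORK_FS) -> ChannelSpectrum:
    """Hann-tapered periodogram of one EGG channel.

    The signal is downsampled to ``work_fs`` (spectra below 0.25 Hz are
    unchanged within 1%), optionally band-passed, mean-removed and tapered
    with a single Hann window.
    """
    x = np.asarray(samples, dtype=float)
    duration = x.size / fs
    if duration < MIN_DURATION_S:
        warnings.warn(
            f"EGG record of {duration:.0f} s is shorter than {MIN_DURATION_S:.0f} s; "
            "spectral resolution in the slow-wave band will be coarse",
            stacklevel=2)
    if not np.any(x):
        freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
        warnings.warn("all-zero EGG channel; spectrum is identically zero",
                      stacklevel=2)
        return ChannelSpectrum(freqs, np.zeros_like(freqs), channel)
    x, fs_w = _downsample(x, fs, work_fs)
    if band_pass is not None:
        lo, hi = band_pass
        hi = min(hi, 0.45 * fs_w)
        sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs_w, output="sos")
        x = sps.sosfiltfilt(sos, x)
    freqs, power = sps.periodogram(x, fs=fs_w, window="hann", detrend="constant")
    return ChannelSpectrum(freqs, power, channel)


def dominant_frequency(spectra: list[ChannelSpectrum],
                       band: tuple[float, float] = DF_BAND,
                       noise_floor_factor: float = NOISE_FLOOR_FACTOR,
                       comparison_range: tuple[float, float] = (0.01, 0.2)
                       ) -> DominantFrequency:
    """Subject-level dominant frequency from 8 channel spectra.

    Per channel the maximum power in the DF band is taken; the subject DF is
    the frequency of the largest of the eight peaks (ties broken toward the
    lower frequency).  The peak must clear a noise floor of
    ``noise_floor_factor`` times the out-of-band reference power, or the DF
    is flagged undefined.  The reference is taken from out-of-band bins
    inside ``comparison_range`` (the band-pass passband, so the floor is not
    deflated by filtered-out regions) at the quantile matching the in-band
    max statistic, so pure noise sits near floor/``noise_floor_factor``.
    """
    if len(spectra) != 8:
        raise ValueError(f"expected 8 channel spectra, got {len(spectra)}")
    f0 = spectra[0].freqs
    for sp in spectra[1:]:
        if sp.freqs.shape != f0.shape or not np.allclose(sp.freqs, f0):
            raise ValueError("channel spectra must share a common frequency axis")
    in_band = (f0 >= band[0]) & (f0 <= band[1])
    if not in_band.any():
        raise ValueError("frequency axis has no bins in the DF band")
    out_band = (f0 >= comparison_range[0]) & (f0 <= comparison_range[1]) & ~in_band
    if not out_band.any():
        out_band = (f0 > 0) & ~in_band
    # the subject peak is a max over (in-band bins x channels) comparisons;
    # match that order statistic on the pooled out-of-band bins
    q_max = 1.0 - 1.0 / max(int(in_band.sum()) * len(spectra), 2)

    best = (-np.inf, np.inf, -1)  # (power, freq, channel); lower freq wins ties
    pooled_out = []
    for sp in spectra:
        p_in = sp.power[in_band]
        f_in = f0[in_band]
        order = np.lexsort((f_in, -p_in))  # max power, then lowest frequency
        j = order[0]
        pooled_out.append(sp.power[out_band])
        cand = (float(p_in[j]), float(f_in[j]), sp.channel)
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    peak_power, df_hz, channel = best
    noise_floor = noise_floor_factor * float(np.quantile(np.concatenate(pooled_out), q_max))
    defined = bool(peak_power > noise_floor and peak_power > 0)
    return DominantFrequency(df_hz=df_hz, source_channel=channel,
                             peak_power=peak_power, defined=defined)


def egg_dominant_frequency(rec: EGGRecording, **kwargs) -> DominantFrequency:
    """Convenience: channel spectra then DF for one 8-channel recording."""
    spectra = [channel_spectrum(rec.channels[i], rec.fs, channel=i + 1)
               for i in range(8)]
    return dominant_frequency(spectra, **kwargs)
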