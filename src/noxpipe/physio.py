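"""Cardiovascular and limb-withdrawal feature extraction.

Heart rate: ECG band-passed 12–40 Hz, R peaks picked with an adaptive
amplitude threshold and a 250 ms refractory period (deterministic rules
replacing manual correction), heart rate computed every second from the
mean RR interval in centred 3-s windows, and the evoked rise taken as
the post-stimulus maximum minus the prestimulus mean.

Limb withdrawal: EMG rectified, band-passed 10–500 Hz with notches at
50/100/150 Hz, RMS in 250 ms bins, post-stimulus bins normalized by the
mean RMS of the prestimulus second, averaged over the first second.
Features that cannot be computed are returned as None (missing), never
silently imputed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._filters import bandpass, notch

#: physiologically plausible neonatal RR interval bounds (s)
RR_BOUNDS_S = (0.25, 1.5)
REFRACTORY_S = 0.25


@dataclass
class RPeakSeries:
    """R-peak times (s, relative to the stimulus), strictly increasing."""

    peak_times_s: np.ndarray
    sfreq_hz: float

    @property
    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.peak_times_s)


@dataclass
class HeartRateSeries:
    """Heart rate (bpm) on an integer-second grid around the stimulus."""

    times_s: np.ndarray
    hr_bpm: np.ndarray


def detect_r_peaks(ecg: np.ndarray, sfreq: float,
                   t0_offset_s: float = 0.0) -> RPeakSeries | None:
    """Detect R peaks; returns None (feature missing) if fewer than 2 found.

    Band-pass 12–40 Hz, then peak picking at an adaptive threshold (40%
    of the 98th absolute-amplitude percentile) with a 250 ms refractory
    period.  Peaks creating implausibly short RR intervals are rejected
    by the refractory rule; implausibly long intervals are kept but the
    3-s-window heart-rate computation naturally bridges them.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < 10 * sfreq:
        raise ValueError("need at least 10 s of ECG")
    filt = bandpass(x, sfreq, 12.0, 40.0)
    scale = np.percentile(np.abs(filt), 98)
    if scale <= 0:
        return None
    idx, _ = find_peaks(filt, height=0.4 * scale,
                        distance=int(round(REFRACTORY_S * sfreq)))
    if idx.size < 2:
        return None
    times = t0_offset_s + idx / sfreq
    return RPeakSeries(peak_times_s=times, sfreq_hz=sfreq)


def heart_rate(peaks: RPeakSeries, window_s: float = 3.0) -> HeartRateSeries:
    """Heart rate every second: 60 / mean RR in the centred 3-s window.

    A grid point is valid only where the window holds at least 2 peaks
    (one full interval); other points are NaN.
    """
    t = peaks.peak_times_s
    if t.size < 2:
        raise ValueError("need at least 2 R peaks")
    rr = np.diff(t)
    starts, ends = t[:-1], t[1:]
    half = window_s / 2.0
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1)
    hr = np.full(grid.size, np.nan)
    for k, tc in enumerate(grid):
        sel = (ends > tc - half) & (starts < tc + half)  # interval overlaps
        if sel.sum() >= 1 and ((t >= tc - half) & (t <= tc + half)).sum() >= 2:
            hr[k] = 60.0 / rr[sel].mean()
    return HeartRateSeries(times_s=grid, hr_bpm=hr)


def hr_rise_feature(hr: HeartRateSeries, pre_s: float = 15.0,
                    post_s: float = 15.0) -> float | None:
    """Evoked heart-rate rise (bpm): max in (0, post_s] − mean in [−pre_s, 0).

    Returns None when either window lacks valid coverage.
    """
    pre = (hr.times_s >= -pre_s) & (hr.times_s < 0) & np.isfinite(hr.hr_bpm)
    post = (hr.times_s > 0) & (hr.times_s <= post_s) & np.isfinite(hr.hr_bpm)
    if not (pre.any() and post.any()):
        return None
    return float(hr.hr_bpm[post].max() - hr.hr_bpm[pre].mean())


def binned_rms(x: np.ndarray, sfreq: float, bin_s: float = 0.25) -> np.ndarray:
    """RMS of consecutive ``bin_s`` bins (trailing partial bin dropped).

    For a pure sine of amplitude a each full bin has RMS ≈ a/√2.
    """
    nbin = int(round(bin_s * sfreq))
    n = (x.size // nbin) * nbin
    return np.sqrt(np.mean(x[:n].reshape(-1, nbin) ** 2, axis=1))


def emg_rms_feature(emg: np.ndarray, sfreq: float, t0_offset_s: float,
                    band_hz: tuple[float, float] = (10.0, 500.0),
                    notches_hz: tuple[float, ...] = (50.0, 100.0, 150.0),
                    bin_s: float = 0.25) -> float | None:
    """Baseline-normalized EMG RMS in the first post-stimulus second.

    Rectify, band-pass, notch-filter; RMS per 250 ms bin; post-stimulus
    bins divided by the mean RMS over the prestimulus second; return the
    mean of the four bins in [0, 1) s.  A zero baseline makes the
    fold-change unbounded: the feature is returned as missing (None)
    with a degenerate-baseline warning.
    """
    x = np.abs(np.asarray(emg, dtype=float))
    h_freq = min(band_hz[1], sfreq / 2.0 - 1.0)
    x = bandpass(x, sfreq, band_hz[0], h_freq)
    usable = [f for f in notches_hz if f < sfreq / 2.0]
    if usable:
        x = notch(x, sfreq, usable, width=2.0)
    nbin = int(round(bin_s * sfreq))
    i_stim = int(round(-t0_offset_s * sfreq))
    pre_idx = [(i_stim - (k + 1) * nbin, i_stim - k * nbin) for k in range(4)]
    post_idx = [(i_stim + k * nbin, i_stim + (k + 1) * nbin) for k in range(4)]
    if pre_idx[-1][0] < 0 or post_idx[-1][1] > x.size:
        raise ValueError("epoch does not cover [-1, +1] s around the stimulus")

    def rms(i0, i1):
        return float(np.sqrt(np.mean(x[i0:i1] ** 2)))

    baseline = np.mean([rms(*ij) for ij in pre_idx])
    if baseline <= 0:
        warnings.warn("degenerate EMG baseline (zero RMS); feature missing")
        return None
    return float(np.mean([rms(*ij) / baseline for ij in post_idx]))
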