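"""EEG preprocessing, template/PC projection, Woody alignment and ERSP.

The cerebral features of the analysis: zero-phase FIR band-pass (1–30 Hz)
with a 50 Hz notch; age-weighted reference construction; Woody-filter
latency alignment (cross-correlation within ±50 ms); temporal PCA of the
first post-stimulus second (epochs as variables, timepoints as
observations); least-squares projection of unit-norm waveforms; and
Morlet-wavelet event-related spectral perturbation maps summarized over
five time-frequency windows of interest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from ._filters import bandpass, notch
from .config import ERSP_WINDOWS

__all__ = [
    "Epoch", "PrincipalWaveform", "ErspMap", "preprocess_eeg",
    "gaussian_age_weight", "age_weighted_reference", "woody_align",
    "extract_pcs", "project_waveform", "morlet_cycles", "compute_ersp",
    "ersp_window_means", "is_artifact",
]


@dataclass
class Epoch:
    """A stimulus-locked uniformly sampled signal segment.

    ``t0_offset_s`` is the time of the first sample relative to the
    stimulus (the stimulus is at t = 0).
    """

    samples: np.ndarray
    sfreq_hz: float
    t0_offset_s: float
    condition: str | None = None
    infant_id: str | None = None
    pma_days: int | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.samples.size) / self.sfreq_hz

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open window [t_start, t_end)."""
        i0 = int(round((t_start - self.t0_offset_s) * self.sfreq_hz))
        i1 = int(round((t_end - self.t0_offset_s) * self.sfreq_hz))
        if i0 < 0 or i1 > self.samples.size:
            raise ValueError("window outside epoch extent")
        return self.samples[i0:i1]


@dataclass
class PrincipalWaveform:
    """A unit-norm time-course over the first post-stimulus second."""

    values: np.ndarray
    sfreq_hz: float
    source: str  # noxious | nonnoxious | all | template
    rank: int = 1
    variance_fraction: float | None = None

    def __post_init__(self) -> None:
        nrm = float(np.linalg.norm(self.values))
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError(f"waveform is not unit-norm (|v| = {nrm:.3g})")


@dataclass
class ErspMap:
    """Log-power (dB) over time × frequency pixels."""

    grid: np.ndarray  # (n_freqs, n_time_pixels)
    time_axis_s: np.ndarray
    freq_axis_hz: np.ndarray


def preprocess_eeg(raw: np.ndarray, sfreq: float, l_freq: float = 1.0,
                   h_freq: float = 30.0, notch_hz: float = 50.0) -> np.ndarray:
    """Zero-phase Hamming windowed-sinc FIR band-pass + notch.

    Output has the same length as the input.  Raises a ValueError naming
    the minimum length if the signal is shorter than the filter.
    """
    if sfreq < 500:
        raise ValueError("EEG preprocessing expects sfreq >= 500 Hz")
    x = np.asarray(raw, dtype=float)
    out = bandpass(x, sfreq, l_freq, h_freq)
    return notch(out, sfreq, notch_hz, width=2.0)


def is_artifact(samples: np.ndarray, amplitude_uv: float = 250.0) -> bool:
    """Automated artifact criterion: amplitude exceedance or flat line."""
    x = np.asarray(samples, dtype=float)
    return bool(np.max(np.abs(x)) > amplitude_uv or np.ptp(x) < 1e-12)


def gaussian_age_weight(delta_days, window_days: float = 56.0):
    """Gaussian age weight for a PMA offset within a sliding window.

    ``w = exp(-0.5 (2.5 Δ / R)^2)`` with R = window_days / 2; offsets
    beyond the window half-length get weight 0.  For the 56-day window
    this decays to ~0.46 at a 2-week offset and to ~0.04 at 4 weeks (the
    window edge); the 28-day trajectory window gives ~0.46 at 1 week.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    delta = np.asarray(delta_days, dtype=float)
    r = window_days / 2.0
    w = np.exp(-0.5 * (2.5 * delta / r) ** 2)
    w = np.where(np.abs(delta) > r, 0.0, w)
    return w if w.ndim else float(w)


def age_weighted_reference(epochs: np.ndarray, pma_days_list, target_index: int,
                           window_days: float = 56.0) -> np.ndarray:
    """Age-weighted average trace centred on the target infant's PMA.

    ``epochs`` is (n_epochs, n_times).  The target's own epoch enters
    with weight 1; the others with the Gaussian age weight of their PMA
    offset.  Weights are renormalized to sum to 1.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2 or epochs.shape[0] < 1:
        raise ValueError("epochs must be a (n_epochs, n_times) matrix")
    pma = np.asarray(pma_days_list, dtype=float)
    w = gaussian_age_weight(pma - pma[target_index], window_days)
    w = np.asarray(w, dtype=float).copy()
    w[target_index] = 1.0
    total = w.sum()
    if total <= 0:
        raise ValueError("all age weights are zero")
    return (w / total) @ epochs


def woody_align(epoch: Epoch, reference: np.ndarray,
                max_jitter_s: float = 0.05,
                window_s: tuple[float, float] = (0.0, 1.0)) -> tuple[Epoch, float]:
    """Latency-align an epoch to a reference by cross-correlation.

    The lag maximizing the Pearson correlation between the epoch and the
    reference within ±``max_jitter_s``, evaluated on the stated window,
    is found on the integer-sample grid; the returned epoch is the input
    shifted by −lag.  The reference must share the epoch's sampling grid
    and time origin.  A positive lag means the epoch lags (is delayed
    relative to) the reference.
    """
    sf = epoch.sfreq_hz
    jmax = int(round(max_jitter_s * sf))
    i0 = int(round((window_s[0] - epoch.t0_offset_s) * sf))
    i1 = int(round((window_s[1] - epoch.t0_offset_s) * sf))
    if i0 - jmax < 0 or i1 + jmax > epoch.samples.size:
        raise ValueError("epoch does not cover the window padded by the jitter")
    ref_seg = np.asarray(reference, dtype=float)[i0:i1]
    if np.allclose(ref_seg, 0.0):
        warnings.warn("all-zero reference; Woody lag set to 0")
        return epoch, 0.0
    lags, r, _ = _lag_correlations(epoch.samples, ref_seg, i0, jmax)
    best = np.flatnonzero(r >= r.max() - 1e-15)
    lag = int(lags[best[np.argmin(np.abs(lags[best]))]])
    shifted = _integer_shift(epoch.samples, -lag)
    aligned = Epoch(shifted, sf, epoch.t0_offset_s, epoch.condition,
                    epoch.infant_id, epoch.pma_days)
    return aligned, lag / sf


def _lag_correlations(x: np.ndarray, w: np.ndarray, i0: int,
                      jmax: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation and raw inner product between ``w`` and each
    lagged segment x[i0+lag : i0+lag+len(w)], for lags −jmax … +jmax."""
    n = w.size
    seg_all = x[i0 - jmax:i0 + n + jmax]
    ones = np.ones(n)
    dots = np.correlate(seg_all, w, mode="valid")
    sums = np.correlate(seg_all, ones, mode="valid")
    ssq = np.correlate(seg_all ** 2, ones, mode="valid")
    w_c = w - w.mean()
    nrm_w = np.linalg.norm(w_c)
    dot_c = dots - sums * w.mean()
    var_seg = np.clip(ssq - sums ** 2 / n, 0.0, None)
    denom = np.sqrt(var_seg) * nrm_w
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, dot_c / denom, -np.inf)
    return np.arange(-jmax, jmax + 1), r, dots


def _integer_shift(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift a 1-D array by an integer number of samples, edge-padding."""
    out = np.empty_like(x)
    if shift == 0:
        out[:] = x
    elif shift > 0:
        out[shift:] = x[:-shift]
        out[:shift] = x[0]
    else:
        out[:shift] = x[-shift:]
        out[shift:] = x[-1]
    return out


def extract_pcs(epoch_matrix: np.ndarray, sfreq: float,
                variance_target: float = 0.75, source: str = "all",
                min_components: int = 0) -> list[PrincipalWaveform]:
    """Temporal PCA of aligned epochs over the first post-stimulus second.

    Epochs are the variables and timepoints the observations: each epoch
    (row of ``epoch_matrix``) is mean-centred over time, and the left
    singular vectors of the timepoints × epochs matrix are the principal
    waveforms.  Returns the smallest number of components whose
    cumulative variance fraction reaches ``variance_target`` (at least
    ``min_components``), each sign-fixed so that the mean projection
    coefficient over the input epochs is non-negative.
    """
    epochs = np.asarray(epoch_matrix, dtype=float)
    if epochs.ndim != 2 or epochs.shape[0] < 3:
        raise ValueError("need at least 3 epochs for PCA")
    m = (epochs - epochs.mean(axis=1, keepdims=True)).T  # times x epochs
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    k = int(np.searchsorted(np.cumsum(frac), variance_target) + 1)
    k = min(max(k, min_components), s.size)
    out = []
    for i in range(k):
        pc = u[:, i].copy()
        # mean coefficient over epochs = s_i * mean(V[:, i])
        if s[i] * vt[i].mean() < 0:
            pc = -pc
        out.append(PrincipalWaveform(pc, sfreq, source, rank=i + 1,
                                     variance_fraction=float(frac[i])))
    return out


def project_waveform(epoch: Epoch, pw: PrincipalWaveform,
                     max_jitter_s: float = 0.05) -> float:
    """Coefficient of a unit-norm waveform in one epoch (µV).

    The epoch (already baseline-corrected to the prestimulus mean) is
    Woody-aligned to the waveform within ±``max_jitter_s``; the
    coefficient is the inner product of the aligned first-second segment
    with the waveform, i.e. the least-squares regression weight.  Linear
    in epoch amplitude.
    """
    sf = epoch.sfreq_hz
    w = np.asarray(pw.values, dtype=float)
    jmax = int(round(max_jitter_s * sf))
    i0 = int(round((0.0 - epoch.t0_offset_s) * sf))
    i1 = i0 + w.size
    if i0 - jmax < 0 or i1 + jmax > epoch.samples.size:
        raise ValueError("epoch does not cover [0, 1] s padded by the jitter")
    # alignment maximizes the signed correlation (classic Woody): content
    # matching the waveform is registered exactly; anti-correlated
    # content is attenuated rather than amplified
    _, r, dots = _lag_correlations(epoch.samples, w, i0, jmax)
    return float(dots[np.argmax(r)])


def morlet_cycles(freqs) -> np.ndarray:
    """Wavelet cycle count: 3 cycles at 1 Hz rising linearly to 45 at 30 Hz
    (half the cycle count of the equivalent FFT window)."""
    f = np.asarray(freqs, dtype=float)
    return 3.0 + 42.0 * (f - 1.0) / 29.0


def compute_ersp(epoch: Epoch, n_freqs: int = 59,
                 f_lo: float = 1.0, f_hi: float = 30.0,
                 n_time_pixels: int = 200,
                 baseline_s: tuple[float, float] = (-0.5, 0.0),
                 decim: int = 10) -> ErspMap:
    """Single-trial event-related spectral perturbation map.

    Morlet-wavelet power at 59 frequencies (1–30 Hz, 0.5 Hz steps) with
    linearly increasing cycles; each frequency's power is divided by that
    frequency's mean power in the 500 ms baseline directly before the
    stimulus, then 10·log10 (dB) transformed, trimmed to the interval
    free of wavelet edge effects, and resampled to 200 time pixels.

    The epoch is reflection-padded before the decomposition so that the
    trimmed interval is supported by data rather than zero-padding.
    """
    sf = epoch.sfreq_hz
    freqs = np.linspace(f_lo, f_hi, n_freqs)
    cycles = morlet_cycles(freqs)
    # half-support of the longest wavelet (EEGlab convention: n_cycles/f)
    edge_s = 0.5 * cycles[0] / freqs[0]
    pad = int(round((edge_s + 0.1) * sf))
    x = np.pad(np.asarray(epoch.samples, dtype=float), pad, mode="reflect")
    power = tfr_array_morlet(x[None, None, :], sf, freqs, n_cycles=cycles,
                             output="power", decim=decim,
                             zero_mean=True, verbose="error")[0, 0]
    times = epoch.t0_offset_s + (np.arange(x.size)[::decim] - pad) / sf
    base = (times >= baseline_s[0]) & (times < baseline_s[1])
    if not base.any():
        raise ValueError("baseline window outside epoch")
    base_power = power[:, base].mean(axis=1)
    if np.any(base_power <= 0):
        raise ValueError("degenerate input: zero baseline power")
    db = 10.0 * np.log10(power / base_power[:, None])
    t_end = epoch.t0_offset_s + epoch.samples.size / sf
    valid = (times >= epoch.t0_offset_s + edge_s) & (times <= t_end - edge_s)
    db, times = db[:, valid], times[valid]
    # resample to the fixed pixel grid spanning the valid interval
    pix_t = np.linspace(times[0], times[-1], n_time_pixels)
    grid = np.vstack([np.interp(pix_t, times, row) for row in db])
    return ErspMap(grid=grid, time_axis_s=pix_t, freq_axis_hz=freqs)


def ersp_window_means(ersp: ErspMap,
                      windows: dict[str, tuple[float, float, float, float]]
                      = ERSP_WINDOWS) -> dict[str, float]:
    """Mean log power in named time-frequency windows.

    Pixels whose centres fall in the half-open time window
    [t_start, t_end) and the inclusive frequency band [f_lo, f_hi]
    are averaged arithmetically.
    """
    out = {}
    for name, (t0, t1, f0, f1) in windows.items():
        tm = (ersp.time_axis_s >= t0) & (ersp.time_axis_s < t1)
        fm = (ersp.freq_axis_hz >= f0) & (ersp.freq_axis_hz <= f1)
        if not (tm.any() and fm.any()):
            raise ValueError(f"empty time-frequency window {name!r}")
        out[name] = float(ersp.grid[np.ix_(fm, tm)].mean())
    return out
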