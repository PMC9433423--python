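"""Cached zero-phase FIR filtering.

Filter kernels (Hamming windowed-sinc, designed by mne) depend only on
the sampling rate and band edges, so they are designed once and cached;
application is a single zero-phase 'same'-mode FFT convolution with the
symmetric kernel.  This keeps per-epoch filtering cost at the cost of
one convolution instead of a full redesign.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve


@lru_cache(maxsize=64)
def fir_design(sfreq: float, l_freq: float | None, h_freq: float | None) -> np.ndarray:
    """Band-pass (or band-stop if l_freq > h_freq) FIR kernel."""
    from mne.filter import create_filter

    return create_filter(None, sfreq, l_freq, h_freq,
                         fir_window="hamming", fir_design="firwin",
                         phase="zero", verbose="error")


@lru_cache(maxsize=64)
def notch_design(sfreq: float, freq: float, width: float = 2.0) -> np.ndarray:
    """Band-stop kernel around ``freq`` (l_freq above h_freq), 1 Hz
    transition bands as in mne's notch filtering."""
    from mne.filter import create_filter

    return create_filter(None, sfreq, freq + width / 2.0, freq - width / 2.0,
                         l_trans_bandwidth=1.0, h_trans_bandwidth=1.0,
                         fir_window="hamming", fir_design="firwin",
                         phase="zero", verbose="error")


def apply_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric odd-length FIR kernel;
    output length equals input length (edges reflect-padded)."""
    pad = (h.size - 1) // 2
    xp = np.pad(x, pad, mode="reflect")
    return fftconvolve(xp, h, mode="same")[pad:-pad]


def bandpass(x: np.ndarray, sfreq: float, l_freq: float | None,
             h_freq: float | None) -> np.ndarray:
    h = fir_design(sfreq, l_freq, h_freq)
    if x.size < h.size:
        raise ValueError(
            f"signal of {x.size} samples shorter than the {h.size}-tap "
            f"filter; need at least {h.size} samples at {sfreq:g} Hz")
    return apply_fir(x, h)


def notch(x: np.ndarray, sfreq: float, freqs, width: float = 2.0) -> np.ndarray:
    for f in np.atleast_1d(freqs):
        x = apply_fir(x, notch_design(sfreq, float(f), width))
    return x
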