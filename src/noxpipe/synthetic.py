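"""Synthetic multimodal cohort generator.

Emulates the study conditions the analysis assumes: stimulus-locked EEG
epochs whose event-related morphology changes with postmenstrual age
(slow-wave/delta-brush-like activity below ~30 weeks, a transitory
negative deflection peaking near 445 ms around 30–33 weeks, and a
positive deflection near 595 ms emerging from ~33 weeks), an evoked
heart-rate rise whose magnitude increases with PMA, stimulus-evoked EMG
bursts within the first second whose duration shortens with age, and a
brow-bulge (facial grimace) probability that rises from roughly one
third at 28–30 weeks to two thirds at term.  Noxious-specific components
scale with ``effect_scales``; at 0 the two conditions are exchangeable.

All amplitudes are parametric placeholders chosen for realistic
signal-to-noise, not literature values; only directions and latencies
are meaningful.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import DAYS_PER_WEEK, CohortConfig

CONDITIONS = ("noxious", "nonnoxious")

#: extents of the generated traces, seconds relative to the stimulus
EEG_SPAN_S = (-2.5, 4.0)
ECG_SPAN_S = (-30.0, 30.0)
EMG_SPAN_S = (-5.0, 15.0)
ERP_KERNEL_SPAN_S = (-0.5, 1.05)


@dataclass
class InfantRecord:
    """One infant's demographics, condition-labelled traces and behaviour.

    Traces are dictionaries keyed by condition ("noxious"/"nonnoxious").
    EMG is additionally keyed by side ("ipsi"/"contra").  ``missing``
    holds, per condition, the set of feature names the downstream table
    must mark as absent.
    """

    infant_id: str
    pma_days: int
    pna_days: int
    eeg: dict = field(default_factory=dict)
    ecg: dict = field(default_factory=dict)
    emg: dict = field(default_factory=dict)
    brow_bulge_s: dict = field(default_factory=dict)
    missing: dict = field(default_factory=dict)
    eeg_sfreq: float = 2000.0
    ecg_sfreq: float = 500.0
    emg_sfreq: float = 2000.0


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def erp_kernel(
    pma_days: float,
    condition: str,
    sfreq: float = 2000.0,
    effect_scale: float = 1.0,
    amplitude_scale: float = 1.0,
    gains: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free deterministic ERP kernel over −0.5 … +1.05 s (µV).

    Shared components (both conditions): an age-decaying slow wave with a
    superimposed fast (15 Hz) burst — the delta-brush-like pattern of the
    youngest infants — and a small early N–P complex.  Noxious-only
    components, scaled by ``effect_scale``: a negative Gaussian deflection
    at 445 ms, present roughly between 29 and 34 weeks and gone by ~36
    weeks, and a positive deflection at 595 ms (with a small early P–N
    complex) rising from 33 weeks to a plateau at term.  The noxious
    response partially supplants the immature slow wave, which therefore
    stays larger in the nonnoxious condition.

    ``gains`` optionally carries per-infant multiplicative amplitude
    factors (keys: slow, brush, n2, p3; mean ~1) modelling idiosyncratic
    response-magnitude variability on top of the age trends.

    Returns (times_s, values_uv).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    p = pma_days / DAYS_PER_WEEK
    if not (28.0 <= p < 40.0):
        raise ValueError(f"PMA {p:.2f} weeks outside [28, 40)")
    g = {"slow": 1.0, "brush": 1.0, "n2": 1.0, "p3": 1.0, **(gains or {})}
    t = np.arange(round(ERP_KERNEL_SPAN_S[0] * sfreq),
                  round(ERP_KERNEL_SPAN_S[1] * sfreq)) / sfreq

    def bump(center, width):
        return np.exp(-(((t - center) / width) ** 2))

    def ricker(center, width):
        # zero-mean biphasic deflection: main lobe with polarity-reversed
        # flanks, as filtered ERP components appear
        x = (t - center) / width
        return (1.0 - x ** 2) * np.exp(-x ** 2 / 2.0)

    def gwcos(center, sigma, freq):
        # Gaussian-windowed cosine, mean-corrected to zero area
        m = np.exp(-((2 * np.pi * freq * sigma) ** 2) / 2.0)
        return ((np.cos(2 * np.pi * freq * (t - center)) - m)
                * np.exp(-(((t - center) / (sigma * np.sqrt(2.0))) ** 2)))

    # (a) slow wave + fast burst, dominant below 30 weeks, both conditions
    slow_shape = gwcos(0.24, 0.106, 1.1)
    slow_shape = slow_shape / np.max(np.abs(slow_shape))
    a_sw = g["slow"] * 80.0 * _sigmoid(-(p - 29.6) / 0.55)
    slow = a_sw * slow_shape
    a_br = g["brush"] * 16.0 * _sigmoid(-(p - 29.5) / 0.8)
    brush = a_br * bump(0.26, 0.08) * np.sin(2 * np.pi * 15.0 * t)
    # small early N–P complex, visible in both conditions
    early_np = 4.0 * (-bump(0.15, 0.04) + bump(0.25, 0.04))
    kernel = slow + brush + early_np

    if condition == "noxious":
        # the specific noxious response partially supplants the immature
        # slow wave, leaving it larger in the nonnoxious condition
        kernel = kernel - 0.25 * effect_scale * slow
        # (b) transitory negative deflection at 445 ms
        a_n2 = g["n2"] * 30.0 * np.exp(-(((p - 30.8) / 1.7) ** 2))
        n2 = -a_n2 * ricker(0.445, 0.035)
        # (c) positive deflection at ~600 ms with early P–N complex,
        # rising from 33 wk to a plateau at term
        a_p3 = g["p3"] * 12.0 * _sigmoid((p - 35.5) / 1.3)
        p3 = a_p3 * (ricker(0.60, 0.045) + 0.3 * bump(0.214, 0.04)
                     - 0.3 * bump(0.30, 0.04))
        kernel = kernel + effect_scale * (n2 + p3)

    # stimulus-locked: nothing before t = 0, smooth onset over 30 ms
    ramp = np.clip(t / 0.03, 0.0, 1.0)
    kernel *= 0.5 * (1.0 - np.cos(np.pi * ramp))
    kernel[t < 0.0] = 0.0
    return t, amplitude_scale * kernel


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude-shaped noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / max(out.std(), 1e-12)


def draw_component_gains(rng: np.random.Generator) -> dict[str, float]:
    """Per-infant multiplicative ERP amplitude factors (gamma, mean 1,
    CV 0.5), shared between an infant's two conditions."""
    return {name: float(rng.gamma(4.0, 0.25))
            for name in ("slow", "brush", "n2", "p3")}


def simulate_eeg(pma_days, condition, config: CohortConfig,
                 rng: np.random.Generator,
                 gains: dict[str, float] | None = None) -> np.ndarray:
    """EEG trace over −2.5 … +4 s: ERP kernel plus pink+white background."""
    sf = config.sfreq_hz
    n = round((EEG_SPAN_S[1] - EEG_SPAN_S[0]) * sf)
    sd = config.noise_sd["eeg"]
    noise = sd * (0.8 * _pink_noise(n, rng) + 0.2 * rng.standard_normal(n))
    trace = noise
    _, kernel = erp_kernel(pma_days, condition, sf,
                           effect_scale=config.effect_scales["erp"],
                           gains=gains)
    i0 = round((ERP_KERNEL_SPAN_S[0] - EEG_SPAN_S[0]) * sf)
    trace[i0:i0 + kernel.size] += kernel
    return trace


def evoked_hr_rise_bpm(pma_days: float, effect_scale: float = 1.0) -> float:
    """Peak magnitude (bpm) of the evoked heart-rate rise; linear in PMA."""
    p = pma_days / DAYS_PER_WEEK
    return effect_scale * (2.0 + 1.6 * (p - 28.0))


def _hr_response_shape(t: np.ndarray) -> np.ndarray:
    """Unit-peak transient, onset at 0, peak near 3 s, gone by ~15 s."""
    shape = np.where(t > 0, (t / 3.0) * np.exp(1.0 - t / 3.0), 0.0)
    return np.clip(shape, 0.0, None)


def simulate_rr(pma_days, condition, config: CohortConfig,
                rng: np.random.Generator,
                base_hr_bpm: float | None = None) -> np.ndarray:
    """Beat (R-peak) times in seconds over −30 … +30 s around the stimulus.

    Baseline heart rate ~120–160 bpm with per-beat RR jitter; the noxious
    condition adds a transient rate increase in 0–15 s whose magnitude
    grows with PMA (scaled by ``effect_scales['heart_rate']``).
    """
    if base_hr_bpm is None:
        base_hr_bpm = float(np.clip(140.0 + 7.0 * rng.standard_normal(),
                                    120.0, 160.0))
    rise = evoked_hr_rise_bpm(pma_days, config.effect_scales["heart_rate"])
    if condition == "nonnoxious":
        rise = 0.0
    jitter_s = config.noise_sd["rr_ms"] / 1000.0
    beats = []
    t = ECG_SPAN_S[0] - 1.0
    while t < ECG_SPAN_S[1] + 1.0:
        rate = base_hr_bpm + rise * _hr_response_shape(np.array([t]))[0]
        rr = 60.0 / rate + jitter_s * rng.standard_normal()
        rr = max(rr, 0.25)
        t += rr
        beats.append(t)
    return np.asarray(beats)


def ecg_from_beats(beats: np.ndarray, config: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Synthetic single-lead ECG: Gaussian R waves at beat times + noise."""
    sf = config.ecg_sfreq_hz
    t = np.arange(round(ECG_SPAN_S[0] * sf), round(ECG_SPAN_S[1] * sf)) / sf
    trace = config.noise_sd["ecg"] * rng.standard_normal(t.size)
    width = 0.012  # R-wave half-width, s
    halfspan = int(round(5 * width * sf))
    for b in beats:
        if not (ECG_SPAN_S[0] - 0.1 < b < ECG_SPAN_S[1] + 0.1):
            continue
        c = int(round((b - ECG_SPAN_S[0]) * sf))
        i0, i1 = max(c - halfspan, 0), min(c + halfspan, t.size)
        if i0 < i1:
            trace[i0:i1] += np.exp(-(((t[i0:i1] - b) / width) ** 2))
    return trace


def simulate_emg(pma_days, condition, config: CohortConfig,
                 rng: np.random.Generator, side: str = "ipsi") -> np.ndarray:
    """EMG trace (µV) over −5 … +15 s.

    Baseline stochastic activity everywhere; the noxious condition adds a
    noise burst starting <1 s post-stimulus.  Burst onset magnitude is
    independent of PMA; burst duration is longer at younger PMA.
    """
    sf = config.emg_sfreq_hz
    t = np.arange(round(EMG_SPAN_S[0] * sf), round(EMG_SPAN_S[1] * sf)) / sf
    sd = config.noise_sd["emg"]
    trace = sd * rng.standard_normal(t.size)
    effect = config.effect_scales["emg"]
    if condition == "noxious" and effect > 0:
        p = pma_days / DAYS_PER_WEEK
        onset = 0.15
        # the burst always spans the 1-s analysis window; the extra
        # duration in younger infants lies beyond it, so the windowed
        # fold-change stays age-independent while the visible response
        # lasts longer at lower PMA
        duration = 1.0 + 0.12 * (40.0 - p)
        gain = 5.0 if side == "ipsi" else 3.5
        env = np.zeros_like(t)
        rise = 0.05
        in_burst = (t >= onset) & (t <= onset + duration)
        env[in_burst] = np.minimum((t[in_burst] - onset) / rise, 1.0)
        tail = t > onset + duration
        env[tail] = np.exp(-(t[tail] - onset - duration) / 0.15)
        burst_sd = effect * gain * max(sd, 1.0)
        trace += burst_sd * env * rng.standard_normal(t.size)
    return trace


def browbulge_response_probability(pma_days: float, condition: str,
                                   effect_scale: float = 1.0) -> float:
    """Probability of a nonzero brow-bulge response.

    Nonnoxious events respond at a constant base rate; noxious response
    probability rises with PMA from ~1/3 below 30 weeks to ~2/3 at term,
    interpolated towards the base rate as the effect scale shrinks.
    """
    base = 0.25
    if condition == "nonnoxious":
        return base
    p = pma_days / DAYS_PER_WEEK
    p_age = 1.0 / 3.0 + (1.0 / 3.0) * float(np.clip((p - 29.5) / 9.5, 0.0, 1.0))
    return base + effect_scale * (p_age - base)


def simulate_browbulge(pma_days, condition, config: CohortConfig,
                       rng: np.random.Generator,
                       probability: float | None = None) -> float:
    """Brow-bulge duration (s) in [0, 30]; zero for non-responders."""
    if probability is None:
        probability = browbulge_response_probability(
            pma_days, condition, config.effect_scales["brow_bulge"])
    if rng.random() >= probability:
        return 0.0
    return float(min(30.0, 0.5 + rng.gamma(2.0, 3.0)))


_MISSING_PER_INFANT = ("heart_rate", "brow_bulge", "ipsi_reflex", "contra_reflex")


ALL_MODALITIES = ("eeg", "ecg", "emg", "browbulge")


def generate_cohort(config: CohortConfig,
                    modalities=ALL_MODALITIES) -> list[InfantRecord]:
    """Generate a reproducible cohort; one noxious and one nonnoxious event
    per infant; PMA uniformly covering the configured range.

    ``modalities`` restricts which traces are synthesized (the random
    substreams are per-modality, so a restricted cohort's traces are
    identical to the corresponding traces of the full cohort); features
    of omitted modalities are later marked missing.
    """
    root = np.random.SeedSequence(config.seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    lo, hi = config.pma_range_weeks
    # evenly spread PMA over the range with a small uniform scatter so
    # every postmenstrual week is represented at any n
    grid = lo + (hi - lo) * (np.arange(config.n_infants) + 0.5) / config.n_infants
    pma_weeks = grid + demo_rng.uniform(-0.3, 0.3, config.n_infants)
    pma_weeks = np.clip(pma_weeks, lo, np.nextafter(hi, lo))
    pna_days = demo_rng.integers(2, int(config.pna_max_weeks * 7), config.n_infants)

    records: list[InfantRecord] = []
    infant_seqs = root.spawn(config.n_infants)
    for i, seq in enumerate(infant_seqs):
        pma_d = int(round(pma_weeks[i] * DAYS_PER_WEEK))
        pma_d = int(np.clip(pma_d, int(lo * 7), int(hi * 7) - 1))
        rec = InfantRecord(
            infant_id=f"inf{i:03d}", pma_days=pma_d, pna_days=int(pna_days[i]),
            eeg_sfreq=config.sfreq_hz, ecg_sfreq=config.ecg_sfreq_hz,
            emg_sfreq=config.emg_sfreq_hz)
        streams = seq.spawn(6)
        eeg_rng, ecg_rng, emg_rng, face_rng, miss_rng, base_rng = (
            np.random.default_rng(s) for s in streams)
        base_hr = float(np.clip(140.0 + 7.0 * base_rng.standard_normal(),
                                120.0, 160.0))
        gains = draw_component_gains(base_rng)
        for cond in CONDITIONS:
            rec.missing[cond] = set()
            rec.emg[cond] = {}
            if "eeg" in modalities:
                rec.eeg[cond] = simulate_eeg(pma_d, cond, config, eeg_rng,
                                             gains=gains)
            if "ecg" in modalities:
                beats = simulate_rr(pma_d, cond, config, ecg_rng,
                                    base_hr_bpm=base_hr)
                rec.ecg[cond] = ecg_from_beats(beats, config, ecg_rng)
            else:
                rec.missing[cond].add("heart_rate")
            if "emg" in modalities:
                rec.emg[cond] = {
                    side: simulate_emg(pma_d, cond, config, emg_rng, side=side)
                    for side in ("ipsi", "contra")}
            if "browbulge" in modalities:
                rec.brow_bulge_s[cond] = simulate_browbulge(
                    pma_d, cond, config, face_rng)
            else:
                rec.brow_bulge_s[cond] = 0.0
                rec.missing[cond].add("brow_bulge")
        # missingness: per-infant for physiology/behaviour, per-event for ERSP
        for feat in _MISSING_PER_INFANT:
            if miss_rng.random() < config.missing_rates.get(feat, 0.0):
                for cond in CONDITIONS:
                    rec.missing[cond].add(feat)
        for cond in CONDITIONS:
            if miss_rng.random() < config.missing_rates.get("ersp", 0.0):
                rec.missing[cond].add("ersp")
        records.append(rec)
    return records


def cohort_frame(records: list[InfantRecord]):
    """Demographics of a cohort as a DataFrame (infant_id, pma_days, pna_days)."""
    import pandas as pd

    return pd.DataFrame(
        {"infant_id": [r.infant_id for r in records],
         "pma_days": [r.pma_days for r in records],
         "pna_days": [r.pna_days for r in records]})
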