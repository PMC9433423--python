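"""Configuration objects for cohort simulation and the analysis pipeline.

All defaults are the values used throughout the analysis (filter bands,
epoch extents, time-frequency windows, classifier hyperparameters,
permutation counts).  Overrides are explicit dataclass replacements so a
provenance log can record exactly what changed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

DAYS_PER_WEEK = 7.0


def _default_effect_scales() -> dict[str, float]:
    return {"erp": 1.0, "heart_rate": 1.0, "emg": 1.0, "brow_bulge": 1.0}


def _default_noise_sd() -> dict[str, float]:
    # EEG/EMG in microvolt RMS, RR jitter in milliseconds, ECG in arbitrary mV-like units
    return {"eeg": 5.0, "emg": 4.0, "rr_ms": 10.0, "ecg": 0.03}


def _default_missing_rates() -> dict[str, float]:
    # Missing-completely-at-random rates, roughly matching the observed
    # per-feature exclusion counts in the source cohorts.
    return {
        "heart_rate": 0.10,
        "ersp": 0.05,
        "ipsi_reflex": 0.04,
        "contra_reflex": 0.06,
        "brow_bulge": 0.06,
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic multimodal cohort generator.

    Attributes
    ----------
    n_infants : number of infants; each carries one noxious and one
        nonnoxious stimulus event.
    pma_range_weeks : half-open postmenstrual-age interval covered
        uniformly by the cohort (weeks).
    pna_max_weeks : exclusive upper bound on postnatal age at study.
    sfreq_hz : EEG sampling rate.
    effect_scales : dimensionless multipliers on the condition-specific
        (noxious-only) response components, per feature family.  Setting
        every entry to 0 makes the two conditions exchangeable.
    noise_sd : additive noise amplitudes per modality.
    missing_rates : per-feature probability that the feature is marked
        missing (applied per infant, or per event for the ERSP family).
    seed : master seed; every random draw derives from it through
        per-infant/per-modality substreams.
    """

    n_infants: int = 47
    pma_range_weeks: tuple[float, float] = (28.0, 40.0)
    pna_max_weeks: float = 8.0
    sfreq_hz: float = 2000.0
    ecg_sfreq_hz: float = 500.0
    emg_sfreq_hz: float = 2000.0
    effect_scales: dict[str, float] = field(default_factory=_default_effect_scales)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_infants < 1:
            raise ValueError("n_infants must be >= 1")
        lo, hi = self.pma_range_weeks
        if not (lo < hi):
            raise ValueError(f"invalid PMA range {self.pma_range_weeks}")
        if self.sfreq_hz <= 0 or self.ecg_sfreq_hz <= 0 or self.emg_sfreq_hz <= 0:
            raise ValueError("sampling rates must be positive")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} not in [0, 1]: {rate}")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise sd for {name!r}")


# Time-frequency windows of interest: (t_start_s, t_end_s, f_lo_hz, f_hi_hz),
# half-open in time, inclusive in frequency.
ERSP_WINDOWS: dict[str, tuple[float, float, float, float]] = {
    "early_delta": (0.250, 0.750, 2.0, 4.0),
    "early_alpha": (0.250, 0.750, 7.0, 15.0),
    "late_delta": (1.000, 2.000, 1.0, 2.0),
    "late_alpha": (1.000, 2.000, 7.0, 15.0),
    "late_beta": (1.500, 2.300, 28.0, 30.0),
}


@dataclass
class PipelineConfig:
    """Every numeric setting of the analysis, at its canonical default."""

    # EEG filtering / epoching
    eeg_l_freq: float = 1.0
    eeg_h_freq: float = 30.0
    notch_hz: float = 50.0
    erp_window_s: tuple[float, float] = (-0.5, 1.05)
    ersp_window_s: tuple[float, float] = (-2.5, 4.0)
    artifact_uv: float = 250.0

    # ERSP decomposition
    ersp_n_freqs: int = 59
    ersp_f_lo: float = 1.0
    ersp_f_hi: float = 30.0
    ersp_n_time_pixels: int = 200
    ersp_baseline_s: tuple[float, float] = (-0.5, 0.0)

    # PCA / Woody alignment
    pca_variance_target: float = 0.75
    woody_max_jitter_s: float = 0.05
    gaussian_window_days: float = 56.0
    trajectory_window_days: float = 28.0

    # ECG / EMG
    hr_pre_s: float = 15.0
    hr_post_s: float = 15.0
    ecg_band_hz: tuple[float, float] = (12.0, 40.0)
    emg_band_hz: tuple[float, float] = (10.0, 500.0)
    emg_notches_hz: tuple[float, ...] = (50.0, 100.0, 150.0)

    # Classifier
    n_trees: int = 500
    min_leaf: int = 3
    n_surrogates: int = 5

    # Inference
    n_perm: int = 10_000
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("erp_window_s", "ersp_window_s", "ecg_band_hz", "emg_band_hz",
                "emg_notches_hz", "ersp_baseline_s"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "pma_range_weeks" in data and isinstance(data["pma_range_weeks"], list):
        data["pma_range_weeks"] = tuple(data["pma_range_weeks"])
    return CohortConfig(**data)
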