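"""Cohort readers and writers.

The interchange format is plain CSV: a long-format signals table
(infant_id, modality, condition, t_s, value), a demographics table
(infant_id, pma_days, pna_days), a behaviour table (brow-bulge
durations), a missing-feature table, and the cohort configuration as
YAML.  Times are seconds relative to the stimulus; PMA is in days.
EDF recordings with a stimulus annotation can be read through mne.
Signals sampled below the working EEG rate are upsampled (polyphase
resampling), preserving duration.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly

from .config import CohortConfig
from .synthetic import CONDITIONS, InfantRecord

_MODALITIES = ("eeg", "ecg", "emg_ipsi", "emg_contra")


def write_cohort_csv(records: list[InfantRecord], out_dir,
                     config: CohortConfig | None = None) -> dict:
    """Write a cohort as long-format CSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_chunks = []
    for rec in records:
        for cond in CONDITIONS:
            traces = {
                "eeg": (rec.eeg[cond], rec.eeg_sfreq, -2.5),
                "ecg": (rec.ecg[cond], rec.ecg_sfreq, -30.0),
                "emg_ipsi": (rec.emg[cond]["ipsi"], rec.emg_sfreq, -5.0),
                "emg_contra": (rec.emg[cond]["contra"], rec.emg_sfreq, -5.0),
            }
            for modality, (x, sf, t0) in traces.items():
                t = t0 + np.arange(x.size) / sf
                sig_chunks.append(pd.DataFrame(
                    {"infant_id": rec.infant_id, "modality": modality,
                     "condition": cond, "t_s": t, "value": x}))
    pd.concat(sig_chunks, ignore_index=True).to_csv(
        out / "signals.csv", index=False)
    pd.DataFrame(
        {"infant_id": [r.infant_id for r in records],
         "pma_days": [r.pma_days for r in records],
         "pna_days": [r.pna_days for r in records]}).to_csv(
        out / "demographics.csv", index=False)
    pd.DataFrame(
        [{"infant_id": r.infant_id, "condition": c,
          "brow_bulge_s": r.brow_bulge_s[c]}
         for r in records for c in CONDITIONS]).to_csv(
        out / "behavior.csv", index=False)
    missing_rows = [{"infant_id": r.infant_id, "condition": c, "feature": f}
                    for r in records for c in CONDITIONS
                    for f in sorted(r.missing[c])]
    pd.DataFrame(missing_rows,
                 columns=["infant_id", "condition", "feature"]).to_csv(
        out / "missing.csv", index=False)
    if config is not None:
        with open(out / "cohort_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)
    return {name: out / f"{name}.csv"
            for name in ("signals", "demographics", "behavior", "missing")}


def _infer_sfreq(t_s: np.ndarray) -> float:
    dt = np.median(np.diff(t_s))
    return float(round(1.0 / dt))


def read_cohort_csv(in_dir, target_eeg_sfreq: float = 2000.0) -> list[InfantRecord]:
    """Read a long-format CSV cohort back into InfantRecords.

    Rows may arrive in any order (they are time-sorted per trace).  EEG
    sampled below ``target_eeg_sfreq`` is upsampled, duration preserved.
    """
    src = Path(in_dir)
    signals = pd.read_csv(src / "signals.csv")
    demo = pd.read_csv(src / "demographics.csv").set_index("infant_id")
    behavior = pd.read_csv(src / "behavior.csv")
    missing_path = src / "missing.csv"
    missing = (pd.read_csv(missing_path) if missing_path.exists()
               else pd.DataFrame(columns=["infant_id", "condition", "feature"]))
    records = []
    for iid, grp in signals.groupby("infant_id", sort=True):
        rec = InfantRecord(infant_id=str(iid),
                           pma_days=int(demo.loc[iid, "pma_days"]),
                           pna_days=int(demo.loc[iid, "pna_days"]))
        for cond in CONDITIONS:
            rec.emg[cond] = {}
            rec.missing[cond] = set(
                missing.query("infant_id == @iid and condition == @cond")
                ["feature"])
            bb = behavior.query("infant_id == @iid and condition == @cond")
            rec.brow_bulge_s[cond] = float(bb["brow_bulge_s"].iloc[0])
            for modality in _MODALITIES:
                tr = grp[(grp["modality"] == modality)
                         & (grp["condition"] == cond)].sort_values("t_s")
                if tr.empty:
                    continue
                x = tr["value"].to_numpy(float)
                sf = _infer_sfreq(tr["t_s"].to_numpy(float))
                if modality == "eeg":
                    if sf < target_eeg_sfreq:
                        up = int(round(target_eeg_sfreq / sf))
                        x = resample_poly(x, up, 1)
                        sf = sf * up
                    rec.eeg[cond], rec.eeg_sfreq = x, sf
                elif modality == "ecg":
                    rec.ecg[cond], rec.ecg_sfreq = x, sf
                else:
                    side = modality.split("_")[1]
                    rec.emg[cond][side] = x
                    rec.emg_sfreq = sf
        records.append(rec)
    return records


def read_recordings(paths, fmt: str = "csv", **kwargs) -> list[InfantRecord]:
    """Read infant recordings from CSV (directory) or EDF (file list).

    EDF files must carry a stimulus annotation; one file per infant per
    modality, named ``<infant>_<modality>_<condition>.edf``.
    """
    if fmt == "csv":
        return read_cohort_csv(paths, **kwargs)
    if fmt == "edf":
        return _read_edf_files(paths, **kwargs)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edf_files(paths, stim_label: str = "stimulus",
                    target_eeg_sfreq: float = 2000.0) -> list[InfantRecord]:
    import mne

    by_infant: dict[str, InfantRecord] = {}
    for path in paths:
        path = Path(path)
        infant, modality, cond = path.stem.rsplit("_", 2)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        onsets = [a["onset"] for a in raw.annotations
                  if stim_label in a["description"]]
        if not onsets:
            raise ValueError(f"{path.name}: no {stim_label!r} annotation; "
                             "file rejected")
        x = raw.get_data()[0] * (1e6 if modality == "eeg" else 1.0)
        sf = raw.info["sfreq"]
        if modality == "eeg" and sf < target_eeg_sfreq:
            up = int(round(target_eeg_sfreq / sf))
            x, sf = resample_poly(x, up, 1), sf * up
        rec = by_infant.setdefault(
            infant, InfantRecord(infant_id=infant, pma_days=0, pna_days=0))
        rec.missing.setdefault(cond, set())
        if modality == "eeg":
            rec.eeg[cond], rec.eeg_sfreq = x, sf
        elif modality == "ecg":
            rec.ecg[cond], rec.ecg_sfreq = x, sf
        elif modality.startswith("emg"):
            rec.emg.setdefault(cond, {})[modality.split("_")[1]] = x
            rec.emg_sfreq = sf
    return list(by_infant.values())
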