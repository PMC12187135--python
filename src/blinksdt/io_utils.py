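"""Serialization: CSV for trial records and contingency counts, JSON for
parameters and statistics, HDF5 for epoched EEG and coherograms, YAML for
configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import ContingencyData
from .coherence import Coherogram
from .sdt_geometry import CONTRASTS, LAGS_MS, ModelParameters
from .synthetic_eeg import EpochedEEG

__all__ = [
    "trials_to_csv", "trials_from_csv",
    "contingency_to_csv", "contingency_from_csv",
    "params_to_json", "params_from_json",
    "save_eeg", "load_eeg",
    "save_coherogram", "load_coherogram",
    "write_json", "config_hash",
]


def trials_to_csv(trials: pd.DataFrame, path) -> None:
    cols = ["trial_id", "block", "lag_ms", "contrast", "t2_state", "t1_correct", "response"]
    cols = [c for c in cols if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def trials_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "contrast" in df:
        df["contrast"] = df["contrast"].where(df["contrast"].notna(), None)
    return df


def contingency_to_csv(data: ContingencyData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def contingency_from_csv(path) -> ContingencyData:
    df = pd.read_csv(path)
    df["contrast"] = df["contrast"].where(df["contrast"].notna(), None)
    return ContingencyData.from_frame(df)


def params_to_json(params: ModelParameters, path=None) -> str:
    """Serialize model parameters keyed by lag and contrast."""
    payload = {
        "lags_ms": list(LAGS_MS),
        "contrasts": list(CONTRASTS),
        "d_det": {str(lag): {con: params.d_det[li, ci] for ci, con in enumerate(CONTRASTS)}
                  for li, lag in enumerate(LAGS_MS)},
        "d_dis": {str(lag): {con: params.d_dis[li, ci] for ci, con in enumerate(CONTRASTS)}
                  for li, lag in enumerate(LAGS_MS)},
        "t_det": {str(lag): params.t_det[li] for li, lag in enumerate(LAGS_MS)},
        "c_dis": {str(lag): params.c_dis[li] for li, lag in enumerate(LAGS_MS)},
        "beta": {str(lag): params.beta[li] for li, lag in enumerate(LAGS_MS)},
        "tie_mask": params.tie_mask,
    }
    text = json.dumps(payload, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_json(source) -> ModelParameters:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(source)
    d_det = np.array([[payload["d_det"][str(lag)][con] for con in CONTRASTS]
                      for lag in LAGS_MS])
    d_dis = np.array([[payload["d_dis"][str(lag)][con] for con in CONTRASTS]
                      for lag in LAGS_MS])
    t_det = np.array([payload["t_det"][str(lag)] for lag in LAGS_MS])
    c_dis = np.array([payload["c_dis"][str(lag)] for lag in LAGS_MS])
    beta = np.array([payload["beta"][str(lag)] for lag in LAGS_MS])
    return ModelParameters(d_det=d_det, d_dis=d_dis, t_det=t_det, c_dis=c_dis, beta=beta,
                           tie_mask=payload.get("tie_mask"))


def save_eeg(eeg: EpochedEEG, path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data, compression="gzip", compression_opts=4)
        f.create_dataset("times", data=eeg.times)
        f.attrs["sfreq"] = eeg.sfreq
        f.attrs["ch_names"] = list(eeg.ch_names)
        lab = f.create_group("labels")
        for col in eeg.labels.columns:
            vals = eeg.labels[col].to_numpy()
            if vals.dtype == object:
                vals = np.array(["" if v is None else str(v) for v in vals], dtype="S16")
            lab.create_dataset(col, data=vals)
        for key, val in (meta or {}).items():
            f.attrs[key] = val


def load_eeg(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = tuple(str(c) for c in f.attrs["ch_names"])
        labels = {}
        for col in f["labels"]:
            vals = f["labels"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() or None for v in vals], dtype=object)
            labels[col] = vals
    return EpochedEEG(data=data, ch_names=ch_names, sfreq=sfreq, times=times,
                      labels=pd.DataFrame(labels))


def save_coherogram(cohg: Coherogram, path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cohg.values)
        f.create_dataset("times", data=cohg.times)
        f.create_dataset("freqs", data=cohg.freqs)
        f.attrs["lag_group"] = list(cohg.lag_group)
        f.attrs["normalized"] = cohg.normalized
        f.attrs["cr_subtracted"] = cohg.cr_subtracted
        for key, val in (meta or {}).items():
            f.attrs[key] = val


def load_coherogram(path) -> Coherogram:
    with h5py.File(path, "r") as f:
        return Coherogram(values=f["values"][()], times=f["times"][()], freqs=f["freqs"][()],
                          lag_group=tuple(int(l) for l in f.attrs["lag_group"]),
                          normalized=bool(f.attrs["normalized"]),
                          cr_subtracted=bool(f.attrs["cr_subtracted"]))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a (YAML-serializable) configuration mapping."""
    text = yaml.safe_dump(config_dict, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
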