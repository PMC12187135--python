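"""Detection and discrimination neural dimensions.

At each time point, the mean activity over a 33-channel occipito-parietal
subset forms one vector per stimulus class (CW, CCW, absent).  After
subtracting the correct-rejection (T2-absent) mean — which removes the
stream-evoked component — the detection dimension ``eta_det`` is the
vector mean of the two T2-present class vectors, and the discrimination
dimension ``eta_dis`` is their difference.  The Euclidean norm of each
dimension is the inter-class distance: how separable the neural
representations are along that axis.  Distances are equalized across
lags by bootstrap-resampling every lag down to the minimum trial count,
and reported relative to the longest (900 ms) lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdt_geometry import LAGS_MS
from .synthetic_eeg import EpochedEEG, OCCIPITO_PARIETAL_33

__all__ = ["NeuralDimensions", "compute_dimensions", "equalized_distances"]


@dataclass
class NeuralDimensions:
    """Per-timepoint detection/discrimination dimensions at one lag."""

    lag_ms: int
    channels: tuple
    times: np.ndarray
    eta_det: np.ndarray   # (n_times, n_channels)
    eta_dis: np.ndarray   # (n_times, n_channels)

    @property
    def det_norm(self) -> np.ndarray:
        return np.linalg.norm(self.eta_det, axis=1)

    @property
    def dis_norm(self) -> np.ndarray:
        return np.linalg.norm(self.eta_dis, axis=1)


def _class_masks(eeg: EpochedEEG, lag: int, t1_correct_only: bool = True):
    lab = eeg.labels
    keep = np.ones(len(lab), dtype=bool)
    if t1_correct_only and "t1_correct" in lab:
        keep &= lab["t1_correct"].to_numpy(dtype=bool)
    in_lag = keep & (lab["lag_ms"].to_numpy() == int(lag))
    state = lab["t2_state"].to_numpy()
    masks = {
        "CW": in_lag & (state == "CW"),
        "CCW": in_lag & (state == "CCW"),
        "CR": in_lag & lab["is_cr"].to_numpy(dtype=bool),
    }
    return masks


def compute_dimensions(eeg: EpochedEEG, lag: int, subtract_cr: bool = True,
                       channels=None, t1_correct_only: bool = True) -> NeuralDimensions:
    """Class-mean activity vectors and the derived dimensions at one lag.

    ``eta_det`` is the mean of the CW and CCW class vectors (each taken
    relative to the correct-rejection mean when ``subtract_cr`` is set);
    ``eta_dis`` is the CW minus CCW vector.
    """
    channels = tuple(channels) if channels is not None else tuple(
        ch for ch in OCCIPITO_PARIETAL_33 if ch in eeg.ch_names)
    ch = eeg.channel_index(channels)
    masks = _class_masks(eeg, lag, t1_correct_only)
    needed = ["CW", "CCW"] + (["CR"] if subtract_cr else [])
    for cls in needed:
        if not np.any(masks[cls]):
            raise ValueError(f"no {cls} trials at lag {lag}")
    mean = {cls: eeg.data[np.ix_(np.flatnonzero(masks[cls]), ch)].mean(axis=0).T
            for cls in needed}  # (n_times, n_channels)
    cw, ccw = mean["CW"], mean["CCW"]
    if subtract_cr:
        cw = cw - mean["CR"]
        ccw = ccw - mean["CR"]
    return NeuralDimensions(lag_ms=int(lag), channels=channels, times=eeg.times,
                            eta_det=(cw + ccw) / 2.0, eta_dis=cw - ccw)


def equalized_distances(eeg: EpochedEEG, n_boot: int = 10, window: tuple = (0.3, 0.6),
                        seed: int | None = 0, subtract_cr: bool = True, channels=None,
                        lags=LAGS_MS, t1_correct_only: bool = True) -> pd.DataFrame:
    """Bootstrap-equalized, lag-900-normalized inter-class distances.

    For each bootstrap draw, every lag's trials are resampled with
    replacement down to the per-class minimum count across lags (removing
    the positive norm bias differential caused by unequal trial counts),
    the per-timepoint ``||eta_det||`` and ``||eta_dis||`` are averaged
    over ``window``, and the draws are averaged.  Each lag's value is
    finally divided by the longest-lag (900 ms) value, which is 1 by
    construction.  Deterministic under a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    channels = tuple(channels) if channels is not None else tuple(
        ch for ch in OCCIPITO_PARIETAL_33 if ch in eeg.ch_names)
    ch = eeg.channel_index(channels)
    tsel = np.flatnonzero((eeg.times >= window[0] - 1e-9) & (eeg.times <= window[1] + 1e-9))
    if len(tsel) == 0:
        raise ValueError("distance window contains no samples")
    rng = np.random.default_rng(seed)

    per_lag_idx = {}
    for lag in lags:
        masks = _class_masks(eeg, lag, t1_correct_only)
        idx = {cls: np.flatnonzero(masks[cls]) for cls in ("CW", "CCW", "CR")}
        for cls in ("CW", "CCW") + (("CR",) if subtract_cr else ()):
            if len(idx[cls]) == 0:
                raise ValueError(f"no {cls} trials at lag {lag}")
        per_lag_idx[lag] = idx
    n_min = {cls: min(len(per_lag_idx[lag][cls]) for lag in lags)
             for cls in ("CW", "CCW", "CR")}

    det = {lag: 0.0 for lag in lags}
    dis = {lag: 0.0 for lag in lags}
    sub = eeg.data[:, ch][:, :, tsel]  # trials x channels x window-samples
    for _ in range(n_boot):
        for lag in lags:
            idx = per_lag_idx[lag]
            means = {}
            for cls in ("CW", "CCW") + (("CR",) if subtract_cr else ()):
                draw = rng.choice(idx[cls], size=max(n_min[cls], 1), replace=True)
                means[cls] = sub[draw].mean(axis=0)  # (channels, window-samples)
            cw, ccw = means["CW"], means["CCW"]
            if subtract_cr:
                cw = cw - means["CR"]
                ccw = ccw - means["CR"]
            det[lag] += np.linalg.norm((cw + ccw) / 2.0, axis=0).mean()
            dis[lag] += np.linalg.norm(cw - ccw, axis=0).mean()
    rows = []
    ref_det, ref_dis = det[900] / n_boot, dis[900] / n_boot
    for lag in lags:
        rows.append((lag, det[lag] / n_boot / ref_det, dis[lag] / n_boot / ref_dis,
                     det[lag] / n_boot, dis[lag] / n_boot))
    return pd.DataFrame(rows, columns=["lag_ms", "det_norm_rel", "dis_norm_rel",
                                       "det_norm", "dis_norm"])
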