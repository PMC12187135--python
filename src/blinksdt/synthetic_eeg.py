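"""Synthetic T2-locked epoched EEG with known ground truth.

Every downstream neural analysis in this package (correct-rejection
subtracted ERPs, frontoparietal multitaper coherence, detection and
discrimination neural dimensions) is exercised on data from this
generator.  Each trial is built additively from

* a common stimulus-evoked template present on every trial (including
  T2-absent ones), so that correct-rejection subtraction cancels it
  exactly;
* Gaussian-windowed ERP deflections on component-specific electrode sets,
  with per-lag amplitudes (present trials only);
* a class-dependent spatial pattern over the 33-channel occipito-parietal
  subset, active in a stated window: clockwise trials receive
  ``eta_det + eta_dis / 2``, counterclockwise trials ``eta_det -
  eta_dis / 2``, with configurable per-lag magnitudes;
* 24 Hz oscillations in frontal and parietal channels whose phase offset
  is von-Mises distributed with a per-lag concentration kappa on present
  trials (uniform offset on absent trials), yielding a monotone
  kappa -> coherence mapping;
* AR(1) noise with optional uniform inter-channel correlation.

The 10 Hz RSVP steady-state component is not injected by default (data
are emitted as if it had already been removed by a bandstop filter); an
optional flag adds it back for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sdt_geometry import LAGS_MS

__all__ = [
    "EpochedEEG",
    "EEGGenConfig",
    "ERPComponentGen",
    "generate_eeg_dataset",
    "DEFAULT_CHANNELS",
    "OCCIPITO_PARIETAL_33",
    "FRONTAL",
    "PARIETAL",
]

FRONTAL = ("F3", "Fz", "F4")
CENTRAL = ("C3", "Cz", "C4")
PARIETAL = ("P3", "Pz", "P4")

# Named occipito-parietal subset used for the neural-dimension analyses.
OCCIPITO_PARIETAL_33: tuple[str, ...] = (
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9", "P10", "Pz",
    "PO3", "PO4", "PO5", "PO6", "PO7", "PO8", "PO9", "PO10", "POz",
    "O1", "O2", "Oz", "O9", "O10", "Iz",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz",
)

DEFAULT_CHANNELS: tuple[str, ...] = FRONTAL + CENTRAL + ("TP7", "TP8") + OCCIPITO_PARIETAL_33

N2P_ELECTRODES = ("O1", "O2", "Oz", "P3", "P4", "Pz", "PO3", "PO4", "POz", "PO7", "PO8")


@dataclass
class ERPComponentGen:
    """One planted ERP deflection: Gaussian bump on an electrode set."""

    name: str
    channels: tuple
    center_s: float
    width_s: float
    amplitude_by_lag: np.ndarray  # microvolt, signed; one entry per lag

    def __post_init__(self):
        self.amplitude_by_lag = np.asarray(self.amplitude_by_lag, dtype=float)
        if self.width_s <= 0:
            raise ValueError("component width must be positive")
        if self.amplitude_by_lag.shape != (len(LAGS_MS),):
            raise ValueError("amplitude_by_lag needs one entry per lag")


def _default_components() -> list[ERPComponentGen]:
    return [
        # early sensory component: no lag modulation
        ERPComponentGen("P1", ("P7", "P8"), 0.090, 0.020, [2.0] * 5),
        # late components suppressed at short lags
        ERPComponentGen("N2p", N2P_ELECTRODES, 0.225, 0.040, [-2.0, -2.1, -2.3, -2.5, -2.5]),
        ERPComponentGen("P2", CENTRAL + FRONTAL, 0.225, 0.040, [1.3, 1.35, 1.4, 1.5, 1.5]),
        ERPComponentGen("P3", PARIETAL, 0.425, 0.080, [2.0, 2.1, 2.4, 2.5, 2.5]),
    ]


@dataclass
class EEGGenConfig:
    """Generator settings; defaults emulate the study's blink modulation."""

    sfreq: float = 250.0
    tmin: float = -0.3
    tmax: float = 0.7
    channels: tuple = DEFAULT_CHANNELS
    erp_components: list = field(default_factory=_default_components)
    # common stimulus-evoked template (all trials incl. absent)
    template_amplitude: float = 1.5
    # class-separated spatial patterns over the 33-channel subset
    pattern_channels: tuple = OCCIPITO_PARIETAL_33
    eta_det_by_lag: np.ndarray = field(
        default_factory=lambda: np.array([2.0, 2.2, 2.8, 3.2, 3.4]))
    eta_dis_by_lag: np.ndarray = field(
        default_factory=lambda: np.array([1.2, 1.3, 1.7, 2.0, 2.1]))
    pattern_window: tuple = (0.3, 0.6)
    # frontoparietal beta oscillation
    osc_freq: float = 24.0
    osc_amplitude: float = 1.5
    kappa_by_lag: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.3, 2.0, 6.0, 6.0]))
    osc_window: tuple = (0.0, 0.3)
    frontal_channels: tuple = FRONTAL
    parietal_channels: tuple = PARIETAL
    # noise
    noise_sd: float = 3.0
    ar_coef: float = 0.9
    channel_corr: float = 0.2
    # 10 Hz RSVP steady-state component (off: data emitted post-removal)
    inject_rsvp_10hz: bool = False
    rsvp_amplitude: float = 1.0
    t1_accuracy: float = 0.875

    def __post_init__(self):
        self.eta_det_by_lag = np.asarray(self.eta_det_by_lag, dtype=float)
        self.eta_dis_by_lag = np.asarray(self.eta_dis_by_lag, dtype=float)
        self.kappa_by_lag = np.asarray(self.kappa_by_lag, dtype=float)
        if np.any(self.kappa_by_lag < 0):
            raise ValueError("phase-coupling concentration kappa must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not 0 <= self.channel_corr < 1:
            raise ValueError("channel_corr must lie in [0, 1)")
        for comp in self.erp_components:
            unknown = set(comp.channels) - set(self.channels)
            if unknown:
                raise ValueError(f"component {comp.name} references unknown channels "
                                 f"{sorted(unknown)}")
        for group in (self.pattern_channels, self.frontal_channels, self.parietal_channels):
            unknown = set(group) - set(self.channels)
            if unknown:
                raise ValueError(f"config references unknown channels {sorted(unknown)}")


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: trials x channels x time, T2-locked."""

    data: np.ndarray
    ch_names: tuple
    sfreq: float
    times: np.ndarray
    labels: pd.DataFrame  # per-trial: lag_ms, t2_state, contrast, t1_correct, is_cr
    ground_truth: dict | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel-name count does not match data")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time-axis length does not match data")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label rows must align with the trial axis")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")

    def channel_index(self, names) -> np.ndarray:
        lookup = {ch: i for i, ch in enumerate(self.ch_names)}
        missing = [ch for ch in names if ch not in lookup]
        if missing:
            raise ValueError(f"channels not present: {missing}")
        return np.array([lookup[ch] for ch in names])

    def select_trials(self, mask: np.ndarray) -> "EpochedEEG":
        return EpochedEEG(data=self.data[mask], ch_names=self.ch_names, sfreq=self.sfreq,
                          times=self.times, labels=self.labels[mask].reset_index(drop=True),
                          ground_truth=self.ground_truth)


def _gauss_bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def _window_profile(times: np.ndarray, window: tuple) -> np.ndarray:
    """Hann-shaped temporal profile supported on ``window``."""
    lo, hi = window
    prof = np.zeros_like(times)
    sel = (times >= lo) & (times <= hi)
    if hi > lo:
        prof[sel] = 0.5 * (1 - np.cos(2 * np.pi * (times[sel] - lo) / (hi - lo)))
    return prof


def _pattern_vectors(n_ch: int, salt: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed unit pattern directions for eta_det / eta_dis (orthogonalized)."""
    rng = np.random.default_rng(987654321 + salt)
    a = rng.standard_normal(n_ch)
    b = rng.standard_normal(n_ch)
    a /= np.linalg.norm(a)
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


def generate_eeg_dataset(design: pd.DataFrame, config: EEGGenConfig | None = None,
                         seed: int | None = 0) -> EpochedEEG:
    """Generate an epoched dataset for every trial of a behavioral design.

    ``design`` needs ``lag_ms`` and ``t2_state`` columns; ``contrast``,
    ``t1_correct`` and ``response`` are carried into the labels when
    present (absent trials whose response is "none" are flagged as
    correct rejections; without responses every absent trial counts as a
    correct rejection).  Bit-identical output under a fixed seed.
    """
    config = config or EEGGenConfig()
    if len(design) == 0:
        raise ValueError("design must contain at least one trial")
    design = design.reset_index(drop=True)
    rng = np.random.default_rng(seed)

    n_samp = int(round((config.tmax - config.tmin) * config.sfreq))
    times = config.tmin + np.arange(n_samp) / config.sfreq
    chans = tuple(config.channels)
    n_trials, n_ch = len(design), len(chans)
    ch_idx = {ch: i for i, ch in enumerate(chans)}

    lag = design["lag_ms"].to_numpy().astype(int)
    lag_pos = np.searchsorted(LAGS_MS, lag)
    state = design["t2_state"].to_numpy()
    present = state != "absent"

    data = np.zeros((n_trials, n_ch, n_samp))

    # common stimulus-evoked template on every trial
    template = config.template_amplitude * (
        _gauss_bump(times, 0.12, 0.05) - 0.6 * _gauss_bump(times, 0.30, 0.08))
    data += template[None, None, :]

    # ERP components on present trials
    for comp in config.erp_components:
        idx = [ch_idx[c] for c in comp.channels]
        bump = _gauss_bump(times, comp.center_s, comp.width_s)
        amps = np.where(present, comp.amplitude_by_lag[lag_pos], 0.0)
        data[:, idx, :] += amps[:, None, None] * bump[None, None, :]

    # class-separated spatial patterns in the occipito-parietal subspace
    pat_idx = [ch_idx[c] for c in config.pattern_channels]
    det_dir, dis_dir = _pattern_vectors(len(pat_idx), salt=0)
    profile = _window_profile(times, config.pattern_window)
    cls_sign = np.where(state == "CW", 0.5, np.where(state == "CCW", -0.5, 0.0))
    det_amp = np.where(present, config.eta_det_by_lag[lag_pos], 0.0)
    dis_amp = np.where(present, config.eta_dis_by_lag[lag_pos], 0.0) * cls_sign
    spatial = det_amp[:, None] * det_dir[None, :] + dis_amp[:, None] * dis_dir[None, :]
    data[:, pat_idx, :] += spatial[:, :, None] * profile[None, None, :]

    # frontoparietal beta oscillations with lag-dependent phase coupling
    if config.osc_amplitude > 0:
        f_idx = [ch_idx[c] for c in config.frontal_channels]
        p_idx = [ch_idx[c] for c in config.parietal_channels]
        env = _window_profile(times, config.osc_window)
        phi = rng.uniform(0, 2 * np.pi, size=n_trials)
        kappa = np.where(present, config.kappa_by_lag[lag_pos], 0.0)
        offset = rng.vonmises(0.0, np.maximum(kappa, 1e-12))
        offset[kappa == 0] = rng.uniform(0, 2 * np.pi, size=int(np.sum(kappa == 0)))
        carrier = 2 * np.pi * config.osc_freq * times
        front = np.cos(carrier[None, :] + phi[:, None]) * env[None, :]
        pari = np.cos(carrier[None, :] + (phi + offset)[:, None]) * env[None, :]
        data[:, f_idx, :] += config.osc_amplitude * front[:, None, :]
        data[:, p_idx, :] += config.osc_amplitude * pari[:, None, :]

    # optional 10 Hz RSVP steady-state component
    if config.inject_rsvp_10hz:
        phase = rng.uniform(0, 2 * np.pi)
        data += config.rsvp_amplitude * np.cos(2 * np.pi * 10.0 * times + phase)[None, None, :]

    # AR(1) noise with optional uniform channel correlation
    if config.noise_sd > 0:
        a = config.ar_coef
        innov_sd = config.noise_sd * np.sqrt(max(1.0 - a * a, 1e-12))
        c = config.channel_corr
        noise = np.empty((n_trials, n_ch, n_samp))
        state_ar = rng.standard_normal((n_trials, n_ch)) * config.noise_sd
        if c > 0:
            shared0 = rng.standard_normal((n_trials, 1))
            state_ar = (np.sqrt(c) * shared0 + np.sqrt(1 - c) * rng.standard_normal(
                (n_trials, n_ch))) * config.noise_sd
        noise[:, :, 0] = state_ar
        for t in range(1, n_samp):
            if c > 0:
                shared = rng.standard_normal((n_trials, 1))
                innov = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.standard_normal(
                    (n_trials, n_ch))
            else:
                innov = rng.standard_normal((n_trials, n_ch))
            noise[:, :, t] = a * noise[:, :, t - 1] + innov_sd * innov
        data += noise

    labels = pd.DataFrame({
        "lag_ms": lag,
        "t2_state": state,
        "contrast": design["contrast"] if "contrast" in design else None,
    })
    if "t1_correct" in design:
        labels["t1_correct"] = design["t1_correct"].astype(bool)
    else:
        labels["t1_correct"] = rng.random(n_trials) < config.t1_accuracy
    if "response" in design:
        labels["is_cr"] = (state == "absent") & (design["response"] == "none")
    else:
        labels["is_cr"] = state == "absent"

    ground_truth = {
        "config": config,
        "eta_det_direction": det_dir,
        "eta_dis_direction": dis_dir,
        "template": template,
    }
    return EpochedEEG(data=data, ch_names=chans, sfreq=config.sfreq, times=times,
                      labels=labels, ground_truth=ground_truth)
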