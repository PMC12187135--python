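"""Multitaper time-frequency coherence between frontal and parietal channels.

Coherence between signals x and y is the magnitude-squared cross
spectrum normalized by the auto spectra,

    C_xy(f) = |G_xy(f)|^2 / (G_xx(f) * G_yy(f)),

estimated with DPSS (Slepian) tapers in sliding windows, averaging the
tapered cross/auto spectra over tapers and trials.  Coherograms can be
divisively normalized frequency-wise by the pre-T2 baseline window and
corrected for the stream-evoked component by subtracting the matched-lag
correct-rejection coherogram before pooling a lag group, mirroring the
ERP analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .synthetic_eeg import EpochedEEG, FRONTAL, PARIETAL

__all__ = ["CoherenceConfig", "Coherogram", "compute_coherogram", "band_coherence",
           "resolve_pair_set", "BILATERAL_PAIRS"]

BILATERAL_PAIRS: tuple = tuple((f, p) for f in FRONTAL for p in PARIETAL)  # 9 pairs

PAIR_SETS = {
    "bilateral": BILATERAL_PAIRS,
    "left": (("F3", "P3"),),
    "right": (("F4", "P4"),),
}


def resolve_pair_set(pair_set) -> tuple:
    """Map a named pair set (bilateral/left/right) or explicit list to pairs."""
    if isinstance(pair_set, str):
        try:
            return PAIR_SETS[pair_set]
        except KeyError:
            raise ValueError(f"unknown pair set {pair_set!r}; "
                             f"expected one of {sorted(PAIR_SETS)}") from None
    return tuple((str(a), str(b)) for a, b in pair_set)


@dataclass
class CoherenceConfig:
    """Multitaper settings: TW = 3 with 5 tapers, 300 ms windows, 50 ms stride."""

    time_halfbandwidth: float = 3.0
    n_tapers: int = 5
    window_s: float = 0.3
    stride_s: float = 0.05
    span: tuple = (-0.2, 0.6)        # requested window-center span
    baseline: tuple = (-0.3, 0.0)    # pre-T2 baseline window
    bands: dict = field(default_factory=lambda: {"low_beta": (13.0, 19.0),
                                                 "high_beta": (20.0, 30.0)})

    def __post_init__(self):
        if self.n_tapers > 2 * self.time_halfbandwidth - 1:
            raise ValueError("need n_tapers <= 2*TW - 1")
        if self.window_s <= 0 or self.stride_s <= 0:
            raise ValueError("window and stride must be positive")


@dataclass
class Coherogram:
    """Coherence values over window centers x frequencies."""

    values: np.ndarray   # (n_times, n_freqs)
    times: np.ndarray    # window centers, s
    freqs: np.ndarray    # Hz
    lag_group: tuple
    normalized: bool
    cr_subtracted: bool


def _window_centers(eeg_times: np.ndarray, config: CoherenceConfig) -> np.ndarray:
    """Requested centers whose full window fits inside the epoch."""
    half = config.window_s / 2.0
    n = int(np.floor((config.span[1] - config.span[0]) / config.stride_s + 1e-9)) + 1
    centers = config.span[0] + config.stride_s * np.arange(n)
    lo, hi = eeg_times[0], eeg_times[-1]
    ok = (centers - half >= lo - 1e-9) & (centers + half <= hi + 1e-9)
    centers = centers[ok]
    if len(centers) == 0:
        raise ValueError("no coherence window fits inside the epoch; "
                         "check window/stride against the epoch length")
    return centers


def _ensemble_coherence(x: np.ndarray, y: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """Coherence of two (n_trials, n_samples) ensembles, averaged over tapers+trials."""
    # spectra: (n_trials, n_tapers, n_freqs)
    xs = rfft(x[:, None, :] * tapers[None, :, :], axis=-1)
    ys = rfft(y[:, None, :] * tapers[None, :, :], axis=-1)
    gxy = np.mean(xs * np.conj(ys), axis=(0, 1))
    gxx = np.mean(np.abs(xs) ** 2, axis=(0, 1))
    gyy = np.mean(np.abs(ys) ** 2, axis=(0, 1))
    denom = gxx * gyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(gxy) ** 2 / denom
    coh[denom == 0] = np.nan
    return coh


def _lag_coherogram(eeg: EpochedEEG, trial_mask: np.ndarray, pairs: tuple,
                    centers: np.ndarray, tapers: np.ndarray, per_pair_baseline,
                    config: CoherenceConfig) -> np.ndarray:
    """Pair-averaged coherogram (optionally baseline-normalized per pair)."""
    idx = np.flatnonzero(trial_mask)
    half = config.window_s / 2.0
    n_freqs = tapers.shape[1] // 2 + 1
    out = np.zeros((len(centers), n_freqs))
    for pi, (a, b) in enumerate(pairs):
        ia, ib = eeg.channel_index([a, b])
        xa = eeg.data[idx, ia, :]
        xb = eeg.data[idx, ib, :]
        pair_vals = np.empty((len(centers), n_freqs))
        for wi, c in enumerate(centers):
            sel = (eeg.times >= c - half - 1e-9) & (eeg.times < c + half - 1e-9)
            sel = np.flatnonzero(sel)[: tapers.shape[1]]
            pair_vals[wi] = _ensemble_coherence(xa[:, sel], xb[:, sel], tapers)
        if per_pair_baseline is not None:
            pair_vals = pair_vals / per_pair_baseline[pi][None, :]
        out += pair_vals
    return out / len(pairs)


def compute_coherogram(eeg: EpochedEEG, pair_set="bilateral", lag_group=(700, 900),
                       config: CoherenceConfig | None = None, normalize: bool = True,
                       subtract_cr: bool = True, t1_correct_only: bool = True) -> Coherogram:
    """Pair-averaged multitaper coherogram for a lag group.

    Per lag, coherence is estimated in sliding windows over T2-present
    trials (tapered cross/auto spectra averaged over tapers and trials,
    then over pairs).  With ``normalize``, each pair's coherogram is
    divided frequency-wise by that pair's coherence in the pre-T2
    baseline window of the same trial ensemble.  With ``subtract_cr``,
    the matched-lag correct-rejection coherogram (same normalization) is
    subtracted.  Per-lag maps are pooled weighted by present-trial
    counts.  Raw (un-normalized, un-subtracted) values lie in [0, 1].
    """
    config = config or CoherenceConfig()
    pairs = resolve_pair_set(pair_set)
    lag_group = tuple(int(l) for l in np.atleast_1d(lag_group))
    n_win = int(round(config.window_s * eeg.sfreq))
    if n_win > len(eeg.times):
        raise ValueError("coherence window longer than the epoch")
    tapers = dpss(n_win, config.time_halfbandwidth, config.n_tapers)
    centers = _window_centers(eeg.times, config)
    freqs = rfftfreq(n_win, 1.0 / eeg.sfreq)

    lab = eeg.labels
    keep = np.ones(len(lab), dtype=bool)
    if t1_correct_only and "t1_correct" in lab:
        keep &= lab["t1_correct"].to_numpy(dtype=bool)
    lag_arr = lab["lag_ms"].to_numpy()
    state = lab["t2_state"].to_numpy()
    is_cr = lab["is_cr"].to_numpy(dtype=bool)

    half = config.window_s / 2.0
    base_center = (config.baseline[0] + config.baseline[1]) / 2.0
    bsel = (eeg.times >= base_center - half - 1e-9) & (eeg.times < base_center + half - 1e-9)
    bsel = np.flatnonzero(bsel)[:n_win]

    def baseline_per_pair(mask):
        idx = np.flatnonzero(mask)
        vals = []
        for a, b in pairs:
            ia, ib = eeg.channel_index([a, b])
            vals.append(_ensemble_coherence(eeg.data[idx, ia][:, bsel],
                                            eeg.data[idx, ib][:, bsel], tapers))
        return vals

    maps, weights = [], []
    for lag in lag_group:
        pres = keep & (lag_arr == lag) & (state != "absent")
        if pres.sum() < 2:
            raise ValueError(f"need at least 2 T2-present trials at lag {lag}")
        base = baseline_per_pair(pres) if normalize else None
        m = _lag_coherogram(eeg, pres, pairs, centers, tapers, base, config)
        if subtract_cr:
            cr = keep & (lag_arr == lag) & is_cr
            if cr.sum() < 2:
                raise ValueError(f"need at least 2 correct-rejection trials at lag {lag}")
            base_cr = baseline_per_pair(cr) if normalize else None
            m = m - _lag_coherogram(eeg, cr, pairs, centers, tapers, base_cr, config)
        maps.append(m)
        weights.append(pres.sum())
    values = np.average(np.stack(maps), axis=0, weights=np.asarray(weights, dtype=float))
    return Coherogram(values=values, times=centers, freqs=freqs, lag_group=lag_group,
                      normalized=normalize, cr_subtracted=subtract_cr)


def band_coherence(cohg: Coherogram, band=(20.0, 30.0), window=(0.0, 0.3)) -> float:
    """Mean coherence over a time x frequency rectangle."""
    tsel = (cohg.times >= window[0] - 1e-9) & (cohg.times <= window[1] + 1e-9)
    fsel = (cohg.freqs >= band[0] - 1e-9) & (cohg.freqs <= band[1] + 1e-9)
    if not np.any(tsel) or not np.any(fsel):
        raise ValueError(f"empty selection for band {band}, window {window}")
    return float(cohg.values[np.ix_(np.flatnonzero(tsel), np.flatnonzero(fsel))].mean())
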