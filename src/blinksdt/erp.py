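"""Correct-rejection-subtracted event-related potentials.

ERPs are computed T2-locked.  Because the rapid serial stream evokes a
strong periodic response on every trial, the average over T2-absent
correct-rejection (CR) trials at the matched lag is subtracted from the
T2-present average, lag by lag, before pooling lags; what remains is the
T2-specific response.  Component amplitudes are quantified as the peak
(signed extremum) of the electrode-averaged trace inside the component's
latency window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_eeg import EpochedEEG

__all__ = ["ERPComponentSpec", "DEFAULT_COMPONENT_SPECS", "compute_erp", "peak_amplitude"]

# "surrounding PO electrodes" for the N2p resolved to a fixed, documented list
_N2P_SET = ("O1", "O2", "Oz", "P3", "P4", "Pz", "PO3", "PO4", "POz", "PO7", "PO8")


@dataclass(frozen=True)
class ERPComponentSpec:
    """A named component: electrode set, latency window (s post T2), polarity."""

    name: str
    electrodes: tuple
    window: tuple  # seconds post T2 onset
    polarity: str  # "positive" or "negative"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if not self.electrodes:
            raise ValueError("electrode set must be nonempty")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must be increasing")


DEFAULT_COMPONENT_SPECS: dict[str, ERPComponentSpec] = {
    "P1": ERPComponentSpec("P1", ("P7", "P8"), (0.040, 0.140), "positive"),
    "N1": ERPComponentSpec("N1", ("P7", "P8"), (0.090, 0.160), "negative"),
    "N2p": ERPComponentSpec("N2p", _N2P_SET, (0.150, 0.300), "negative"),
    "P2": ERPComponentSpec("P2", ("C3", "C4", "Cz", "F3", "F4", "Fz"), (0.150, 0.300),
                           "positive"),
    "P3": ERPComponentSpec("P3", ("P3", "P4", "Pz"), (0.300, 0.550), "positive"),
}


def _baseline_correct(trace: np.ndarray, times: np.ndarray, baseline: tuple) -> np.ndarray:
    sel = (times >= baseline[0]) & (times <= baseline[1])
    if not np.any(sel):
        raise ValueError("baseline window outside the epoch")
    return trace - trace[..., sel].mean(axis=-1, keepdims=True)


def compute_erp(eeg: EpochedEEG, lag_group, electrodes, subtract_cr: bool = True,
                baseline: tuple = (-0.3, 0.0), t1_correct_only: bool = True) -> np.ndarray:
    """Electrode-averaged, CR-subtracted ERP trace pooled over a lag group.

    For each lag in ``lag_group`` the trial-average over T2-present
    trials (electrode mean) is baseline-corrected on the pre-T2 window;
    when ``subtract_cr`` is set, the matched-lag correct-rejection
    average is subtracted first.  Per-lag traces are then pooled weighted
    by their present-trial counts.  Raises when a requested lag has no CR
    trials while subtraction is on.
    """
    lag_group = [int(l) for l in np.atleast_1d(lag_group)]
    ch = eeg.channel_index(tuple(electrodes))
    lab = eeg.labels
    keep = np.ones(len(lab), dtype=bool)
    if t1_correct_only and "t1_correct" in lab:
        keep &= lab["t1_correct"].to_numpy(dtype=bool)

    traces, weights = [], []
    for lag in lag_group:
        in_lag = keep & (lab["lag_ms"].to_numpy() == lag)
        pres = in_lag & (lab["t2_state"].to_numpy() != "absent")
        if not np.any(pres):
            raise ValueError(f"no T2-present trials at lag {lag}")
        trace = eeg.data[np.ix_(np.flatnonzero(pres), ch)].mean(axis=(0, 1))
        trace = _baseline_correct(trace, eeg.times, baseline)
        if subtract_cr:
            cr = in_lag & lab["is_cr"].to_numpy(dtype=bool)
            if not np.any(cr):
                raise ValueError(f"no correct-rejection trials at lag {lag}")
            cr_trace = eeg.data[np.ix_(np.flatnonzero(cr), ch)].mean(axis=(0, 1))
            trace = trace - _baseline_correct(cr_trace, eeg.times, baseline)
        traces.append(trace)
        weights.append(pres.sum())
    weights = np.asarray(weights, dtype=float)
    return np.average(np.stack(traces), axis=0, weights=weights)


def peak_amplitude(trace: np.ndarray, times: np.ndarray, spec: ERPComponentSpec) -> float:
    """Peak value of a trace within a component window.

    Positive-polarity components return the maximum, negative-polarity
    components the (signed) minimum, so N-components come out negative.
    """
    sel = (times >= spec.window[0]) & (times <= spec.window[1])
    if not np.any(sel):
        raise ValueError(f"window {spec.window} contains no samples")
    seg = np.asarray(trace)[..., sel]
    return float(seg.max(axis=-1) if spec.polarity == "positive" else seg.min(axis=-1))
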