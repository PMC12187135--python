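"""Trial-design generation and behavioral psychometrics.

A session consists of blocks of RSVP trials.  T2 appears on exactly
two-thirds of the trials; among present trials, orientation (CW/CCW) and
contrast (low/high) are counterbalanced within each lag, and the T1-T2
lag follows a truncated-geometric schedule over {100, 300, 500, 700,
900} ms.  Responses are tallied, per lag, into two present-condition 2x3
contingency tables (one per contrast) plus one shared absent-condition
row, from which hit/miss/misidentification/false-alarm/correct-rejection
rates, detection and discrimination accuracies, and short-vs-long-lag
blink deficits are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sdt_geometry import CONTRASTS, LAGS_MS, RESPONSES

__all__ = [
    "DesignConfig",
    "ContingencyData",
    "BehavioralMetrics",
    "generate_trial_design",
    "tabulate_responses",
    "summary_metrics",
    "lag_weights",
]

SHORT_LAGS = (100, 300)
LONG_LAGS = (700, 900)
_STIMS = ("CW", "CCW")


@dataclass
class DesignConfig:
    """Session structure: 3 blocks x 312 trials, 2/3 present, geometric lags."""

    n_blocks: int = 3
    trials_per_block: int = 312
    present_fraction: float = 2.0 / 3.0
    lag_ratio: float = 0.85  # geometric decay of lag frequencies across the 5 lags
    lags: tuple = LAGS_MS

    def __post_init__(self):
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block and one trial per block")
        if not 0.0 <= self.present_fraction <= 1.0:
            raise ValueError("present_fraction must be a probability")
        if self.lag_ratio <= 0:
            raise ValueError("lag_ratio must be positive")


def lag_weights(config: DesignConfig) -> np.ndarray:
    """Renormalized truncated-geometric lag weights."""
    w = config.lag_ratio ** np.arange(len(config.lags))
    return w / w.sum()


def _apportion(n: int, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer apportionment by largest remainder; remainder ties broken by seeded draw."""
    exact = n * weights
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    if short > 0:
        frac = exact - base
        # jitter breaks exact ties reproducibly without moving large remainders
        order = np.argsort(-(frac + rng.random(len(weights)) * 1e-9))
        base[order[:short]] += 1
    return base


def generate_trial_design(config: DesignConfig | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Emit a full session as a trial table.

    Columns: ``trial_id``, ``block``, ``lag_ms``, ``t2_state``
    (absent/CW/CCW), ``contrast`` (low/high, None on absent trials).
    Within each lag's present trials the four orientation x contrast
    cells are exactly counterbalanced up to remainders, which are
    assigned by a seeded shuffle; trial order is shuffled within block.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    weights = lag_weights(config)
    rows = []
    for block in range(config.n_blocks):
        tpb = config.trials_per_block
        n_present = int(round(config.present_fraction * tpb))
        n_absent = tpb - n_present
        present_per_lag = _apportion(n_present, weights, rng)
        absent_per_lag = _apportion(n_absent, weights, rng)
        block_rows = []
        for lag, n_lag in zip(config.lags, present_per_lag):
            cells = [(s, c) for s in _STIMS for c in CONTRASTS]
            per_cell = n_lag // 4
            counts = {cell: per_cell for cell in cells}
            extra = n_lag - 4 * per_cell
            if extra:
                order = rng.permutation(4)[:extra]
                for j in order:
                    counts[cells[j]] += 1
            for (s, c), m in counts.items():
                block_rows += [(block, lag, s, c)] * m
        for lag, n_lag in zip(config.lags, absent_per_lag):
            block_rows += [(block, lag, "absent", None)] * n_lag
        order = rng.permutation(len(block_rows))
        rows += [block_rows[i] for i in order]
    df = pd.DataFrame(rows, columns=["block", "lag_ms", "t2_state", "contrast"])
    df.insert(0, "trial_id", np.arange(len(df)))
    return df


@dataclass
class ContingencyData:
    """Per-lag response counts of the 3-AFC task.

    ``present`` has shape (n_lags, n_contrasts, 2 stimuli [CW, CCW],
    3 responses [CW, CCW, none]); ``absent`` has shape (n_lags, 3) and is
    stored once per lag (false alarms and correct rejections do not
    depend on T2 contrast).
    """

    present: np.ndarray
    absent: np.ndarray
    lags: tuple = LAGS_MS

    def __post_init__(self):
        self.present = np.asarray(self.present)
        self.absent = np.asarray(self.absent)
        if self.present.shape != (len(self.lags), len(CONTRASTS), 2, 3):
            raise ValueError("present counts must have shape (lags, contrasts, 2, 3)")
        if self.absent.shape != (len(self.lags), 3):
            raise ValueError("absent counts must have shape (lags, 3)")
        if np.any(self.present < 0) or np.any(self.absent < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.present.sum() + self.absent.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts (columns lag_ms, contrast, t2_state, response, count)."""
        rows = []
        for li, lag in enumerate(self.lags):
            for ci, con in enumerate(CONTRASTS):
                for si, stim in enumerate(_STIMS):
                    for ri, resp in enumerate(RESPONSES):
                        rows.append((lag, con, stim, resp, int(self.present[li, ci, si, ri])))
            for ri, resp in enumerate(RESPONSES):
                rows.append((lag, None, "absent", resp, int(self.absent[li, ri])))
        return pd.DataFrame(rows, columns=["lag_ms", "contrast", "t2_state", "response", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lags: tuple = LAGS_MS) -> "ContingencyData":
        present = np.zeros((len(lags), len(CONTRASTS), 2, 3), dtype=int)
        absent = np.zeros((len(lags), 3), dtype=int)
        for _, row in df.iterrows():
            li = lags.index(int(row["lag_ms"]))
            ri = RESPONSES.index(row["response"])
            if row["t2_state"] == "absent":
                absent[li, ri] += int(row["count"])
            else:
                ci = CONTRASTS.index(row["contrast"])
                si = _STIMS.index(row["t2_state"])
                present[li, ci, si, ri] += int(row["count"])
        return cls(present=present, absent=absent, lags=lags)


def tabulate_responses(trials: pd.DataFrame, require_t1_correct: bool = True) -> ContingencyData:
    """Tally trial records into per-lag contingency tables.

    With ``require_t1_correct`` set, trials with an incorrect T1 response
    are excluded before counting (all-excluded input yields all-zero
    tables, not an error).
    """
    needed = {"lag_ms", "t2_state", "contrast", "response"}
    missing = needed - set(trials.columns)
    if missing:
        raise ValueError(f"trial records missing columns {sorted(missing)}")
    bad = (trials["t2_state"] == "absent") & trials["contrast"].notna()
    if bad.any():
        raise ValueError("absent trials must not carry a contrast label")
    if require_t1_correct:
        if "t1_correct" not in trials.columns:
            raise ValueError("t1_correct column required when filtering on T1 accuracy")
        trials = trials[trials["t1_correct"].astype(bool)]

    present = np.zeros((len(LAGS_MS), len(CONTRASTS), 2, 3), dtype=int)
    absent = np.zeros((len(LAGS_MS), 3), dtype=int)
    lag_idx = {lag: i for i, lag in enumerate(LAGS_MS)}
    for row in trials.itertuples(index=False):
        li = lag_idx[int(row.lag_ms)]
        ri = RESPONSES.index(row.response)
        if row.t2_state == "absent":
            absent[li, ri] += 1
        else:
            present[li, CONTRASTS.index(row.contrast), _STIMS.index(row.t2_state), ri] += 1
    return ContingencyData(present=present, absent=absent)


@dataclass
class BehavioralMetrics:
    """Per-lag rates, accuracies, and short-minus-long-lag deficits."""

    rates: pd.DataFrame            # per lag x contrast: H, MI, M; per lag: FA, CR
    detection_accuracy: pd.DataFrame    # per lag (pooled) and per lag x contrast
    discrimination_accuracy: pd.DataFrame
    deficits: dict = field(default_factory=dict)


def _pooled(series: pd.Series, counts: pd.Series, lags) -> float:
    """Trial-weighted mean of a per-lag metric over a lag pool."""
    num = den = 0.0
    for lag in lags:
        if lag in series.index and np.isfinite(series[lag]):
            num += series[lag] * counts[lag]
            den += counts[lag]
    return num / den if den > 0 else np.nan


def summary_metrics(table: ContingencyData, pooled_detection: bool = True) -> BehavioralMetrics:
    """Compute psychometric rates, accuracies, and blink deficits.

    Detection accuracy at a lag is, by default, the trial-pooled
    proportion ``(n_hit + n_misid + n_cr) / n_total``; setting
    ``pooled_detection=False`` averages the condition-wise rates instead.
    Discrimination accuracy is ``n_hit / n_present``.  Deficits are
    pooled short-lag (100+300 ms) minus pooled long-lag (700+900 ms)
    values, trial-weighted within each pool; zero-trial conditions yield
    NaN rates rather than errors.
    """
    if table.n_trials == 0:
        raise ValueError("empty contingency table")
    lags = table.lags
    pres = table.present.astype(float)
    abs_ = table.absent.astype(float)

    rate_rows = []
    det_rows, dis_rows = [], []
    det_counts, dis_counts = {}, {}
    for li, lag in enumerate(lags):
        n_absent = abs_[li].sum()
        cr = abs_[li, 2] / n_absent if n_absent else np.nan
        fa = (abs_[li, 0] + abs_[li, 1]) / n_absent if n_absent else np.nan
        for ci, con in enumerate(CONTRASTS):
            n_present = pres[li, ci].sum()
            if n_present:
                n_hit = pres[li, ci, 0, 0] + pres[li, ci, 1, 1]
                n_mi = pres[li, ci, 0, 1] + pres[li, ci, 1, 0]
                n_miss = pres[li, ci, :, 2].sum()
                h, mi, m = n_hit / n_present, n_mi / n_present, n_miss / n_present
            else:
                n_hit = n_mi = n_miss = 0.0
                h = mi = m = np.nan
            rate_rows.append((lag, con, h, mi, m, fa, cr))
            if pooled_detection:
                det = ((n_hit + n_mi + abs_[li, 2]) / (n_present + n_absent)
                       if n_present + n_absent else np.nan)
            else:
                det = np.nanmean([h + mi, cr])
            det_rows.append((lag, con, det))
            dis_rows.append((lag, con, n_hit / n_present if n_present else np.nan))
        # contrast-pooled values
        n_present_all = pres[li].sum()
        n_hit_all = pres[li, :, 0, 0].sum() + pres[li, :, 1, 1].sum()
        n_mi_all = pres[li, :, 0, 1].sum() + pres[li, :, 1, 0].sum()
        if pooled_detection:
            det_all = ((n_hit_all + n_mi_all + abs_[li, 2]) / (n_present_all + n_absent)
                       if n_present_all + n_absent else np.nan)
        else:
            det_all = np.nanmean([(n_hit_all + n_mi_all) / n_present_all
                                  if n_present_all else np.nan, cr])
        det_rows.append((lag, "pooled", det_all))
        dis_rows.append((lag, "pooled", n_hit_all / n_present_all if n_present_all else np.nan))
        det_counts[lag] = n_present_all + n_absent
        dis_counts[lag] = n_present_all

    rates = pd.DataFrame(rate_rows, columns=["lag_ms", "contrast", "H", "MI", "M", "FA", "CR"])
    det = pd.DataFrame(det_rows, columns=["lag_ms", "contrast", "accuracy"])
    dis = pd.DataFrame(dis_rows, columns=["lag_ms", "contrast", "accuracy"])

    deficits = {}
    for name, frame, counts in (("detection_accuracy", det, det_counts),
                                ("discrimination_accuracy", dis, dis_counts)):
        ser = frame[frame["contrast"] == "pooled"].set_index("lag_ms")["accuracy"]
        cnt = pd.Series(counts)
        deficits[name] = _pooled(ser, cnt, SHORT_LAGS) - _pooled(ser, cnt, LONG_LAGS)
    for metric in ("H", "MI", "M", "FA", "CR"):
        ser = rates.groupby("lag_ms")[metric].mean()
        cnt = pd.Series(det_counts)
        deficits[metric] = _pooled(ser, cnt, SHORT_LAGS) - _pooled(ser, cnt, LONG_LAGS)

    return BehavioralMetrics(rates=rates, detection_accuracy=det,
                             discrimination_accuracy=dis, deficits=deficits)
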