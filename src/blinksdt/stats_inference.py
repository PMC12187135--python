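"""Inferential layer: permutation-based partial correlations and friends.

The neural-behavioral coupling analyses pool per-participant, per-lag
metric values (after dividing each participant's values by their own
across-lag sum), partial out the competing behavioral parameter, and
assess significance by permuting lag labels within participant,
independently for each measure.  Additional tools: step-down Holm
adjustment, the percentage-bend robust correlation, a cluster-based
permutation test for time-frequency difference maps, and the
normal-approximation Wilcoxon signed-rank z test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .sdt_geometry import LAGS_MS

__all__ = [
    "MetricSeries",
    "normalize_per_participant",
    "partial_correlation_perm",
    "holm_adjust",
    "bend_correlation",
    "cluster_permutation",
    "signed_rank_z",
    "Cluster",
]


@dataclass
class MetricSeries:
    """A participant x lag matrix of one scalar metric."""

    values: pd.DataFrame  # index: participant, columns: the 5 lags
    name: str = ""
    normalized: bool = False

    def __post_init__(self):
        if isinstance(self.values, np.ndarray):
            self.values = pd.DataFrame(self.values, columns=list(LAGS_MS))
        if self.values.shape[1] != len(LAGS_MS):
            raise ValueError(f"metric series needs exactly {len(LAGS_MS)} lag columns")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def normalize_per_participant(m: MetricSeries) -> MetricSeries:
    """Divide each participant's row by its own across-lag sum.

    Rows whose |sum| is below ``1e-9 * max|entry|`` are excluded (set to
    NaN) rather than divided; an all-excluded input is an error.
    """
    vals = m.matrix.copy()
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are handled below
        sums = np.nansum(vals, axis=1)
        scale = np.nanmax(np.abs(vals), axis=1)
        bad = np.abs(sums) < 1e-9 * np.where(scale > 0, scale, 1.0)
        if np.all(bad | ~np.isfinite(sums)):
            raise ValueError("all rows excluded by near-zero across-lag sums")
        out = vals / sums[:, None]
    out[bad] = np.nan
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return MetricSeries(values=df, name=m.name, normalized=True)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (n_rep, n_points) matrices."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = np.sum(xc * yc, axis=-1)
    den = np.sqrt(np.sum(xc * xc, axis=-1) * np.sum(yc * yc, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """First-order partial correlation r_xy.z for stacked rows of points."""
    rxy = _pearson_rows(x, y)
    rxz = _pearson_rows(x, z)
    ryz = _pearson_rows(y, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))


def partial_correlation_perm(x: MetricSeries, y: MetricSeries, control: MetricSeries,
                             n_perm: int = 1000, tail: str = "greater",
                             seed: int | None = 0, normalize: bool = True):
    """Permutation partial correlation between pooled metric series.

    Values are (optionally) normalized per participant, pooled over
    (participant, lag) points, and the partial correlation of x and y
    controlling for ``control`` is computed.  The null distribution
    permutes lag labels within participant, independently for each of the
    three measures; the one-sided p (positive alternative by default) is
    the proportion of null statistics at least as large as the observed
    one, with the observed statistic included (floor ``1/(n_perm+1)``).
    Returns ``(r_p, p)``.
    """
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    mats = []
    for m in (x, y, control):
        mm = normalize_per_participant(m) if normalize and not m.normalized else m
        mats.append(mm.matrix)
    if not (mats[0].shape == mats[1].shape == mats[2].shape):
        raise ValueError("metric series must share the participant x lag shape")
    finite = np.isfinite(mats[0]) & np.isfinite(mats[1]) & np.isfinite(mats[2])
    keep_rows = finite.all(axis=1)
    mats = [m[keep_rows] for m in mats]
    n_part, n_lag = mats[0].shape
    if n_part * n_lag < 3:
        raise ValueError("need at least 3 pooled points")

    xm, ym, zm = mats
    r_obs = float(_partial_r(xm.ravel()[None, :], ym.ravel()[None, :], zm.ravel()[None, :])[0])

    rng = np.random.default_rng(seed)

    def permuted(mat):
        # independent lag-label shuffle within each participant, per replicate
        reps = np.broadcast_to(mat, (n_perm, n_part, n_lag))
        perm = rng.permuted(np.broadcast_to(np.arange(n_lag), (n_perm, n_part, n_lag)), axis=2)
        return np.take_along_axis(reps, perm, axis=2).reshape(n_perm, -1)

    null = _partial_r(permuted(xm), permuted(ym), permuted(zm))
    null = null[np.isfinite(null)]
    if tail == "greater":
        exceed = np.sum(null >= r_obs)
    elif tail == "less":
        exceed = np.sum(null <= r_obs)
    else:
        exceed = np.sum(np.abs(null) >= abs(r_obs))
    p = (1.0 + exceed) / (len(null) + 1.0)
    return r_obs, float(p)


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm-adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def bend_correlation(x, y, bend: float = 0.2) -> float:
    """Percentage-bend correlation (robust to marginal outliers).

    Downweights the proportion ``bend`` of most extreme observations in
    each margin before correlating.  Symmetric in its arguments and in
    [-1, 1].  Raises when a margin's bend scale (the relevant order
    statistic of |x - median|) is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")

    def bent_scores(v):
        med = np.median(v)
        w = np.sort(np.abs(v - med))
        m = int(np.floor((1.0 - bend) * n + 0.5))
        omega = w[m - 1]
        if omega <= 0:
            raise ValueError("zero bend scale (constant-heavy margin)")
        z = (v - med) / omega
        i1 = np.sum(z < -1)
        i2 = np.sum(z > 1)
        sv = np.sum(v[(z >= -1) & (z <= 1)])
        phi = (omega * (i2 - i1) + sv) / (n - i1 - i2)
        return np.clip((v - phi) / omega, -1.0, 1.0)

    a = bent_scores(x)
    b = bent_scores(y)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


@dataclass
class Cluster:
    """One supra-threshold cluster in a time-frequency difference map."""

    mask: np.ndarray
    stat: float
    p: float
    sign: int


def cluster_permutation(diffs: np.ndarray, cluster_alpha: float = 0.05, n_perm: int = 1000,
                        seed: int | None = 0) -> list[Cluster]:
    """Cluster-based permutation test on participant difference maps.

    ``diffs`` has shape (participants, n_times, n_freqs).  A pointwise
    paired t-test against zero forms clusters (8-connectivity) from
    points exceeding the two-sided ``cluster_alpha`` threshold,
    separately for positive and negative effects; each cluster's
    statistic is the sum of its t-values.  The null distribution is the
    maximum absolute cluster statistic under random per-participant sign
    flips; corrected p-values include the observed flip (floor
    ``1/(n_perm+1)``).  A map with no supra-threshold points returns an
    empty list.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 3:
        raise ValueError("diffs must be participants x times x freqs")
    n_part = diffs.shape[0]
    if n_part < 5:
        raise ValueError("need at least 5 participants")
    shape = diffs.shape[1:]
    flat = diffs.reshape(n_part, -1)
    ss = np.sum(flat ** 2, axis=0)  # invariant under sign flips
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, n_part - 1)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity

    def t_map(signs):
        m = signs @ flat / n_part
        var = (ss - n_part * m ** 2) / (n_part - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / np.sqrt(var / n_part)
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)

    def clusters_of(t2d):
        found = []
        for sign in (1, -1):
            lab, n_lab = ndimage.label(sign * t2d > t_crit, structure=structure)
            for i in range(1, n_lab + 1):
                mask = lab == i
                found.append((mask, float(t2d[mask].sum()), sign))
        return found

    t_obs = t_map(np.ones(n_part)).reshape(shape)
    obs_clusters = clusters_of(t_obs)
    if not obs_clusters:
        return []

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_part))
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        tb = t_map(signs[b]).reshape(shape)
        cl = clusters_of(tb)
        if cl:
            null_max[b] = max(abs(c[1]) for c in cl)

    out = []
    for mask, cstat, sign in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(cstat))) / (n_perm + 1.0)
        out.append(Cluster(mask=mask, stat=cstat, p=float(p), sign=sign))
    out.sort(key=lambda c: abs(c.stat), reverse=True)
    return out


def signed_rank_z(x, y):
    """Wilcoxon signed-rank test with the normal (z) approximation.

    Zero differences are dropped; ties share midranks and the variance
    carries the standard tie correction; no continuity correction is
    applied (matching the large-sample z-statistic convention).  Returns
    ``(z, p)`` two-sided; all-zero differences yield ``(nan, nan)``
    (undefined, flagged by NaN rather than an exception).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = np.sum(ranks[d > 0])
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
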