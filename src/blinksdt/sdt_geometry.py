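"""Two-dimensional signal detection geometry for the 3-AFC blink task.

The observer's evidence on a trial is a bivariate decision variable
``psi = (psi_dis, psi_det)``: the horizontal component carries evidence
about target orientation (clockwise vs. counterclockwise of vertical),
the vertical component carries evidence about target presence.  Across
trials ``psi`` is an isotropic unit-variance Gaussian whose mean depends
on the stimulus: the origin when no target is shown, and
``(+/- d_dis, d_det)`` for clockwise/counterclockwise targets at a given
contrast.

An inverted-Y decision surface partitions the plane into three response
zones.  Its junction sits at ``(c_dis, t_det)``; the stem is the upward
vertical ray (separating CW from CCW reports), and the two arms descend
symmetrically at ``+/- beta/2`` from the downward vertical, fencing off
the "none" zone below.  Each zone is a wedge, i.e. an intersection of two
half-planes through the junction, so its Gaussian measure has a closed
form in the bivariate normal CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._bvn import bvn_cdf

__all__ = [
    "LAGS_MS",
    "CONTRASTS",
    "RESPONSES",
    "T2_STATES",
    "ModelParameters",
    "DecisionZones",
    "ConditionSpec",
    "build_decision_zones",
    "condition_mean",
    "response_probabilities",
    "monte_carlo_probabilities",
    "simulate_responses",
]

LAGS_MS: tuple[int, ...] = (100, 300, 500, 700, 900)
CONTRASTS: tuple[str, str] = ("low", "high")
RESPONSES: tuple[str, str, str] = ("CW", "CCW", "none")
T2_STATES: tuple[str, str, str] = ("absent", "CW", "CCW")

N_LAGS = len(LAGS_MS)
N_CONTRASTS = len(CONTRASTS)


@dataclass
class ModelParameters:
    """Parameter set of the 2-D signal detection model.

    ``d_det`` and ``d_dis`` are (n_lags, n_contrasts) arrays of detection
    and discrimination sensitivity (SD units, >= 0); ``d_dis`` is each
    signal mean's offset from the detection axis, so the CW-CCW mean
    separation is ``2 * d_dis``.  ``t_det``, ``c_dis`` and ``beta`` are
    per-lag decision-surface parameters (vertical/horizontal junction
    placement, and the angle between the oblique arms, in radians).
    ``tie_mask`` optionally records which entries were tied during
    fitting (see :mod:`blinksdt.sdt_fitting`).
    """

    d_det: np.ndarray
    d_dis: np.ndarray
    t_det: np.ndarray
    c_dis: np.ndarray
    beta: np.ndarray
    tie_mask: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.d_det = np.asarray(self.d_det, dtype=float)
        self.d_dis = np.asarray(self.d_dis, dtype=float)
        self.t_det = np.asarray(self.t_det, dtype=float)
        self.c_dis = np.asarray(self.c_dis, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.d_det.shape != (N_LAGS, N_CONTRASTS) or self.d_dis.shape != (N_LAGS, N_CONTRASTS):
            raise ValueError("d_det and d_dis must have shape (5 lags, 2 contrasts)")
        for name in ("t_det", "c_dis", "beta"):
            if getattr(self, name).shape != (N_LAGS,):
                raise ValueError(f"{name} must have shape (5 lags,)")
        if not np.all(np.isfinite(self.d_det)) or not np.all(np.isfinite(self.d_dis)) \
                or not np.all(np.isfinite(self.t_det)) or not np.all(np.isfinite(self.c_dis)) \
                or not np.all(np.isfinite(self.beta)):
            raise ValueError("model parameters must be finite")
        if np.any(self.d_det < 0) or np.any(self.d_dis < 0):
            raise ValueError("sensitivities d_det, d_dis must be non-negative")
        if np.any(self.beta <= 0) or np.any(self.beta > np.pi + 1e-12):
            raise ValueError("beta must lie in (0, pi]")

    def lag_index(self, lag_ms: int) -> int:
        try:
            return LAGS_MS.index(int(lag_ms))
        except ValueError:
            raise ValueError(f"unknown lag {lag_ms}; expected one of {LAGS_MS}") from None

    @classmethod
    def uniform(cls, d_det=1.0, d_dis=1.0, t_det=0.5, c_dis=0.0, beta=2.0,
                tie_mask=None) -> "ModelParameters":
        """Build lag/contrast-homogeneous parameters from scalars."""
        return cls(
            d_det=np.full((N_LAGS, N_CONTRASTS), float(d_det)),
            d_dis=np.full((N_LAGS, N_CONTRASTS), float(d_dis)),
            t_det=np.full(N_LAGS, float(t_det)),
            c_dis=np.full(N_LAGS, float(c_dis)),
            beta=np.full(N_LAGS, float(beta)),
            tie_mask=tie_mask,
        )


@dataclass(frozen=True)
class ConditionSpec:
    """One stimulus condition: T2 state plus contrast (None for absent)."""

    t2_state: str
    contrast: str | None = None

    def __post_init__(self):
        if self.t2_state not in T2_STATES:
            raise ValueError(f"t2_state must be one of {T2_STATES}")
        if self.t2_state == "absent":
            if self.contrast is not None:
                raise ValueError("absent condition carries no contrast")
        elif self.contrast not in CONTRASTS:
            raise ValueError(f"present condition needs contrast in {CONTRASTS}")


@dataclass(frozen=True)
class DecisionZones:
    """The three response wedges of the inverted-Y decision surface.

    Each zone is the set ``{p : n1.(p - junction) >= 0 and
    n2.(p - junction) >= 0}`` for its pair of inward unit normals.
    """

    junction: np.ndarray
    beta: float
    normals: dict  # response -> (2, 2) array of inward unit normals

    @property
    def wedge_angles(self) -> dict:
        half = self.beta / 2.0
        return {"CW": np.pi - half, "CCW": np.pi - half, "none": self.beta}

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Classify points (n, 2) into responses.

        Boundary hits (measure zero) resolve by the fixed precedence
        CW > CCW > none.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.junction
        cw = self.normals["CW"]
        ccw = self.normals["CCW"]
        in_cw = (pts @ cw[0] >= 0) & (pts @ cw[1] >= 0)
        in_ccw = (pts @ ccw[0] >= 0) & (pts @ ccw[1] >= 0)
        out = np.where(in_cw, 0, np.where(in_ccw, 1, 2))
        return np.asarray(RESPONSES, dtype=object)[out]


def build_decision_zones(t_det: float, c_dis: float, beta: float) -> DecisionZones:
    """Construct the inverted-Y response zones.

    The junction is ``(c_dis, t_det)``; the stem is the upward vertical
    ray and the arms descend at ``+/- beta/2`` from the downward
    vertical.  ``beta`` must lie in (0, pi]; at ``beta = pi`` the arms
    collapse to the horizontal line through the junction and the "none"
    zone is the lower half-plane.
    """
    beta = float(beta)
    if not (0.0 < beta <= np.pi + 1e-12):
        raise ValueError("beta must lie in (0, pi]")
    half = beta / 2.0
    c, s = np.cos(half), np.sin(half)
    normals = {
        # stem boundary (interior toward +x), right arm boundary
        "CW": np.array([[1.0, 0.0], [c, s]]),
        "CCW": np.array([[-1.0, 0.0], [-c, s]]),
        "none": np.array([[-c, -s], [c, -s]]),
    }
    return DecisionZones(junction=np.array([float(c_dis), float(t_det)]), beta=beta,
                         normals=normals)


def condition_mean(params: ModelParameters, lag_ms: int, condition: ConditionSpec) -> np.ndarray:
    """Mean of the decision variable for a condition at a lag."""
    if condition.t2_state == "absent":
        return np.zeros(2)
    li = params.lag_index(lag_ms)
    ci = CONTRASTS.index(condition.contrast)
    sign = 1.0 if condition.t2_state == "CW" else -1.0
    return np.array([sign * params.d_dis[li, ci], params.d_det[li, ci]])


def _wedge_probabilities(zones: DecisionZones, mean: np.ndarray) -> np.ndarray:
    """Gaussian measure of each wedge for a unit-isotropic mean-``mean`` variate."""
    mu = np.asarray(mean, dtype=float) - zones.junction
    u1 = np.empty(3)
    u2 = np.empty(3)
    rho = np.empty(3)
    for i, resp in enumerate(RESPONSES):
        n1, n2 = zones.normals[resp]
        u1[i] = n1 @ mu
        u2[i] = n2 @ mu
        rho[i] = n1 @ n2
    return bvn_cdf(u1, u2, rho)


def response_probabilities(params: ModelParameters, lag_ms: int,
                           condition: ConditionSpec) -> np.ndarray:
    """P(CW), P(CCW), P(none) for one condition at one lag.

    Each probability is the standard bivariate normal measure (centred on
    the condition mean) of the corresponding response wedge, evaluated in
    closed form.  Raises if the three measures fail to sum to 1 within
    1e-6 (internal consistency guard).
    """
    li = params.lag_index(lag_ms)
    zones = build_decision_zones(params.t_det[li], params.c_dis[li], params.beta[li])
    mean = condition_mean(params, lag_ms, condition)
    probs = _wedge_probabilities(zones, mean)
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise RuntimeError(f"wedge probabilities sum to {total}, violating normalization")
    return probs


def monte_carlo_probabilities(params: ModelParameters, lag_ms: int, condition: ConditionSpec,
                              n_samples: int = 1_000_000, seed: int | None = 0,
                              chunk: int = 1_000_000) -> np.ndarray:
    """Monte-Carlo oracle for :func:`response_probabilities`.

    Draws ``n_samples`` decision variables from the condition
    distribution, classifies them through the decision zones, and returns
    empirical response frequencies.  Sampling is chunked so arbitrarily
    large ``n_samples`` stay memory-bounded.
    """
    li = params.lag_index(lag_ms)
    zones = build_decision_zones(params.t_det[li], params.c_dis[li], params.beta[li])
    mean = condition_mean(params, lag_ms, condition)
    rng = np.random.default_rng(seed)
    counts = np.zeros(3, dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.standard_normal((m, 2)) + mean
        resp = zones.classify(pts)
        for i, r in enumerate(RESPONSES):
            counts[i] += int(np.sum(resp == r))
        remaining -= m
    return counts / float(n_samples)


def simulate_responses(params: ModelParameters, design: pd.DataFrame,
                       t1_accuracy: float = 0.875, seed: int | None = 0) -> pd.DataFrame:
    """Simulate 3-AFC responses for every trial of a design.

    ``design`` needs columns ``lag_ms``, ``t2_state`` and ``contrast``
    (contrast ignored/None on absent trials); ``trial_id`` and ``block``
    are carried through when present.  Each trial's decision variable is
    drawn from its condition distribution and classified through that
    lag's decision zones; a T1-correct flag is drawn independently as
    Bernoulli(``t1_accuracy``).  Deterministic under a fixed seed.
    """
    if not 0.0 <= t1_accuracy <= 1.0:
        raise ValueError("t1_accuracy must be a probability")
    design = design.reset_index(drop=True)
    n = len(design)
    lag_vals = design["lag_ms"].to_numpy()
    unknown = set(np.unique(lag_vals)) - set(LAGS_MS)
    if unknown:
        raise ValueError(f"design contains unknown lag values {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    means = np.zeros((n, 2))
    states = design["t2_state"].to_numpy()
    contrasts = design["contrast"].to_numpy(dtype=object)
    lag_idx = np.searchsorted(LAGS_MS, lag_vals)
    present = states != "absent"
    if np.any(present):
        ci = np.where(contrasts[present] == CONTRASTS[1], 1, 0)
        sign = np.where(states[present] == "CW", 1.0, -1.0)
        li = lag_idx[present]
        means[present, 0] = sign * params.d_dis[li, ci]
        means[present, 1] = params.d_det[li, ci]
    psi = rng.standard_normal((n, 2)) + means
    responses = np.empty(n, dtype=object)
    for lag in LAGS_MS:
        li = params.lag_index(lag)
        sel = lag_vals == lag
        if not np.any(sel):
            continue
        zones = build_decision_zones(params.t_det[li], params.c_dis[li], params.beta[li])
        responses[sel] = zones.classify(psi[sel])
    t1_correct = rng.random(n) < t1_accuracy

    out = pd.DataFrame({
        "trial_id": design["trial_id"] if "trial_id" in design else np.arange(n),
        "block": design["block"] if "block" in design else 0,
        "lag_ms": lag_vals.astype(int),
        "contrast": contrasts,
        "t2_state": states,
        "t1_correct": t1_correct,
        "response": responses,
    })
    return out
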