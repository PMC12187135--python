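"""Maximum-likelihood fitting of the 2-D signal detection model.

Five nested model variants (I-V) impose progressively stronger parameter
ties: Model I estimates every sensitivity per lag and contrast and every
decision-surface parameter per lag (35 free parameters); Model II ties
the arm angle beta across lags (31); Model III additionally ties
discrimination sensitivity across contrasts and the discrimination
criterion across lags (22); Model IV instead ties detection sensitivity
across contrasts and the detection threshold across lags (22); Model V
applies all of these ties (13).  Variants are compared by AIC/BIC, and
absolute fit quality is assessed with a chi-squared randomization test.

The likelihood treats each condition row of the per-lag contingency
tables (two present-condition 2x3 tables per lag plus one absent row,
stored once per lag) as a multinomial whose cell probabilities come from
the closed-form wedge measures in :mod:`blinksdt.sdt_geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._bvn import bvn_cdf
from .behavior import ContingencyData, LONG_LAGS, SHORT_LAGS
from .sdt_geometry import CONTRASTS, LAGS_MS, ModelParameters, N_CONTRASTS, N_LAGS

__all__ = [
    "ModelVariant",
    "MODEL_VARIANTS",
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "DerivedIndices",
    "count_free_parameters",
    "neg_log_likelihood",
    "fit_model",
    "compare_models",
    "goodness_of_fit",
    "derive_indices",
    "simulate_contingency",
]

_PROB_FLOOR = 1e-12

# tie levels: how many free values a family collapses to
_D_LEVELS = {"lag_contrast": N_LAGS * N_CONTRASTS, "lag": N_LAGS, "shared": 1}
_S_LEVELS = {"lag": N_LAGS, "shared": 1}

_BOUNDS = {"d_det": (0.0, 6.0), "d_dis": (0.0, 6.0), "t_det": (-4.0, 6.0),
           "c_dis": (-4.0, 4.0), "beta": (0.1, np.pi)}


@dataclass(frozen=True)
class ModelVariant:
    """A tie specification: one level per parameter family."""

    name: str
    d_det: str = "lag_contrast"
    d_dis: str = "lag_contrast"
    t_det: str = "lag"
    c_dis: str = "lag"
    beta: str = "lag"

    def __post_init__(self):
        for fam, levels in (("d_det", _D_LEVELS), ("d_dis", _D_LEVELS),
                            ("t_det", _S_LEVELS), ("c_dis", _S_LEVELS), ("beta", _S_LEVELS)):
            if getattr(self, fam) not in levels:
                raise ValueError(f"invalid tie level {getattr(self, fam)!r} for {fam}")

    def ties(self) -> dict:
        return {f: getattr(self, f) for f in ("d_det", "d_dis", "t_det", "c_dis", "beta")}


MODEL_VARIANTS: dict[str, ModelVariant] = {
    "I": ModelVariant("I"),
    "II": ModelVariant("II", beta="shared"),
    "III": ModelVariant("III", d_dis="lag", c_dis="shared", beta="shared"),
    "IV": ModelVariant("IV", d_det="lag", t_det="shared", beta="shared"),
    "V": ModelVariant("V", d_det="lag", d_dis="lag", t_det="shared", c_dis="shared",
                      beta="shared"),
}


def count_free_parameters(variant: ModelVariant | str) -> int:
    """Number of independently estimated parameters under the variant's ties."""
    if isinstance(variant, str):
        try:
            variant = MODEL_VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown model variant {variant!r}") from None
    return (_D_LEVELS[variant.d_det] + _D_LEVELS[variant.d_dis]
            + _S_LEVELS[variant.t_det] + _S_LEVELS[variant.c_dis] + _S_LEVELS[variant.beta])


# ---------------------------------------------------------------------------
# packing free vectors <-> full parameter arrays


def _expand_d(theta_fam: np.ndarray, level: str) -> np.ndarray:
    if level == "lag_contrast":
        return theta_fam.reshape(N_LAGS, N_CONTRASTS)
    if level == "lag":
        return np.repeat(theta_fam[:, None], N_CONTRASTS, axis=1)
    return np.full((N_LAGS, N_CONTRASTS), theta_fam[0])


def _expand_s(theta_fam: np.ndarray, level: str) -> np.ndarray:
    return theta_fam if level == "lag" else np.full(N_LAGS, theta_fam[0])


def _slices(variant: ModelVariant):
    sizes = [_D_LEVELS[variant.d_det], _D_LEVELS[variant.d_dis], _S_LEVELS[variant.t_det],
             _S_LEVELS[variant.c_dis], _S_LEVELS[variant.beta]]
    edges = np.cumsum([0] + sizes)
    return [slice(edges[i], edges[i + 1]) for i in range(5)]


def _unpack(theta: np.ndarray, variant: ModelVariant) -> ModelParameters:
    sl = _slices(variant)
    return ModelParameters(
        d_det=_expand_d(theta[sl[0]], variant.d_det),
        d_dis=_expand_d(theta[sl[1]], variant.d_dis),
        t_det=_expand_s(theta[sl[2]], variant.t_det),
        c_dis=_expand_s(theta[sl[3]], variant.c_dis),
        beta=_expand_s(theta[sl[4]], variant.beta),
        tie_mask=variant.ties(),
    )


def _bounds_vector(variant: ModelVariant):
    lo, hi = [], []
    for fam, level_map in (("d_det", _D_LEVELS), ("d_dis", _D_LEVELS), ("t_det", _S_LEVELS),
                           ("c_dis", _S_LEVELS), ("beta", _S_LEVELS)):
        n = level_map[getattr(variant, fam)]
        lo += [_BOUNDS[fam][0]] * n
        hi += [_BOUNDS[fam][1]] * n
    return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# likelihood


def _all_probabilities(d_det, d_dis, t_det, c_dis, beta):
    """Response probabilities for every (lag, condition) cell, vectorized.

    Returns ``present`` with shape (5, 2, 2, 3) over lag x contrast x
    stimulus x response, and ``absent`` with shape (5, 3).
    """
    half = beta / 2.0
    c, s = np.cos(half), np.sin(half)
    zeros = np.zeros(N_LAGS)
    ones = np.ones(N_LAGS)
    # normals[lag, response, which, coord]
    normals = np.empty((N_LAGS, 3, 2, 2))
    normals[:, 0, 0] = np.stack([ones, zeros], axis=1)
    normals[:, 0, 1] = np.stack([c, s], axis=1)
    normals[:, 1, 0] = np.stack([-ones, zeros], axis=1)
    normals[:, 1, 1] = np.stack([-c, s], axis=1)
    normals[:, 2, 0] = np.stack([-c, -s], axis=1)
    normals[:, 2, 1] = np.stack([c, -s], axis=1)
    rho = np.einsum("lrc,lrc->lr", normals[:, :, 0], normals[:, :, 1])  # (5, 3)

    junction = np.stack([c_dis, t_det], axis=1)  # (5, 2)
    sign = np.array([1.0, -1.0])
    mu_present = np.empty((N_LAGS, N_CONTRASTS, 2, 2))  # lag, contrast, stim, coord
    mu_present[..., 0] = d_dis[:, :, None] * sign
    mu_present[..., 1] = d_det[:, :, None]
    rel_p = mu_present - junction[:, None, None, :]
    rel_a = -junction  # absent mean is the origin

    # u[..., response, which] = normal . (mu - junction)
    u_p = np.einsum("lrwc,lxsc->lxsrw", normals, rel_p)
    u_a = np.einsum("lrwc,lc->lrw", normals, rel_a)
    rho_p = np.broadcast_to(rho[:, None, None, :], u_p.shape[:-1])
    present = bvn_cdf(u_p[..., 0], u_p[..., 1], rho_p)
    absent = bvn_cdf(u_a[..., 0], u_a[..., 1], rho)
    return present, absent


def model_probabilities(params: ModelParameters):
    """Present (5,2,2,3) and absent (5,3) response probabilities of a model."""
    return _all_probabilities(params.d_det, params.d_dis, params.t_det,
                              params.c_dis, params.beta)


def neg_log_likelihood(params: ModelParameters, data: ContingencyData) -> float:
    """Negative multinomial log-likelihood of the contingency counts.

    Cell probabilities below 1e-12 are floored before the log so empty
    model cells cannot produce infinities; zero-count cells contribute
    nothing.
    """
    present, absent = model_probabilities(params)
    lp = np.log(np.clip(present, _PROB_FLOOR, None))
    la = np.log(np.clip(absent, _PROB_FLOOR, None))
    return float(-(data.present * lp).sum() - (data.absent * la).sum())


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """Optimizer settings: bounded quasi-Newton with seeded random restarts."""

    n_starts: int = 10
    maxiter: int = 1000
    ftol: float = 1e-10
    gtol: float = 1e-8


@dataclass
class FitResult:
    params: ModelParameters
    loglik: float
    k: int
    n: int
    variant: ModelVariant
    theta: np.ndarray = field(repr=False)
    converged: bool = True
    n_starts: int = 10
    best_start: int = 0
    at_bounds: list = field(default_factory=list)
    start_nlls: np.ndarray | None = field(default=None, repr=False)

    @property
    def nll(self) -> float:
        return -self.loglik


def _default_start(variant: ModelVariant) -> np.ndarray:
    sl = _slices(variant)
    theta = np.empty(count_free_parameters(variant))
    theta[sl[0]] = 1.5  # d_det
    theta[sl[1]] = 1.0  # d_dis
    theta[sl[2]] = 0.8  # t_det
    theta[sl[3]] = 0.0  # c_dis
    theta[sl[4]] = 2.0  # beta
    return theta


def fit_model(data: ContingencyData, variant: ModelVariant | str,
              config: FitConfig | None = None, seed: int | None = 0) -> FitResult:
    """Fit one model variant by maximum likelihood.

    Runs ``config.n_starts`` bounded L-BFGS-B optimizations (one fixed
    mid-range start plus seeded draws from the box d in [0,6], t_det in
    [-4,6], c_dis in [-4,4], beta in [0.1, pi]) and keeps the best.
    Free parameters resting on a bound are listed in ``at_bounds``.
    """
    if isinstance(variant, str):
        variant = MODEL_VARIANTS[variant]
    config = config or FitConfig()
    if data.n_trials == 0:
        raise ValueError("cannot fit an empty contingency table")
    lo, hi = _bounds_vector(variant)
    rng = np.random.default_rng(seed)

    def objective(theta):
        p = _unpack(theta, variant)
        return neg_log_likelihood(p, data)

    best = None
    start_nlls = np.full(config.n_starts, np.inf)
    n_ok = 0
    for i in range(config.n_starts):
        theta0 = _default_start(variant) if i == 0 else rng.uniform(lo, hi)
        try:
            res = minimize(objective, theta0, method="L-BFGS-B",
                           bounds=list(zip(lo, hi)),
                           options={"maxiter": config.maxiter, "ftol": config.ftol,
                                    "gtol": config.gtol})
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        start_nlls[i] = res.fun
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x.copy(), bool(res.success), i)
    if best is None or n_ok == 0:
        raise RuntimeError(f"all {config.n_starts} optimizer starts failed for "
                           f"model {variant.name}")
    nll, theta, success, idx = best
    params = _unpack(theta, variant)
    tol = 1e-6
    names = _theta_names(variant)
    at_bounds = [nm for nm, th, l, h in zip(names, theta, lo, hi)
                 if th - l < tol or h - th < tol]
    return FitResult(params=params, loglik=-nll, k=count_free_parameters(variant),
                     n=data.n_trials, variant=variant, theta=theta, converged=success,
                     n_starts=config.n_starts, best_start=idx, at_bounds=at_bounds,
                     start_nlls=start_nlls)


def _theta_names(variant: ModelVariant) -> list[str]:
    names = []
    for fam, level_map in (("d_det", _D_LEVELS), ("d_dis", _D_LEVELS), ("t_det", _S_LEVELS),
                           ("c_dis", _S_LEVELS), ("beta", _S_LEVELS)):
        level = getattr(variant, fam)
        n = level_map[level]
        if n == 1:
            names.append(fam)
        elif level == "lag":
            names += [f"{fam}[{lag}]" for lag in LAGS_MS]
        else:
            names += [f"{fam}[{lag},{con}]" for lag in LAGS_MS for con in CONTRASTS]
    return names


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    table: pd.DataFrame
    best_aic: str
    best_bic: str


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """AIC/BIC comparison of fits to the same data.

    AIC = 2k - 2 logL; BIC = k ln(n) - 2 logL with n the total trial
    count.  Lower is better for both.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have inconsistent trial counts {sorted(ns)}")
    n = ns.pop()
    rows = []
    for f in fits:
        aic = 2 * f.k - 2 * f.loglik
        bic = f.k * (np.log(n) if n > 0 else 0.0) - 2 * f.loglik
        rows.append((f.variant.name, f.k, n, f.loglik, aic, bic))
    table = pd.DataFrame(rows, columns=["model", "k", "n", "loglik", "aic", "bic"])
    return ModelComparison(table=table,
                           best_aic=table.loc[table["aic"].idxmin(), "model"],
                           best_bic=table.loc[table["bic"].idxmin(), "model"])


# ---------------------------------------------------------------------------
# goodness of fit


def simulate_contingency(params: ModelParameters, row_counts: ContingencyData,
                         seed: int | None = 0, size: int = 1):
    """Draw replicate contingency tables from the model at fixed row totals.

    Returns arrays ``present (size, 5, 2, 2, 3)`` and ``absent
    (size, 5, 3)``.
    """
    rng = np.random.default_rng(seed)
    p_present, p_absent = model_probabilities(params)
    present = np.zeros((size,) + row_counts.present.shape, dtype=int)
    absent = np.zeros((size,) + row_counts.absent.shape, dtype=int)
    for li in range(N_LAGS):
        n_abs = int(row_counts.absent[li].sum())
        if n_abs:
            absent[:, li] = rng.multinomial(n_abs, p_absent[li], size=size)
        for ci in range(N_CONTRASTS):
            for si in range(2):
                n_row = int(row_counts.present[li, ci, si].sum())
                if n_row:
                    present[:, li, ci, si] = rng.multinomial(n_row, p_present[li, ci, si],
                                                             size=size)
    return present, absent


def _pool_groups(expected: np.ndarray, min_expected: float = 5.0) -> list[list[int]]:
    """Merge cells with small expectation into their nearest neighbour within a row."""
    groups = [[i] for i in range(len(expected))]
    while len(groups) > 1:
        sums = np.array([expected[g].sum() for g in groups])
        small = np.where(sums < min_expected)[0]
        if len(small) == 0:
            break
        i = small[np.argmin(sums[small])]
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:  # merge toward the larger neighbour (deterministic tie-break: left)
            j = i - 1 if sums[i - 1] >= sums[i + 1] else i + 1
        a, b = min(i, j), max(i, j)
        groups[a] = groups[a] + groups[b]
        del groups[b]
    return groups


def _row_chi2_terms(observed: np.ndarray, expected: np.ndarray, groups: list[list[int]]) -> float:
    chi2 = 0.0
    for g in groups:
        e = expected[g].sum()
        if e <= 0:
            raise ValueError("zero expected count after pooling")
        o = observed[..., g].sum(axis=-1)
        chi2 = chi2 + (o - e) ** 2 / e
    return chi2


def goodness_of_fit(fit: FitResult, data: ContingencyData, n_boot: int = 500,
                    seed: int | None = 0, refit: bool = False,
                    config: FitConfig | None = None):
    """Chi-squared randomization goodness-of-fit p-value.

    The observed chi-squared (expected cells below 5 pooled with their
    nearest within-row neighbour) is compared against ``n_boot``
    replicate tables simulated from the fitted model at the observed
    per-condition trial counts.  By default replicates are evaluated at
    the fitted parameters without refitting; ``refit=True`` refits each
    replicate (slow).  Returns ``(p, chi2_obs)``; p has floor
    ``1/(n_boot+1)`` via inclusion of the observed statistic.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    params = fit.params
    p_present, p_absent = model_probabilities(params)
    sim_present, sim_absent = simulate_contingency(params, data, seed=seed, size=n_boot)

    def total_chi2(obs_present, obs_absent):
        chi2 = 0.0
        for li in range(N_LAGS):
            n_abs = data.absent[li].sum()
            if n_abs:
                exp = n_abs * p_absent[li]
                chi2 = chi2 + _row_chi2_terms(obs_absent[..., li, :], exp, _pool_groups(exp))
            for ci in range(N_CONTRASTS):
                for si in range(2):
                    n_row = data.present[li, ci, si].sum()
                    if n_row:
                        exp = n_row * p_present[li, ci, si]
                        chi2 = chi2 + _row_chi2_terms(obs_present[..., li, ci, si, :], exp,
                                                      _pool_groups(exp))
        return chi2

    chi2_obs = total_chi2(data.present, data.absent)
    if refit:
        chi2_sim = np.empty(n_boot)
        for b in range(n_boot):
            rep = ContingencyData(present=sim_present[b], absent=sim_absent[b])
            refit_res = fit_model(rep, fit.variant, config=config, seed=seed)
            pp, pa = model_probabilities(refit_res.params)
            chi2 = 0.0
            for li in range(N_LAGS):
                n_abs = data.absent[li].sum()
                if n_abs:
                    exp = n_abs * pa[li]
                    chi2 += _row_chi2_terms(sim_absent[b, li], exp, _pool_groups(exp))
                for ci in range(N_CONTRASTS):
                    for si in range(2):
                        n_row = data.present[li, ci, si].sum()
                        if n_row:
                            exp = n_row * pp[li, ci, si]
                            chi2 += _row_chi2_terms(sim_present[b, li, ci, si], exp,
                                                    _pool_groups(exp))
            chi2_sim[b] = chi2
    else:
        chi2_sim = total_chi2(sim_present, sim_absent)
    p = (1.0 + np.sum(chi2_sim >= chi2_obs)) / (n_boot + 1.0)
    return float(p), float(chi2_obs)


# ---------------------------------------------------------------------------
# derived indices


@dataclass
class DerivedIndices:
    """Detection criterion, likelihood-ratio bias, deficits, modulation indices."""

    c_det: np.ndarray      # (5, 2) lag x contrast
    lr_bias: np.ndarray    # (5, 2)
    deficits: pd.DataFrame  # per parameter x contrast scope: SL, LL, deficit, MI


def _lag_pool(values: np.ndarray, lags: tuple) -> float:
    idx = [LAGS_MS.index(l) for l in lags]
    return float(np.mean(values[idx]))


def derive_indices(fit: FitResult | ModelParameters,
                   pool_cdet_after: bool = True) -> DerivedIndices:
    """Derived psychophysical indices of a fitted model.

    ``c_det[lag, contrast] = t_det[lag] - d_det[lag, contrast] / 2`` (the
    detection threshold re-expressed relative to the noise/signal
    midpoint) and ``lr_bias = exp(-d_det * c_det)``.  Blink deficits are
    short-lag (100+300 ms) minus long-lag (700+900 ms) lag-pool means;
    modulation indices are ``(LL - SL) / (LL + SL)`` (NaN when the
    denominator is zero).  With ``pool_cdet_after`` (default) the
    contrast-pooled c_det deficit averages c_det across contrasts before
    lag pooling; otherwise it is computed from contrast-pooled t_det and
    d_det.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    c_det = params.t_det[:, None] - params.d_det / 2.0
    lr_bias = np.exp(-params.d_det * c_det)

    series = {}
    for ci, con in enumerate(CONTRASTS):
        series[("d_det", con)] = params.d_det[:, ci]
        series[("d_dis", con)] = params.d_dis[:, ci]
        series[("c_det", con)] = c_det[:, ci]
        series[("lr_bias", con)] = lr_bias[:, ci]
    series[("d_det", "pooled")] = params.d_det.mean(axis=1)
    series[("d_dis", "pooled")] = params.d_dis.mean(axis=1)
    if pool_cdet_after:
        series[("c_det", "pooled")] = c_det.mean(axis=1)
    else:
        series[("c_det", "pooled")] = params.t_det - params.d_det.mean(axis=1) / 2.0
    series[("lr_bias", "pooled")] = lr_bias.mean(axis=1)
    series[("t_det", "all")] = params.t_det
    series[("c_dis", "all")] = params.c_dis
    series[("beta", "all")] = params.beta

    rows = []
    for (name, scope), vals in series.items():
        sl = _lag_pool(vals, SHORT_LAGS)
        ll = _lag_pool(vals, LONG_LAGS)
        denom = ll + sl
        mi = (ll - sl) / denom if abs(denom) > 1e-12 else np.nan
        rows.append((name, scope, sl, ll, sl - ll, mi))
    deficits = pd.DataFrame(rows, columns=["parameter", "scope", "SL", "LL", "deficit", "MI"])
    return DerivedIndices(c_det=c_det, lr_bias=lr_bias, deficits=deficits)
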