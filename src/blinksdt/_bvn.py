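"""Vectorized standard bivariate normal CDF.

Computes ``P(X <= h, Y <= k)`` for a zero-mean, unit-variance bivariate
normal with correlation ``rho`` using Owen's T function,

    Phi2(h, k; rho) = (Phi(h) + Phi(k)) / 2
                      - T(h, a_h) - T(k, a_k) - delta,

with ``a_h = (k - rho h) / (h sqrt(1 - rho^2))`` (and symmetrically for
``a_k``) and ``delta = 1/2`` iff ``h k < 0`` (or ``h k = 0`` with
``h + k < 0``).  The formula is exact; scipy's Owen's T evaluation is
accurate to near machine precision and, unlike
``scipy.stats.multivariate_normal.cdf``, broadcasts over points *and*
correlations, which is what the likelihood evaluation needs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]

# |rho| above this is treated as perfect (anti)correlation.
_RHO_EPS = 1e-12
# near-zero arguments are nudged away from 0 (sign-preserving) so the Owen's T
# slope argument stays finite; the CDF is continuous so the error is O(eps)
_ZERO_NUDGE = 1e-10


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) under a standard bivariate normal with correlation rho.

    All three arguments broadcast against each other; returns an ndarray
    (or scalar for scalar inputs).
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    scalar = h.ndim == 0
    h = np.atleast_1d(h).copy()
    k = np.atleast_1d(k).copy()
    rho = np.atleast_1d(rho).astype(float).copy()

    if np.any(np.abs(rho) > 1 + 1e-9):
        raise ValueError("correlation must lie in [-1, 1]")
    rho = np.clip(rho, -1.0, 1.0)

    out = np.empty_like(h)

    pos = rho >= 1.0 - _RHO_EPS
    neg = rho <= -1.0 + _RHO_EPS
    gen = ~(pos | neg)

    if np.any(pos):  # comonotone: P = Phi(min(h, k))
        out[pos] = ndtr(np.minimum(h[pos], k[pos]))
    if np.any(neg):  # antithetic: P = max(0, Phi(h) + Phi(k) - 1)
        out[neg] = np.maximum(0.0, ndtr(h[neg]) + ndtr(k[neg]) - 1.0)
    if np.any(gen):
        hh = h[gen]
        kk = k[gen]
        rr = rho[gen]
        hh = np.where(np.abs(hh) < _ZERO_NUDGE, np.where(hh < 0, -_ZERO_NUDGE, _ZERO_NUDGE), hh)
        kk = np.where(np.abs(kk) < _ZERO_NUDGE, np.where(kk < 0, -_ZERO_NUDGE, _ZERO_NUDGE), kk)
        denom = np.sqrt(1.0 - rr * rr)
        ah = (kk - rr * hh) / (hh * denom)
        ak = (hh - rr * kk) / (kk * denom)
        delta = np.where(hh * kk < 0.0, 0.5, 0.0)
        val = 0.5 * (ndtr(hh) + ndtr(kk)) - owens_t(hh, ah) - owens_t(kk, ak) - delta
        out[gen] = val

    np.clip(out, 0.0, 1.0, out=out)
    return out[0] if scalar else out
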