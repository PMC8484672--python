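"""Robust estimation primitives shared by the nonlinear and linear fits.

Huber and Tukey-bisquare psi/weight functions, the rescaled-MAD residual
scale, and the M-scale used by the high-breakdown S-estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HUBER_K",
    "BISQUARE_C",
    "S_BISQUARE_C",
    "mad_scale",
    "huber_weights",
    "bisquare_weights",
    "bisquare_rho",
    "m_scale",
]

#: Huber tuning constant giving 95% Gaussian efficiency (M-step default
#: of the nonlinear fits).
HUBER_K = 1.345

#: Tukey bisquare tuning constant giving 95% Gaussian efficiency (final
#: M-step of the MM linear estimator).
BISQUARE_C = 4.685

#: Bisquare constant for the 50%-breakdown S-scale.
S_BISQUARE_C = 1.5476


def mad_scale(resid: np.ndarray) -> float:
    """Median absolute deviation about zero, rescaled for Gaussian consistency.

    Regression residuals are already centered by the fit, so the MAD is
    taken about zero (matching simultaneous-scale IRLS practice).
    """
    resid = np.asarray(resid, dtype=float)
    return 1.4826 * float(np.median(np.abs(resid)))


def huber_weights(u: np.ndarray, k: float = HUBER_K) -> np.ndarray:
    """Huber psi(u)/u: 1 inside [-k, k], k/|u| outside."""
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    with np.errstate(divide="ignore"):
        w = np.where(au > k, k / au, 1.0)
    return w


def bisquare_weights(u: np.ndarray, c: float = BISQUARE_C) -> np.ndarray:
    """Tukey bisquare psi(u)/u: (1 - (u/c)^2)^2 inside [-c, c], 0 outside."""
    u = np.asarray(u, dtype=float)
    t = u / c
    w = (1.0 - t * t) ** 2
    return np.where(np.abs(t) < 1.0, w, 0.0)


def bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    """Bisquare rho, bounded at c^2/6."""
    u = np.asarray(u, dtype=float)
    t = np.clip(np.abs(u) / c, 0.0, 1.0)
    return (c * c / 6.0) * (1.0 - (1.0 - t * t) ** 3)


def bisquare_psi(u: np.ndarray, c: float = BISQUARE_C) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    t = u / c
    return np.where(np.abs(t) < 1.0, u * (1.0 - t * t) ** 2, 0.0)


def bisquare_psi_prime(u: np.ndarray, c: float = BISQUARE_C) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    t = (u / c) ** 2
    return np.where(t < 1.0, (1.0 - t) * (1.0 - 5.0 * t), 0.0)


def m_scale(resid: np.ndarray, c: float = S_BISQUARE_C, tol: float = 1e-10) -> float:
    """M-estimate of scale: s solving mean(rho(r/s)) = delta.

    With the 50%-breakdown bisquare (c = 1.5476) and delta = rho_max / 2
    the estimate is consistent at the Gaussian and tolerates up to half
    gross contamination.  Returns 0 when more than half the residuals are
    exactly zero (degenerate exact-fit case).
    """
    resid = np.asarray(resid, dtype=float)
    n = resid.size
    delta = 0.5 * (c * c / 6.0)
    # rho is bounded, so if > half the residuals are 0 no positive scale
    # can reach delta: the solution is 0.
    if np.sum(resid == 0.0) > n / 2:
        return 0.0
    s0 = mad_scale(resid)
    if s0 == 0.0:
        s0 = float(np.mean(np.abs(resid)))
    if s0 == 0.0:
        return 0.0

    def f(s: float) -> float:
        return float(np.mean(bisquare_rho(resid / s, c))) - delta

    lo, hi = s0, s0
    while f(lo) < 0 and lo > 1e-300:  # mean rho too small -> shrink s
        lo /= 8.0
    while f(hi) > 0 and hi < 1e300:
        hi *= 8.0
    if lo == hi:
        return lo
    return float(brentq(f, lo, hi, xtol=tol * max(s0, 1e-12)))
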