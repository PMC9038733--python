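"""Circular arithmetic and densities on the 180°-periodic orientation space.

Orientations (as opposed to directions of motion) live on a circle of
period 180°: a bar tilted 10° is the same bar tilted 190°.  All arithmetic
here is performed by the standard angle-doubling device: the orientation
circle is mapped onto the ordinary 360° circle by ``x -> 2x``, where the
von Mises distribution and circular moments are defined, and results are
mapped back.  The spread parameter ``sigma`` used throughout the package is
expressed in degrees of *orientation* (the 180° space), so that the
circular SD of the doubled-angle von Mises equals ``2 * sigma``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "wrap_orientation",
    "wrap180",
    "signed_error",
    "sd_to_kappa",
    "kappa_to_sd",
    "vm_pdf_180",
    "mean_error",
    "circular_mean_error",
    "error_sd",
    "precision",
]

#: upper bound for sigma, degrees: at 90° the density is indistinguishable
#: from uniform (kappa ~ 0.014).
SIGMA_MAX = 90.0


def wrap_orientation(x):
    """Map any angle (degrees) to the canonical orientation range [0, 180).

    Inputs in (0, 180] are accepted; 180 maps to 0 (same orientation).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("orientation must be finite")
    out = np.mod(x, 180.0)
    return out if out.ndim else float(out)


def wrap180(delta):
    """Wrap a difference of orientations (degrees) into (-90, 90].

    The orientation circle has period 180°, so differences are only defined
    modulo 180; the representative closest to zero is returned, with the
    boundary assigned to +90 (half-open convention: every difference has a
    unique representative).
    """
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("wrap180 requires finite input")
    # mod into [-90, 90) then move -90 to +90
    out = np.mod(delta + 90.0, 180.0) - 90.0
    out = np.where(out == -90.0, 90.0, out)
    return out if out.ndim else float(out)


def signed_error(response, target):
    """Signed report error in degrees: ``wrap180(response - target)``.

    Zero means the response equals the target orientation; positive errors
    are counter-clockwise of the target under the usual convention.
    """
    response = np.asarray(response, dtype=float)
    target = np.asarray(target, dtype=float)
    return wrap180(response - target)


def kappa_to_sd(kappa: float) -> float:
    """Orientation-space SD (degrees) of a von Mises with concentration kappa.

    Defined through the doubled angle: the circular SD of VM(kappa) on the
    360° circle is ``sqrt(-2 ln R)`` radians with ``R = I1(k)/I0(k)``; this
    equals ``2 sigma`` on the orientation scale, hence the factor 90/pi.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return SIGMA_MAX  # flat density: report the maximal SD of the scale
    r = i1e(kappa) / i0e(kappa)
    return (90.0 / math.pi) * math.sqrt(-2.0 * math.log(r))


def sd_to_kappa(sigma: float) -> float:
    """Invert :func:`kappa_to_sd`: concentration for a given orientation SD.

    Solved by Brent's method; the mapping is strictly decreasing in sigma.
    """
    sigma = float(sigma)
    if not (0.0 < sigma <= SIGMA_MAX):
        raise ValueError(f"sigma must be in (0, {SIGMA_MAX}], got {sigma}")

    def resid(k):
        return kappa_to_sd(k) - sigma

    lo, hi = 1e-8, 10.0
    while resid(hi) > 0 and hi < 1e12:
        hi *= 10.0
    if resid(lo) < 0:  # sigma essentially at the flat limit
        return lo
    return brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)


def vm_pdf_180(x, sigma):
    """von Mises density per degree on the 180°-periodic orientation space.

    ``f(x) = exp(kappa * cos(2x * pi/180)) / (180 * I0(kappa))`` with
    ``kappa = sd_to_kappa(sigma)``; integrates to 1 over any 180° window.
    """
    kappa = sd_to_kappa(sigma)
    x = np.asarray(x, dtype=float)
    # exponentially-scaled Bessel keeps this finite for large kappa
    c = np.cos(np.deg2rad(2.0 * x))
    out = np.exp(kappa * (c - 1.0)) / (180.0 * i0e(kappa))
    return out if out.ndim else float(out)


def mean_error(errors) -> float:
    """Arithmetic mean of wrapped errors (degrees).

    The conventional report for concentrated error distributions: errors are
    first wrapped into (-90, 90] and then averaged linearly.  For the
    circular alternative see :func:`circular_mean_error`.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("mean_error requires at least one error")
    return float(np.mean(wrap180(errors)))


def circular_mean_error(errors) -> float:
    """Circular mean of errors via angle doubling, in degrees in (-90, 90]."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("circular_mean_error requires at least one error")
    doubled = np.deg2rad(2.0 * errors)
    ang = math.atan2(np.mean(np.sin(doubled)), np.mean(np.cos(doubled)))
    return wrap180(np.rad2deg(ang) / 2.0)


def error_sd(errors, ddof: int = 1) -> float:
    """Sample standard deviation of wrapped errors, in degrees."""
    errors = wrap180(np.asarray(errors, dtype=float))
    if errors.size < 2:
        raise ValueError("error_sd requires at least two errors")
    return float(np.std(errors, ddof=ddof))


def precision(errors, kind: str = "inverse_sd") -> float:
    """Precision of a set of report errors.

    kind='inverse_sd' (default) returns ``1 / SD`` in 1/degrees; the
    alternative kind='inverse_variance' returns ``1 / SD**2``.
    """
    sd = error_sd(errors)
    if sd == 0.0:
        raise ValueError("precision undefined for zero-variance errors")
    if kind == "inverse_sd":
        return 1.0 / sd
    if kind == "inverse_variance":
        return 1.0 / sd**2
    raise ValueError(f"unknown precision kind: {kind!r}")
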