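"""Moment-based estimation of a single bi-Gaussian peak from a noisy ion trace.

The summit is not taken to be the highest observed point — at LC-MS noise
levels that estimate is unreliable.  Instead the whole trace is used: for a
candidate split point tau, let

    A(tau) = log(mass left of tau) - log(mass right of tau)
    B(tau) = (1/3) * [log(second moment about tau, left)
                      - log(second moment about tau, right)]

For a bi-Gaussian curve both quantities equal log(sigma1/sigma2) at
tau = alpha, so alpha is a root of A(tau) - B(tau); simulation over a
reasonable range of sigma1/sigma2 shows the difference is monotone in tau,
making the root unique.  On a discrete trace the integrals become
step-function sums weighted by the local step sizes, the difference is
evaluated at the midpoints between adjacent observed times, and the root is
located by linear interpolation between the bracketing pair.

With the summit fixed, sigma1 and sigma2 are intensity-weighted root mean
squared deviations on each side, and delta is a fitted-value-squared weighted
geometric mean of observed/fitted intensity ratios (log-scale weighting
favours points near the summit, where ion counts are least skewed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import BiGaussianPeak

__all__ = [
    "IonTrace",
    "SummitProfile",
    "compute_A_hat",
    "compute_B_hat",
    "summit_profile",
    "estimate_summit",
    "estimate_sigmas",
    "estimate_delta",
    "fit_single_peak",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class UndefinedSplitError(ValueError):
    """The candidate split point leaves zero mass (or moment) on one side."""


class InsufficientDataError(ValueError):
    """The trace does not carry enough signal for the requested estimate."""


class OneSidedPeakError(ValueError):
    """All positive intensity lies on one side of the proposed summit."""


@dataclass(frozen=True)
class IonTrace:
    """A discretely sampled extracted-ion chromatogram.

    Parameters
    ----------
    times : array-like
        Strictly increasing retention times ``t_1 < ... < t_n``, n >= 2.
    intensities : array-like
        Nonnegative finite intensities, at least one positive.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __init__(self, times, intensities) -> None:
        t = np.asarray(times, dtype=float)
        x = np.asarray(intensities, dtype=float)
        if t.ndim != 1 or x.ndim != 1 or t.shape != x.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 2:
            raise InsufficientDataError("an ion trace needs at least 2 points")
        if not np.all(np.isfinite(t)) or not np.all(np.diff(t) > 0):
            raise ValueError("times must be finite and strictly increasing")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValueError("intensities must be finite and >= 0")
        if not np.any(x > 0):
            raise InsufficientDataError("all intensities are zero")
        t.setflags(write=False)
        x.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", x)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def step_sizes(self) -> np.ndarray:
        """Local step sizes: half the span between each point's neighbours.

        dt_1 = t_2 - t_1;  dt_i = (t_{i+1} - t_{i-1}) / 2;  dt_n = t_n - t_{n-1}.
        """
        t = self.times
        dt = np.empty_like(t)
        dt[0] = t[1] - t[0]
        dt[-1] = t[-1] - t[-2]
        if t.size > 2:
            dt[1:-1] = (t[2:] - t[:-2]) / 2.0
        return dt

    def with_intensities(self, intensities) -> "IonTrace":
        return IonTrace(self.times, intensities)


@dataclass(frozen=True)
class SummitProfile:
    """A(tau)-B(tau) evaluated at the valid midpoints between observed times."""

    taus: np.ndarray
    diff_values: np.ndarray


def _side_sums(trace: IonTrace, tau: float):
    t, x, dt = trace.times, trace.intensities, trace.step_sizes
    left = t < tau
    w = x * dt
    d2 = (t - tau) ** 2
    return (
        float(np.sum(w[left])),
        float(np.sum(w[~left])),
        float(np.sum((w * d2)[left])),
        float(np.sum((w * d2)[~left])),
    )


def compute_A_hat(trace: IonTrace, tau: float) -> float:
    """Log-ratio of the step-function masses left vs right of ``tau``.

    Discrete counterpart of log of the area left of tau minus log of the
    area to its right; points with ``t_i < tau`` count as left, ``t_i >= tau``
    as right.
    """
    l0, r0, _, _ = _side_sums(trace, tau)
    if l0 <= 0 or r0 <= 0:
        raise UndefinedSplitError(f"zero mass on one side of tau={tau}")
    return math.log(l0) - math.log(r0)


def compute_B_hat(trace: IonTrace, tau: float) -> float:
    """Log-ratio of the cube roots of the non-centred second moments about
    ``tau`` of the left and right portions of the trace."""
    _, _, l2, r2 = _side_sums(trace, tau)
    if l2 <= 0 or r2 <= 0:
        raise UndefinedSplitError(f"zero second moment on one side of tau={tau}")
    return (math.log(l2) - math.log(r2)) / 3.0


def summit_profile(trace: IonTrace) -> SummitProfile:
    """Evaluate A_hat - B_hat at every midpoint between adjacent observed
    times where both sides carry positive mass and second moment.

    Vectorized with prefix sums: for the midpoint between t_k and t_{k+1} the
    left side is exactly the first k+1 points, so all splits share the same
    cumulative sums of x*dt, x*t*dt and x*t^2*dt.
    """
    t, x, dt = trace.times, trace.intensities, trace.step_sizes
    w = x * dt
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * t)
    s2 = np.cumsum(w * t * t)
    taus = 0.5 * (t[:-1] + t[1:])

    l0 = s0[:-1]
    r0 = s0[-1] - l0
    # second moment about tau: sum w*(t - tau)^2 = s2 - 2*tau*s1 + tau^2*s0
    l2 = s2[:-1] - 2.0 * taus * s1[:-1] + taus * taus * s0[:-1]
    r2 = (s2[-1] - s2[:-1]) - 2.0 * taus * (s1[-1] - s1[:-1]) + taus * taus * r0

    valid = (l0 > 0) & (r0 > 0) & (l2 > 0) & (r2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = (np.log(l0) - np.log(r0)) - (np.log(l2) - np.log(r2)) / 3.0
    return SummitProfile(taus=taus[valid], diff_values=diff[valid])


def estimate_summit(trace: IonTrace) -> float:
    """Locate the peak summit as the root of A_hat(tau) - B_hat(tau).

    The difference is evaluated at all valid midpoints between adjacent
    observed times; the estimate interpolates linearly between the largest
    value below zero and the smallest value above zero.  If the profile never
    changes sign (a one-sided or boundary peak), the midpoint with the
    smallest absolute difference is returned.
    """
    prof = summit_profile(trace)
    taus, diff = prof.taus, prof.diff_values
    if taus.size < 2:
        raise InsufficientDataError(
            "fewer than 2 valid split points; trace too sparse for summit estimation"
        )
    zero = np.flatnonzero(diff == 0.0)
    if zero.size:
        return float(taus[zero[0]])
    neg = diff < 0
    pos = diff > 0
    if neg.any() and pos.any():
        i_neg = np.flatnonzero(neg)[np.argmax(diff[neg])]
        i_pos = np.flatnonzero(pos)[np.argmin(diff[pos])]
        t0, d0 = taus[i_neg], diff[i_neg]
        t1, d1 = taus[i_pos], diff[i_pos]
        return float(t0 - d0 * (t1 - t0) / (d1 - d0))
    return float(taus[np.argmin(np.abs(diff))])


def estimate_sigmas(trace: IonTrace, alpha_hat: float) -> tuple[float, float]:
    """Weighted RMS deviation of retention time about the summit, per side.

    sigma1 uses points with ``t_i < alpha_hat``, sigma2 those with
    ``t_i >= alpha_hat``; weights are ``x_i * dt_i``.  If one side carries no
    positive mass its estimate mirrors the other side's.
    """
    l0, r0, l2, r2 = _side_sums(trace, alpha_hat)
    s1 = math.sqrt(l2 / l0) if l0 > 0 and l2 > 0 else None
    s2 = math.sqrt(r2 / r0) if r0 > 0 and r2 > 0 else None
    if s1 is None and s2 is None:
        raise OneSidedPeakError("no positive mass on either side of the summit")
    if s1 is None:
        s1 = s2
    if s2 is None:
        s2 = s1
    return float(s1), float(s2)


def _unscaled_fitted(times: np.ndarray, alpha: float, sigma1: float, sigma2: float) -> np.ndarray:
    d = times - alpha
    sigma = np.where(d < 0, sigma1, sigma2)
    return np.exp(-(d * d) / (2.0 * sigma * sigma)) / _SQRT_2PI


def estimate_delta(
    trace: IonTrace, alpha_hat: float, sigma1_hat: float, sigma2_hat: float
) -> float:
    """Scaling factor as a weighted geometric mean of observed/fitted ratios.

    With unscaled fitted values z_i, delta_hat = exp(sum z_i^2 * log(x_i/z_i)
    / sum z_i^2) over points with x_i > 0 (zeros are treated as missing —
    log(0) is undefined and dropout zeros carry no amplitude information).
    """
    z = _unscaled_fitted(trace.times, alpha_hat, sigma1_hat, sigma2_hat)
    mask = (trace.intensities > 0) & (z > 0)
    if not mask.any():
        raise InsufficientDataError("no positive intensities to estimate delta from")
    z = z[mask]
    x = trace.intensities[mask]
    # weights normalized by the largest fitted value so z^2 cannot underflow;
    # the ratio is taken in logs for the same reason
    w = (z / z.max()) ** 2
    return float(np.exp(np.sum(w * (np.log(x) - np.log(z))) / np.sum(w)))


def estimate_pooled_sigma(trace: IonTrace, alpha_hat: float) -> float:
    """Symmetric-model spread: weighted RMS deviation about the summit pooled
    over both sides (used by the Gaussian baseline, where sigma1 = sigma2)."""
    l0, r0, l2, r2 = _side_sums(trace, alpha_hat)
    m0, m2 = l0 + r0, l2 + r2
    if m0 <= 0 or m2 <= 0:
        raise OneSidedPeakError("no positive mass around the summit")
    return math.sqrt(m2 / m0)


def fit_single_peak(
    trace: IonTrace,
    alpha_hat: float | None = None,
    symmetric: bool = False,
) -> BiGaussianPeak:
    """Fit one peak: summit root-finding, then sigmas, then delta.

    Parameters
    ----------
    trace : IonTrace
    alpha_hat : float, optional
        Fix the summit instead of estimating it (used when a kernel-smoother
        peak seeds the mixture initialization).
    symmetric : bool
        Constrain sigma1 = sigma2 to the pooled two-sided moment estimate
        (the Gaussian special case).
    """
    if alpha_hat is None:
        alpha_hat = estimate_summit(trace)
    if symmetric:
        s = estimate_pooled_sigma(trace, alpha_hat)
        s1 = s2 = s
    else:
        s1, s2 = estimate_sigmas(trace, alpha_hat)
    delta = estimate_delta(trace, alpha_hat, s1, s2)
    return BiGaussianPeak(alpha=float(alpha_hat), sigma1=s1, sigma2=s2, delta=delta)
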