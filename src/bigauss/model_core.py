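"""Bi-Gaussian peak model: two half-Gaussians joined at a shared summit.

The peak is parameterized by the summit location ``alpha`` (retention time),
the left and right half standard deviations ``sigma1`` and ``sigma2``, and a
scaling factor ``delta``.  The intensity curve is

    g(t) = delta / sqrt(2*pi) * exp(-(t - alpha)^2 / (2 * sigma1^2))   t <  alpha
    g(t) = delta / sqrt(2*pi) * exp(-(t - alpha)^2 / (2 * sigma2^2))   t >= alpha

Both branches equal ``delta / sqrt(2*pi)`` at the summit, so the curve is
continuous.  The half-areas are ``delta*sigma1/2`` (left) and ``delta*sigma2/2``
(right); the total area ``delta*(sigma1+sigma2)/2`` is derived, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BiGaussianPeak", "evaluate_bigaussian", "peak_area"]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class ParameterDomainError(ValueError):
    """A peak parameter is outside its valid domain."""


@dataclass(frozen=True)
class BiGaussianPeak:
    """A four-parameter asymmetric chromatographic peak.

    Parameters
    ----------
    alpha : float
        Retention time of the peak summit (minutes by convention).
    sigma1 : float
        Standard deviation of the left half-Gaussian, > 0.
    sigma2 : float
        Standard deviation of the right half-Gaussian, > 0.
    delta : float
        Scaling factor, > 0.  The summit height is ``delta / sqrt(2*pi)``.
    """

    alpha: float
    sigma1: float
    sigma2: float
    delta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha)):
            raise ParameterDomainError(f"alpha must be finite, got {self.alpha}")
        for name in ("sigma1", "sigma2", "delta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(f"{name} must be finite and > 0, got {v}")

    # -- derived quantities -------------------------------------------------

    @property
    def height(self) -> float:
        """Intensity at the summit, ``delta / sqrt(2*pi)``."""
        return self.delta / _SQRT_2PI

    @property
    def area_left(self) -> float:
        """Area under the left half, ``delta * sigma1 / 2``."""
        return self.delta * self.sigma1 / 2.0

    @property
    def area_right(self) -> float:
        """Area under the right half, ``delta * sigma2 / 2``."""
        return self.delta * self.sigma2 / 2.0

    @property
    def area(self) -> float:
        """Total area, ``delta * (sigma1 + sigma2) / 2``."""
        return self.delta * (self.sigma1 + self.sigma2) / 2.0

    def __call__(self, times) -> np.ndarray:
        return evaluate_bigaussian(self, times)


def evaluate_bigaussian(peak: BiGaussianPeak, times) -> np.ndarray:
    """Evaluate the bi-Gaussian curve at the given retention times.

    Points strictly left of the summit use ``sigma1``; the summit itself and
    everything to its right use ``sigma2`` (the two branches coincide at the
    summit, so the convention is observationally irrelevant).
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    d = t - peak.alpha
    sigma = np.where(d < 0, peak.sigma1, peak.sigma2)
    out = peak.delta / _SQRT_2PI * np.exp(-(d * d) / (2.0 * sigma * sigma))
    return out


def peak_area(peak: BiGaussianPeak) -> float:
    """Closed-form area under the peak, ``delta * (sigma1 + sigma2) / 2``."""
    return peak.area
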