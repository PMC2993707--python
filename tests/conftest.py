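import numpy as np
import pytest

from bigauss import BiGaussianPeak, IonTrace, evaluate_bigaussian


@pytest.fixture
def dense_trace():
    """Factory: noiseless densely sampled trace of a single bi-Gaussian."""

    def make(peak: BiGaussianPeak, n: int = 500, span_sigmas: float = 6.0) -> IonTrace:
        smax = max(peak.sigma1, peak.sigma2)
        t = np.linspace(peak.alpha - span_sigmas * smax, peak.alpha + span_sigmas * smax, n)
        return IonTrace(t, evaluate_bigaussian(peak, t))

    return make


@pytest.fixture
def mixture_trace():
    """Factory: noiseless trace of a sum of bi-Gaussian components."""

    def make(components, n: int = 500, pad_sigmas: float = 5.0) -> IonTrace:
        smax = max(max(c.sigma1, c.sigma2) for c in components)
        lo = min(c.alpha for c in components) - pad_sigmas * smax
        hi = max(c.alpha for c in components) + pad_sigmas * smax
        t = np.linspace(lo, hi, n)
        x = np.zeros(n)
        for c in components:
            x += evaluate_bigaussian(c, t)
        return IonTrace(t, x)

    return make
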