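"""Posterior/bootstrap interval summaries: percentile CI and HPDI.

Percentile intervals are equal-tailed quantile intervals.  The highest
posterior density interval (HPDI) is the narrowest contiguous window of the
sorted draws containing the requested mass; for skewed distributions it is
narrower than the percentile interval and always contains the mode region,
which is why it is preferred for correlation coefficients.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["hpdi", "percentile_ci"]


def percentile_ci(samples: np.ndarray, mass: float = 0.97) -> tuple[float, float]:
    """Equal-tailed interval at quantiles (1-mass)/2 and 1-(1-mass)/2."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    tail = (1.0 - mass) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


def hpdi(samples: np.ndarray, mass: float = 0.97) -> tuple[float, float]:
    """Narrowest contiguous window of sorted draws holding ``ceil(mass*n)``."""
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 50:
        raise ValueError("need at least 50 samples for an HPDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    window = math.ceil(mass * n)
    if window >= n:
        return float(samples[0]), float(samples[-1])
    widths = samples[window - 1 :] - samples[: n - window + 1]
    start = int(np.argmin(widths))
    return float(samples[start]), float(samples[start + window - 1])
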