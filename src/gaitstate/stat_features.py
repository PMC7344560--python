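"""Window-level statistical features of the acceleration signal.

Ten scalars per knee per window. All are computed on the per-sample Euclidean
magnitude of the tri-axial block except the signal magnitude area, whose
formula sums absolute values over the three axes directly. Conventions:

* standard deviation uses the population normaliser (1/N);
* skewness is the Fisher-Pearson adjusted coefficient,
  n/((n-1)(n-2)) * sum(((x_i - mean)/s)^3) with s the sample (1/(n-1)) SD;
* kurtosis is excess kurtosis, E[(x - mean)^4]/var^2 - 3 with population
  moments;
* the interquartile range uses Tukey hinges: the window is split at its
  median into two halves (the median included in both for odd n) and the IQR
  is the difference of the halves' medians;
* zero-variance windows report skewness and kurtosis of 0, never NaN, so the
  feature matrix stays dense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def magnitude(block: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(ax^2 + ay^2 + az^2) of an (n, 3) block."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 3 or len(block) == 0:
        raise ValueError("expected a non-empty (n, 3) tri-axial block")
    return np.sqrt(np.einsum("ij,ij->i", block, block))


def _tukey_iqr(x: np.ndarray) -> float:
    """IQR via Tukey hinges (median-of-halves; median shared for odd n)."""
    x = np.sort(x)
    n = len(x)
    half = (n + 1) // 2
    lower = x[:half]
    upper = x[n - half:]
    return float(np.median(upper) - np.median(lower))


@dataclass(frozen=True)
class StatFeatureSet:
    """The ten statistical features for one knee in one window."""

    mean: float
    std: float
    mad: float
    minimum: float
    maximum: float
    energy: float
    iqr: float
    sma: float
    skewness: float
    kurtosis: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.mean,
            self.std,
            self.mad,
            self.minimum,
            self.maximum,
            self.energy,
            self.iqr,
            self.sma,
            self.skewness,
            self.kurtosis,
        )


def stat_features(x: np.ndarray, block: np.ndarray) -> StatFeatureSet:
    """Compute the ten statistical features.

    ``x`` is the scalar basis series for the window (the magnitude series)
    and ``block`` the matching (n, 3) tri-axial block used only by the signal
    magnitude area. ``n`` is whatever the window actually holds, so partial
    trailing folds use their own length throughout.
    """
    x = np.asarray(x, dtype=float)
    block = np.asarray(block, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("degenerate window: need at least 2 samples")
    if block.shape != (n, 3):
        raise ValueError("tri-axial block must be (n, 3) and match the scalar series")

    mean = float(np.mean(x))
    std = float(np.std(x))  # population (1/N)
    mad = float(np.median(np.abs(x - np.median(x))))
    energy = float(np.mean(np.abs(x) ** 2))
    sma = float(np.mean(np.sum(np.abs(block), axis=1)))
    iqr = _tukey_iqr(x)

    if n < 4:
        logger.info("window of %d samples: skewness/kurtosis reported as 0", n)
        skew = kurt = 0.0
    else:
        s = float(np.std(x, ddof=1))
        if s == 0.0:
            skew = kurt = 0.0
        else:
            skew = float(n / ((n - 1) * (n - 2)) * np.sum(((x - mean) / s) ** 3))
            m2 = float(np.mean((x - mean) ** 2))
            kurt = float(np.mean((x - mean) ** 4) / m2**2 - 3.0)

    return StatFeatureSet(
        mean=mean,
        std=std,
        mad=mad,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        energy=energy,
        iqr=iqr,
        sma=sma,
        skewness=skew,
        kurtosis=kurt,
    )
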