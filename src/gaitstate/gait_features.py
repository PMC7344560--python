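"""Spatiotemporal gait parameters from a knee acceleration signal.

Each window yields six parameters per knee: step/stride length (m), step/
stride time (s) and step/stride velocity (m/s). The estimator is explicit
and deliberately simple:

1. heel strikes of the instrumented leg are detected on the filtered
   magnitude series (autocorrelation cadence estimate, threshold peaks,
   refractory suppression), so inter-event intervals are stride times;
2. per stride, the vertical acceleration is linearly detrended, converted
   g -> m/s^2, and doubly integrated (velocity detrended again to kill the
   integration constant); the vertical excursion h is the range of the
   resulting displacement;
3. the inverted-pendulum model converts h to step length,
   step_length = 2*sqrt(2*l*h - h^2) for leg length l (h clipped at l).

Symmetric gait is assumed: step time = stride time / 2 and stride length =
2 * step length by construction. Windows with fewer than two detected
strikes emit zeros and carry a quality flag rather than missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps

G_TO_MS2 = 9.81


@dataclass
class GaitDetectorConfig:
    """Tunable thresholds of the heel-strike detector.

    The autocorrelation band must cover one full stride at the slowest gait
    of interest (3.0 s at 40 steps/min, hence the 3.2 s default upper lag).
    ``min_periodicity`` is the minimum normalised autocorrelation at the
    dominant lag for the window to count as gait at all; white noise stays
    well below it, so aperiodic windows yield empty (flagged) events.
    """

    prominence_std: float = 0.5  # peak threshold: mean + this * std
    refractory_frac: float = 0.5  # fraction of the estimated stride period
    acf_min_s: float = 0.4  # autocorrelation search band, lower lag
    acf_max_s: float = 3.2  # upper lag
    min_periodicity: float = 0.2  # normalised ACF gate


@dataclass
class GaitEvents:
    """Detected heel strikes for one leg within one window."""

    strike_indices: np.ndarray
    cadence_est: float  # strikes (strides of this leg) per minute

    def __post_init__(self) -> None:
        idx = np.asarray(self.strike_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("strike indices must be strictly increasing")
        self.strike_indices = idx

    @property
    def n_strikes(self) -> int:
        return int(self.strike_indices.size)


@dataclass(frozen=True)
class GaitFeatureSet:
    """The six spatiotemporal parameters (window-level means) for one knee."""

    step_length: float
    stride_length: float
    step_time: float
    stride_time: float
    step_velocity: float
    stride_velocity: float
    flagged: bool = False

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.step_length,
            self.stride_length,
            self.step_time,
            self.stride_time,
            self.step_velocity,
            self.stride_velocity,
        )


ZERO_GAIT = GaitFeatureSet(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, flagged=True)


def _dominant_period_s(
    x: np.ndarray, fs: float, cfg: GaitDetectorConfig
) -> tuple[float, float]:
    """Dominant autocorrelation lag within the band and its normalised height."""
    x = x - np.mean(x)
    acf = np.correlate(x, x, mode="full")[len(x) - 1 :]
    if acf[0] <= 0:
        return cfg.acf_max_s, 0.0
    lo = max(1, int(round(cfg.acf_min_s * fs)))
    hi = min(len(acf) - 1, int(round(cfg.acf_max_s * fs)))
    if hi <= lo:
        return cfg.acf_max_s, 0.0
    band = acf[lo : hi + 1]
    top = float(band.max())
    if top <= 0:
        return cfg.acf_max_s, 0.0
    # prefer the fundamental: ACF of a periodic train peaks at every multiple
    # of the period with near-equal height, so take the smallest local
    # maximum within 85% of the band maximum rather than the raw argmax.
    interior = np.arange(1, len(band) - 1)
    is_peak = (band[interior] >= band[interior - 1]) & (band[interior] >= band[interior + 1])
    candidates = interior[is_peak & (band[interior] >= 0.85 * top)]
    k = int(candidates[0]) if candidates.size else int(np.argmax(band))
    return (lo + k) / fs, float(top / acf[0])


def detect_strikes(
    mag: np.ndarray, fs: float, cfg: GaitDetectorConfig | None = None
) -> GaitEvents:
    """Detect heel strikes of the instrumented leg on a magnitude series.

    Candidate peaks are local maxima exceeding mean + prominence_std * std;
    when two candidates fall closer than refractory_frac of the estimated
    stride period, the larger survives. Fewer than two surviving peaks
    yields an empty (flagged) event set.
    """
    cfg = cfg or GaitDetectorConfig()
    mag = np.asarray(mag, dtype=float)
    if len(mag) < 2 * fs:
        raise ValueError("need at least 2 s of signal to detect gait events")
    period_s, strength = _dominant_period_s(mag, fs, cfg)
    cadence = 60.0 / period_s
    if strength < cfg.min_periodicity:
        return GaitEvents(np.array([], dtype=int), cadence)
    threshold = float(np.mean(mag) + cfg.prominence_std * np.std(mag))
    candidates, _ = sps.find_peaks(mag, height=threshold)
    refractory = cfg.refractory_frac * (60.0 / cadence) * fs  # samples
    # amplitude-priority non-maximum suppression
    order = candidates[np.argsort(mag[candidates])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= refractory for k in kept):
            kept.append(int(idx))
    kept.sort()
    if len(kept) < 2:
        return GaitEvents(np.array([], dtype=int), cadence)
    return GaitEvents(np.asarray(kept, dtype=int), cadence)


def step_length_from_h(h: float, leg_length: float) -> float:
    """Inverted-pendulum step length 2*sqrt(2*l*h - h^2), h clipped at l."""
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    h = min(max(h, 0.0), leg_length)
    return 2.0 * float(np.sqrt(2.0 * leg_length * h - h * h))


def _vertical_excursion(segment: np.ndarray, fs: float) -> float:
    """Range of the doubly-integrated, detrended vertical acceleration (m)."""
    if len(segment) < 3:
        return 0.0
    acc = sps.detrend(segment * G_TO_MS2, type="linear")
    vel = spi.cumulative_trapezoid(acc, dx=1.0 / fs, initial=0.0)
    vel = sps.detrend(vel, type="linear")
    pos = spi.cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)
    return float(np.max(pos) - np.min(pos))


def gait_features(
    events: GaitEvents,
    vertical: np.ndarray,
    fs: float,
    leg_length: float = 0.9,
) -> GaitFeatureSet:
    """Window-level gait parameters from detected strikes.

    ``vertical`` is the (filtered) vertical-axis acceleration in g for the
    same window the events were detected in. With fewer than two strikes the
    all-zero flagged set is returned.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if events.n_strikes < 2:
        return ZERO_GAIT
    vertical = np.asarray(vertical, dtype=float)
    idx = events.strike_indices
    stride_time = float(np.mean(np.diff(idx)) / fs)
    step_time = stride_time / 2.0
    h_values = [
        _vertical_excursion(vertical[a:b], fs) for a, b in zip(idx[:-1], idx[1:])
    ]
    h = min(float(np.mean(h_values)), leg_length)
    step_length = step_length_from_h(h, leg_length)
    stride_length = 2.0 * step_length
    step_velocity = step_length / step_time if step_time > 0 else 0.0
    stride_velocity = stride_length / stride_time if stride_time > 0 else 0.0
    return GaitFeatureSet(
        step_length=step_length,
        stride_length=stride_length,
        step_time=step_time,
        stride_time=stride_time,
        step_velocity=step_velocity,
        stride_velocity=stride_velocity,
        flagged=False,
    )
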