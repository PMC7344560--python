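"""Noise filtering and fold segmentation.

The pipeline low-pass filters each axis with a fourth-order Butterworth at
15 Hz (fs 32 Hz) and then cuts each course into contiguous non-overlapping
folds of 320 samples (10 s), the unit of classification. A trailing partial
fold is kept iff it is at least half a fold long, so the emitted count is
round-half-up(N / fold).

With fs = 32 Hz the 15 Hz cutoff sits at 0.94 x Nyquist and removes only a
sliver of band; it is implemented exactly as published, with an advisory
logged when the cutoff exceeds 0.9 x Nyquist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording

logger = logging.getLogger(__name__)

DEFAULT_FOLD = 320


@dataclass
class FilterSpec:
    """Low-pass Butterworth filter specification.

    ``zero_phase`` applies the filter forward and backward (no phase lag,
    magnitude response squared); ``causal`` is a single forward pass.
    """

    order: int = 4
    cutoff_hz: float = 15.0
    fs_hz: float = 32.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={self.fs_hz / 2} Hz)"
            )
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError("mode must be 'zero_phase' or 'causal'")

    def sos(self) -> np.ndarray:
        return sps.butter(self.order, self.cutoff_hz, btype="low", fs=self.fs_hz, output="sos")


def lowpass_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Filter each axis of a recording independently; output length == input."""
    spec = spec or FilterSpec(fs_hz=rec.fs)
    if rec.fs != spec.fs_hz:
        raise ValueError(f"recording fs {rec.fs} != filter fs {spec.fs_hz}")
    n = len(rec)
    if n <= 3 * spec.order:
        raise ValueError(f"recording of {n} samples too short for order {spec.order}")
    if spec.cutoff_hz > 0.9 * spec.fs_hz / 2:
        logger.info(
            "cutoff %.3g Hz is %.0f%% of Nyquist; the filter removes little band",
            spec.cutoff_hz,
            100 * spec.cutoff_hz / (spec.fs_hz / 2),
        )
    sos = spec.sos()
    if spec.mode == "zero_phase":
        filtered = sps.sosfiltfilt(sos, rec.samples, axis=0)
    else:
        # step-response initial conditions avoid the zero-state startup
        # transient (a constant input then stays exactly constant)
        zi = sps.sosfilt_zi(sos)
        cols = []
        for k in range(rec.samples.shape[1]):
            x = rec.samples[:, k]
            y, _ = sps.sosfilt(sos, x, zi=zi * x[0])
            cols.append(y)
        filtered = np.column_stack(cols)
    return rec.replace(samples=np.asarray(filtered))


@dataclass
class WindowSegment:
    """One fold of a course: paired left/right tri-axial blocks plus metadata."""

    subject_id: str
    course_id: str
    window_index: int
    left: np.ndarray
    right: np.ndarray
    label: str
    fs: float

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right blocks must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.left)


def window_count(n: int, fold: int = DEFAULT_FOLD) -> int:
    """Number of folds emitted for an n-sample course.

    floor(n/fold) full folds plus the trailing partial fold iff its length is
    at least fold/2 — i.e. round-half-up of n/fold.
    """
    if fold < 2:
        raise ValueError("fold must be >= 2")
    if n < 0:
        raise ValueError("n must be non-negative")
    full, rem = divmod(n, fold)
    return full + (1 if rem >= fold / 2 else 0)


def segment_windows(
    left: Recording, right: Recording, fold: int = DEFAULT_FOLD
) -> list[WindowSegment]:
    """Cut one course's left/right pair into ordered, contiguous folds.

    Mismatched knee lengths are truncated to the shorter stream with a
    warning; every window inherits the course label from the recordings'
    medication state.
    """
    if fold < 2:
        raise ValueError("fold must be >= 2")
    if left.state != right.state or left.subject_id != right.subject_id:
        raise ValueError("left/right recordings must share subject and state")
    n_left, n_right = len(left), len(right)
    n = min(n_left, n_right)
    if n_left != n_right:
        warnings.warn(
            f"knee streams differ in length ({n_left} vs {n_right}); "
            f"truncating to {n} samples",
            stacklevel=2,
        )
    count = window_count(n, fold)
    windows = []
    for i in range(count):
        start = i * fold
        stop = min(start + fold, n)
        windows.append(
            WindowSegment(
                subject_id=left.subject_id,
                course_id=left.course_id or right.course_id,
                window_index=i,
                left=left.samples[start:stop],
                right=right.samples[start:stop],
                label=left.state,
                fs=left.fs,
            )
        )
    return windows
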