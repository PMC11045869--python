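"""Per-minute feature extraction from raw 2 Hz triaxial accelerometry.

The smartwatch samples acceleration on three axes twice per second, so one
minute holds exactly 120 readings per axis.  From those it derives three
per-minute features:

``pa_avg``
    The mean of the 119 absolute consecutive differences on the axis where
    that mean is largest (the *dominant* axis).  It measures the average
    change in acceleration per sample and is the watch's "average of PA".

``pa_var``
    The mean, over the same 119 absolute differences of the dominant axis,
    of the squared deviation from ``pa_avg`` — the "variance of PA".

``steps``
    A deterministic step count from peak detection on the smoothed,
    per-axis-demeaned vector magnitude.

Acceleration units are arbitrary but must be consistent within a stream;
every feature here depends only on within-minute differences, so constant
offsets (gravity, sensor bias) do not affect the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

SAMPLE_HZ = 2.0
SAMPLES_PER_MINUTE = 120
DIFFS_PER_MINUTE = SAMPLES_PER_MINUTE - 1

Axis = Literal["x", "y", "z"]
#: dominant-axis tie break: earlier axis wins
AXIS_PRIORITY: tuple[Axis, ...] = ("x", "y", "z")


class AccelSample(NamedTuple):
    """One triaxial reading: ``t`` is seconds within the minute (0, 0.5, ... 59.5)."""

    t: float
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class StepDetectorParams:
    """Tunables of the step counter (the watch firmware publishes none).

    smooth_width
        Width in samples of the centered moving-average filter.
    amplitude_threshold
        Minimum height of a peak above the median of the smoothed
        magnitude signal, in acceleration units.
    min_spacing
        Minimum distance between accepted peaks, in samples (2 = 1 s).
    """

    smooth_width: int = 3
    amplitude_threshold: float = 0.15
    min_spacing: int = 2


@dataclass(frozen=True)
class MinuteWindow:
    """One minute of raw accelerometry: 120 samples per axis at 2 Hz.

    ``t`` must be strictly increasing; windows are half-open
    ``[minute_start, minute_start + 60 s)``.  Partial windows are rejected,
    never padded.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    minute_start: datetime | None = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (SAMPLES_PER_MINUTE,):
                raise ValueError(
                    f"axis {name!r} must hold exactly {SAMPLES_PER_MINUTE} "
                    f"samples, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"axis {name!r} contains non-finite values")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_samples(
        cls, samples: Iterable[AccelSample], minute_start: datetime | None = None
    ) -> "MinuteWindow":
        rows = [AccelSample(*s) for s in samples]
        return cls(
            t=np.array([s.t for s in rows]),
            x=np.array([s.x for s in rows]),
            y=np.array([s.y for s in rows]),
            z=np.array([s.z for s in rows]),
            minute_start=minute_start,
        )

    def axis(self, name: Axis) -> np.ndarray:
        if name not in AXIS_PRIORITY:
            raise ValueError(f"unknown axis {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class MinuteFeatures:
    """The watch's per-minute feature triple plus the axis pa_var was taken on."""

    pa_avg: float
    pa_var: float
    steps: int
    dominant_axis: Axis


def axis_mean_abs_diff(axis_samples: Sequence[float] | np.ndarray) -> float:
    """Mean of the 119 absolute consecutive differences of one axis.

    The signed sum of consecutive differences telescopes to a start/end
    difference and carries no activity information, so the magnitude of each
    change is used: this is the per-axis "average change in acceleration".
    """
    values = np.asarray(axis_samples, dtype=float)
    if values.shape != (SAMPLES_PER_MINUTE,):
        raise ValueError(
            f"expected {SAMPLES_PER_MINUTE} samples, got {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("axis samples contain non-finite values")
    return float(np.mean(np.abs(np.diff(values))))


def compute_pa_avg(window: MinuteWindow) -> tuple[float, Axis]:
    """Per-minute average of PA and the dominant axis it was measured on.

    pa_avg is the maximum of the three per-axis mean absolute differences;
    ties resolve by the fixed axis priority x > y > z.
    """
    per_axis = {name: axis_mean_abs_diff(window.axis(name)) for name in AXIS_PRIORITY}
    best = max(AXIS_PRIORITY, key=lambda name: (per_axis[name], -AXIS_PRIORITY.index(name)))
    return per_axis[best], best


def compute_pa_var(window: MinuteWindow, pa_avg: float, dominant_axis: Axis) -> float:
    """Variance of PA: mean squared deviation of the dominant axis's 119
    absolute differences from ``pa_avg`` (divisor 119).

    ``pa_avg``/``dominant_axis`` must come from :func:`compute_pa_avg` on the
    same window; a mismatch raises ``ValueError``.
    """
    diffs = np.abs(np.diff(window.axis(dominant_axis)))
    if abs(float(np.mean(diffs)) - pa_avg) > 1e-9:
        raise ValueError(
            "pa_avg does not match the stated dominant axis of this window"
        )
    return float(np.mean((diffs - pa_avg) ** 2))


def count_steps(
    window: MinuteWindow, params: StepDetectorParams | None = None
) -> int:
    """Deterministic step count from the vector-magnitude signal.

    Each axis is demeaned (removing gravity/bias so the count is invariant
    under constant offsets), the Euclidean magnitude is smoothed with a
    centered moving average, and steps are the local maxima exceeding the
    median of the smoothed signal by at least ``amplitude_threshold``,
    separated by at least ``min_spacing`` samples.
    """
    p = params or StepDetectorParams()
    axes = np.stack([window.x, window.y, window.z])
    axes = axes - axes.mean(axis=1, keepdims=True)
    magnitude = np.sqrt((axes**2).sum(axis=0))
    smoothed = uniform_filter1d(magnitude, size=p.smooth_width, mode="nearest")
    height = float(np.median(smoothed)) + p.amplitude_threshold
    peaks, _ = find_peaks(smoothed, height=height, distance=p.min_spacing)
    return int(peaks.size)


def extract_minute_features(
    window: MinuteWindow, step_params: StepDetectorParams | None = None
) -> MinuteFeatures:
    """All three per-minute features, with pa_var computed on the dominant axis."""
    pa_avg, dominant = compute_pa_avg(window)
    pa_var = compute_pa_var(window, pa_avg, dominant)
    steps = count_steps(window, step_params)
    return MinuteFeatures(pa_avg=pa_avg, pa_var=pa_var, steps=steps, dominant_axis=dominant)
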