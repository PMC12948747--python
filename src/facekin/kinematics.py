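"""Kinematic derivations from landmark and activation time series.

Jerk is operationalised as four successive frame differences of the raw
3-D landmark coordinates — movement (change in position), velocity,
acceleration, then jerk (change in acceleration).  Each difference shortens
the series by one frame, so jerk is defined over N - 4 timepoints; a
382-frame spoken recording yields 378 valid jerk frames and a 540-frame
cued recording yields 536.  (Field usage often calls jerk the "third
derivative" of position; the operational four-difference chain above, with
its N - 4 valid frames, is what this package computes.)

No sampling-interval scaling is applied: differences are per frame, so jerk
is in avatar units per frame^4.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .types import DataError, JerkSeries, Recording

DEFAULT_PEAK_INDEX = 270   # 1-based midpoint frame of a 540-frame cued trial


class InsufficientLengthError(DataError):
    """Series too short for the requested operation."""


def successive_differences(series: np.ndarray, order: int) -> np.ndarray:
    """Apply ``order`` successive first differences along the frame axis.

    Returns an array with exactly ``order`` fewer frames; equivalent to
    ``order`` repeated applications of the first difference.
    """
    series = np.asarray(series, dtype=float)
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    n = series.shape[0]
    if n <= order:
        raise InsufficientLengthError(
            f"need more than {order} frames for an order-{order} "
            f"difference, got {n}")
    return np.diff(series, n=order, axis=0)


def compute_jerk(landmarks: np.ndarray, combine: str = "norm") -> JerkSeries:
    """Per-landmark absolute jerk magnitudes from (frames, 68, 3) coordinates.

    ``combine="norm"`` (default) takes the Euclidean norm of the 3-axis
    fourth-difference vector, which is invariant to the axis order and to
    global rigid rotation of a static pose.  ``combine="absmean"`` averages
    the per-axis absolute fourth differences instead, for sensitivity
    checks.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 3 or landmarks.shape[2] != 3:
        raise DataError(
            f"landmarks must be (frames, landmarks, 3), got {landmarks.shape}")
    if not np.isfinite(landmarks).all():
        raise DataError("landmark coordinates contain non-finite values")
    n = landmarks.shape[0]
    if n < 5:
        raise InsufficientLengthError(
            f"jerk needs at least 5 frames, got {n}")
    d4 = np.diff(landmarks, n=4, axis=0)
    if combine == "norm":
        values = np.linalg.norm(d4, axis=2)
    elif combine == "absmean":
        values = np.abs(d4).mean(axis=2)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    return JerkSeries(values=values, source_frames=n)


def resample_to_length(series: np.ndarray, target_frames: int,
                       method: str = "linear") -> np.ndarray:
    """Resample a (frames, ...) series to ``target_frames`` evenly spaced
    frames, preserving the overall shape.

    Endpoints are kept exactly; constant input stays constant and linear
    interpolation preserves monotonicity.  ``method`` may be ``"linear"``
    (default) or ``"cubic"`` (natural cubic spline).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 2 or target_frames < 2:
        raise InsufficientLengthError(
            f"resampling needs >= 2 frames on both sides, got "
            f"{n} -> {target_frames}")
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_frames)
    if method == "linear":
        interp = interp1d(x_old, series, axis=0, assume_sorted=True)
    elif method == "cubic":
        interp = CubicSpline(x_old, series, axis=0)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return np.asarray(interp(x_new))


def peak_frame_activation(recording: Recording,
                          peak_index: int = DEFAULT_PEAK_INDEX) -> np.ndarray:
    """Blendshape activation vector at the expression peak of a cued trial.

    ``peak_index`` is 1-based (default 270, the midpoint of a 540-frame
    trial, inside the expression hold).  Defined only for the cued
    condition, whose fixed beep timing makes the peak frame comparable
    across recordings.
    """
    if recording.condition != "cued":
        raise DataError(
            "peak-frame extraction is defined only for cued recordings; "
            f"got condition {recording.condition!r}")
    if not 1 <= peak_index <= recording.n_frames:
        raise IndexError(
            f"peak index {peak_index} outside recording of "
            f"{recording.n_frames} frames")
    return recording.blendshapes[peak_index - 1].copy()


def mean_over_time(series: np.ndarray) -> np.ndarray:
    """Arithmetic mean per channel over the frame axis.

    For jerk series, pass ``JerkSeries.values`` so the mean covers only the
    N - 4 valid frames.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] == 0:
        raise DataError("cannot average an empty series")
    return series.mean(axis=0)


def recording_jerk(recording: Recording, combine: str = "norm") -> JerkSeries:
    """Jerk series of one recording's landmark tracks."""
    return compute_jerk(recording.landmarks, combine=combine)
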