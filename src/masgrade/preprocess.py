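"""Signal conditioning and stretch segmentation.

The cleaning chain mirrors standard practice for goniometer/myometer/sEMG
recordings:

* elbow angle: resultant of the two goniometer planes, then 5th-order median
  and 5th-order mean filters;
* resisting force: 5th-order median and mean filters, then fix-zero
  levelling (subtraction of the resting baseline);
* surface EMG: zero-mean levelling, full-wave rectification, 4th-order
  Butterworth 10 Hz low-pass (applied forward-backward, i.e. zero phase),
  then decimation onto the 1000 Hz timebase.

Segmentation finds the rising phases (flexed -> extended) of the elbow
angle.  A session contains six stretches, three slow followed by three
fast; only the fast ones exhibit the catch and feed classification.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, signal

from masgrade.io import FS_HIGH, FS_LOW, StretchRecording

#: Minimum sEMG length accepted by :func:`semg_condition` (filter warm-up).
SEMG_MIN_SAMPLES = 28

#: Fraction of a stretch's excursion used to refine window boundaries.
#: Onset/offset are placed at the 2% / 98% excursion crossings, a standard
#: movement-onset convention that is well defined even though the angular
#: velocity vanishes at the true endpoints of a smooth stretch.
BOUNDARY_FRAC = 0.02


class SegmentationError(RuntimeError):
    """Raised when a session cannot be segmented into the expected stretches."""


@dataclasses.dataclass
class ProcessedSession:
    """Cleaned, aligned single-session signals on the common 1000 Hz timebase."""

    time: np.ndarray  # s
    angle: np.ndarray  # resultant elbow angle, deg
    force: np.ndarray  # zero-levelled force, N
    semg_env: np.ndarray  # rectified low-passed sEMG envelope, mV

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.angle) == len(self.force) == len(self.semg_env) == n):
            raise ValueError("all processed channels must share one timebase")
        if np.any(self.angle < 0):
            raise ValueError("resultant angle must be non-negative")
        if np.any(self.semg_env < 0):
            raise ValueError("sEMG envelope must be non-negative")


@dataclasses.dataclass
class StretchSegment:
    """One isolated stretch: a rising-phase window of the session.

    Indices are 0-based and half-open ``[start_idx, end_idx)`` on the
    1000 Hz timebase.  ``rom`` is the angular span covered inside the
    window (deg).
    """

    start_idx: int
    end_idx: int
    speed: str  # "slow" | "fast"
    angle: np.ndarray
    force: np.ndarray
    semg_env: np.ndarray
    rom: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_idx < self.end_idx:
            raise ValueError("require 0 <= start_idx < end_idx")
        if self.speed not in ("slow", "fast"):
            raise ValueError(f"speed must be 'slow' or 'fast', got {self.speed!r}")
        if self.rom < 0:
            raise ValueError("rom must be non-negative")


def resultant_angle(angle_x: np.ndarray, angle_y: np.ndarray) -> np.ndarray:
    """Combine the two goniometer planes into one elbow angle.

    The twin-axis goniometer reports the joint angle split across two
    planes; the physical elbow angle is the Euclidean resultant
    ``sqrt(theta_x**2 + theta_y**2)`` (non-negative by construction).
    """
    angle_x = np.asarray(angle_x, dtype=float)
    angle_y = np.asarray(angle_y, dtype=float)
    if angle_x.shape != angle_y.shape:
        raise ValueError(
            f"angle_x and angle_y lengths differ: {angle_x.shape} vs {angle_y.shape}"
        )
    return np.hypot(angle_x, angle_y)


def _check_order(order: int) -> None:
    if order < 1 or order % 2 == 0:
        raise ValueError(f"filter order must be odd and >= 1, got {order}")


def median_filter(series: np.ndarray, order: int = 5) -> np.ndarray:
    """Sliding-window median; edges by reflection; length preserved."""
    _check_order(order)
    return ndimage.median_filter(
        np.asarray(series, dtype=float), size=order, mode="reflect"
    )


def mean_filter(series: np.ndarray, order: int = 5) -> np.ndarray:
    """Sliding-window mean; edges by reflection; length preserved."""
    _check_order(order)
    return ndimage.uniform_filter1d(
        np.asarray(series, dtype=float), size=order, mode="reflect"
    )


def fix_zero_levelling(
    series: np.ndarray, baseline_window: float = 0.1, fs: float = FS_LOW
) -> np.ndarray:
    """Remove the resting offset of the force channel.

    Subtracts the mean of the first ``baseline_window`` seconds, assuming
    the recording starts with the arm at rest against the myometer.
    """
    series = np.asarray(series, dtype=float)
    n_base = int(round(baseline_window * fs))
    if len(series) < n_base or n_base < 1:
        raise ValueError(
            f"series of {len(series)} samples shorter than the "
            f"{n_base}-sample baseline window"
        )
    return series - series[:n_base].mean()


def semg_condition(semg: np.ndarray, fs: float = FS_HIGH, cutoff_hz: float = 10.0) -> np.ndarray:
    """Condition raw surface EMG into a linear envelope.

    Steps, in order: (i) zero-mean levelling (subtract the series mean);
    (ii) full-wave rectification; (iii) 4th-order Butterworth low-pass at
    ``cutoff_hz``, applied forward-backward so the envelope is not
    lag-shifted relative to the kinematics.  Small negative ringing from
    the filter is clipped to zero.
    """
    semg = np.asarray(semg, dtype=float)
    if len(semg) < SEMG_MIN_SAMPLES:
        raise ValueError(
            f"sEMG series of {len(semg)} samples is shorter than the filter "
            f"warm-up of {SEMG_MIN_SAMPLES}"
        )
    rectified = np.abs(semg - semg.mean())
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rectified)
    return np.clip(env, 0.0, None)


def align_semg(semg_env: np.ndarray, target_len: int) -> np.ndarray:
    """Decimate the 2000 Hz envelope onto the 1000 Hz timebase.

    Sample ``i`` of the output is the envelope at index ``2*i``; the 10 Hz
    low-pass applied beforehand already prevents aliasing.
    """
    semg_env = np.asarray(semg_env, dtype=float)
    if abs(len(semg_env) - 2 * target_len) > 2:
        raise ValueError(
            f"envelope length {len(semg_env)} is not ~2x target {target_len}"
        )
    idx = np.minimum(2 * np.arange(target_len), len(semg_env) - 1)
    return semg_env[idx]


def preprocess_recording(
    rec: StretchRecording,
    filter_order: int = 5,
    baseline_window: float = 0.1,
    semg_cutoff_hz: float = 10.0,
) -> ProcessedSession:
    """Run the full cleaning chain on one raw recording."""
    angle = mean_filter(
        median_filter(resultant_angle(rec.angle_x, rec.angle_y), filter_order),
        filter_order,
    )
    force = fix_zero_levelling(
        mean_filter(median_filter(rec.force, filter_order), filter_order),
        baseline_window,
        fs=FS_LOW,
    )
    env_hi = semg_condition(rec.semg, fs=FS_HIGH, cutoff_hz=semg_cutoff_hz)
    semg_env = align_semg(env_hi, rec.n_low)
    return ProcessedSession(
        time=rec.time_lo, angle=angle, force=force, semg_env=semg_env
    )


def smoothed_derivative(
    series: np.ndarray, fs: float = FS_LOW, deriv: int = 1, smooth_ms: float = 0.0
) -> np.ndarray:
    """Time derivative by Savitzky-Golay local polynomial fitting.

    ``smooth_ms`` sets the fit window; 0 falls back to plain central
    differences.  Direct double differencing at 1000 Hz amplifies sensor
    noise by ~fs**2, so acceleration estimates use a fitted window instead.
    A cubic fit reproduces polynomials up to degree 3 exactly, which keeps
    ramps and constant-acceleration segments bias-free.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    w = int(round(smooth_ms * fs / 1000.0)) | 1
    if smooth_ms <= 0 or w <= 5 or n <= 5:
        out = series
        for _ in range(deriv):
            out = np.gradient(out)
        return out * fs**deriv
    w = min(w, n if n % 2 else n - 1)
    return signal.savgol_filter(series, w, 3, deriv=deriv, delta=1.0 / fs, mode="interp")


def _refine_window(
    smooth,
    a: int,
    b: int,
    left_bound: int = 0,
    right_bound: int | None = None,
    noise_floor: float = 0.0,
) -> tuple[int, int, float]:
    """Snap a coarse rise region ``[a, b)`` to its excursion crossings.

    The rest and hold levels are estimated as medians of short patches just
    outside the region (robust to noise extremes); start/end are the 2% /
    98% excursion crossings between those levels.  Returns
    (start, end_exclusive, rise).
    """
    n = len(smooth)
    right_bound = n if right_bound is None else right_bound
    pre = smooth[max(left_bound, a - 300) : max(left_bound, a - 10)]
    post = smooth[min(b + 10, right_bound) : min(b + 300, right_bound)]
    lo = max(left_bound, a - 50)
    hi = min(right_bound, b + 50)
    win = smooth[lo:hi]
    if len(win) < 2:
        return lo, lo + 1, 0.0
    amin = float(np.median(pre)) if len(pre) else float(win.min())
    amax = float(np.median(post)) if len(post) else float(win.max())
    amin = max(amin, float(win.min()))
    amax = min(amax, float(win.max()))
    rise = amax - amin
    if rise <= 0:
        return lo, lo + 1, 0.0
    # crossing levels: the nominal excursion fraction, floored at the noise
    # level so sustained noise excursions cannot fake an onset
    lo_level = amin + min(max(BOUNDARY_FRAC * rise, noise_floor), 0.3 * rise)
    hi_level = amax - min(max(BOUNDARY_FRAC * rise, noise_floor), 0.3 * rise)
    above = np.nonzero(win >= hi_level)[0]
    end = lo + int(above[0]) if len(above) else hi - 1
    below = np.nonzero(win[: end - lo + 1] <= lo_level)[0]
    start = lo + int(below[-1]) if len(below) else lo
    return start, end + 1, rise


def _rising_seeds(velocity, high: float, min_run: int, gap_limit: int):
    """Sustained runs above the high threshold, merged across short gaps."""
    idx = np.flatnonzero(velocity > high)
    if len(idx) == 0:
        return []
    # strictly consecutive runs; only sustained ones count as evidence, so
    # isolated noise spikes can neither seed nor bridge stretches
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = [
        (int(r[0]), int(r[-1]) + 1)
        for r in np.split(idx, splits + 1)
        if len(r) >= min_run
    ]
    if not runs:
        return []
    seeds = [runs[0]]
    for a, b in runs[1:]:
        if a - seeds[-1][1] <= gap_limit:
            seeds[-1] = (seeds[-1][0], b)
        else:
            seeds.append((a, b))
    return seeds


def detect_stretch_windows(
    angle: np.ndarray,
    fs: float = FS_LOW,
    min_prominence: float = 10.0,
    min_separation: float = 0.5,
) -> list[tuple[int, int]]:
    """Locate the rising phases (flexed -> extended) of the elbow angle.

    Rises are found by hysteresis on the smoothed angular velocity:
    sustained runs above 5% of the session's peak velocity seed the
    regions (runs closer than ``min_separation`` seconds are merged), and
    each seed is extended outward while the velocity stays above a low,
    noise-aware floor, so the gentle tails of slow stretches are kept.
    Each region is then refined to the 2%/98% crossings of its excursion
    between the surrounding rest/hold levels, and rises smaller than
    ``min_prominence`` degrees are discarded.  This velocity view is
    equivalent to pairing alternating local minima and maxima but remains
    well defined for plateau-separated staircase motion, where interior
    maxima do not exist.  Windows are ordered in time and non-overlapping;
    an empty list means no stretch-like motion was found.
    """
    angle = np.asarray(angle, dtype=float)
    n = len(angle)
    if n < 10:
        return []
    smooth_len = max(3, int(round(0.05 * fs)) | 1)
    smooth = ndimage.uniform_filter1d(angle, size=smooth_len, mode="reflect")
    if smooth.max() - smooth.min() < min_prominence:
        return []
    velocity = np.gradient(smooth) * fs
    high = 0.05 * velocity.max()
    if high <= 0:
        return []
    low = 0.004 * velocity.max()
    # noise scale from the high-frequency residual (trend-insensitive); the
    # sqrt factor maps it onto the smoothed signal's noise level
    resid = angle - smooth
    noise_floor = 3.0 * 1.4826 * float(np.median(np.abs(resid))) / np.sqrt(smooth_len / 7.0)
    # merge only across short dropouts (e.g. the catch's velocity dip);
    # longer gaps are genuine rests between stretches
    gap_limit = max(1, int(round(min(0.1, min_separation) * fs)))
    min_run = max(3, int(round(0.025 * fs)))
    seeds = _rising_seeds(velocity, high, min_run, gap_limit)

    windows: list[tuple[int, int]] = []
    prev_end = 0
    for k, (a, b) in enumerate(seeds):
        left = max(prev_end, seeds[k - 1][1] if k > 0 else 0)
        right = seeds[k + 1][0] if k + 1 < len(seeds) else n
        while a - 1 >= left and velocity[a - 1] > low:
            a -= 1
        while b < right and velocity[b] > low:
            b += 1
        start, end, rise = _refine_window(
            smooth, a, b, left, right, noise_floor=noise_floor
        )
        if rise >= min_prominence and end - start >= 2:
            windows.append((start, end))
            prev_end = end
    return windows



def _window_prominence(angle: np.ndarray, window: tuple[int, int]) -> float:
    seg = angle[window[0] : window[1]]
    return float(seg.max() - seg.min())


def segment_session(
    proc: ProcessedSession,
    expected_stretches: int = 6,
    min_prominence: float | str = "auto",
    min_separation: float = 0.5,
    fs: float = FS_LOW,
) -> list[StretchSegment]:
    """Split a session into its stretches and tag them slow/fast.

    The protocol records three slow stretches followed by three fast ones,
    so the first half of the detected rises is tagged ``slow`` and the
    second half ``fast`` (positional assignment).  A velocity sanity check
    warns when the tagging is not corroborated by the peak angular
    velocities.  Spurious extra rises are pruned by prominence ranking.

    ``min_prominence="auto"`` scales the detection threshold with the
    session's angular span (40% of the span, capped at 10 deg) so that
    severely restricted sessions — a rigid elbow moves only a few degrees —
    are still segmentable.
    """
    angle = proc.angle
    if min_prominence == "auto":
        span = float(angle.max() - angle.min())
        prominence = min(10.0, max(0.5, 0.4 * span))
    else:
        prominence = float(min_prominence)
    windows = detect_stretch_windows(
        angle, fs=fs, min_prominence=prominence, min_separation=min_separation
    )
    if len(windows) < expected_stretches:
        raise SegmentationError(
            f"found {len(windows)} of {expected_stretches} expected stretches"
        )
    if len(windows) > expected_stretches:
        ranked = sorted(windows, key=lambda w: _window_prominence(angle, w))
        keep = ranked[len(windows) - expected_stretches :]
        windows = sorted(keep)

    half = expected_stretches // 2
    segments = []
    for i, (start, end) in enumerate(windows):
        seg_angle = angle[start:end]
        segments.append(
            StretchSegment(
                start_idx=start,
                end_idx=end,
                speed="slow" if i < half else "fast",
                angle=seg_angle,
                force=proc.force[start:end],
                semg_env=proc.semg_env[start:end],
                rom=float(seg_angle.max() - seg_angle.min()),
            )
        )

    def _peak_vel(seg_angle: np.ndarray) -> float:
        vel = smoothed_derivative(seg_angle, fs=fs, deriv=1, smooth_ms=51)
        half = 25  # the fitted derivative extrapolates (noisily) at the edges
        if len(vel) > 4 * half:
            vel = vel[half:-half]
        return float(np.max(np.abs(vel)))

    peak_vel = [_peak_vel(s.angle) for s in segments]
    slow_max = max(peak_vel[:half], default=0.0)
    fast_min = min(peak_vel[half:], default=np.inf)
    if fast_min <= slow_max:
        warnings.warn(
            "speed tagging is positional but the peak angular velocities do "
            "not separate slow from fast stretches",
            stacklevel=2,
        )
    return segments
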