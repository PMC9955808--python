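"""Catch detection and per-stretch feature extraction.

The catch is the jerk-like instant of maximum deceleration of the elbow
during a fast passive stretch; its position within the range of motion is
the key clinical cue for MAS grading.  From one stretch segment this
module computes 17 features in three groups:

* kinematic (8): range of motion, catch angle, the angles at maximum sEMG
  and maximum force, each also as a fraction of the range of motion, and
  the maximum angular velocity;
* kinetic (6): the force at the catch relative to the initial force, the
  normalised force increment at the catch, normalised average forces over
  the whole stretch and after the catch, and least-squares force slopes
  after the force maximum and after the catch;
* physiological (3 unique): normalised sEMG at the catch, normalised
  average sEMG after the catch, normalised average sEMG slope after the
  catch.  The catch-force-to-initial-force ratio also belongs to this
  group clinically (it reflects the stretch reflex) but is counted once,
  under kinetics, so the vector has 17 unique entries.

Angles are measured as excursion from the segment-start angle so that the
catch-position ratios lie in [0, 1] and are comparable across patients.
All "normalised" quantities are divided by the within-segment maximum of
the corresponding channel, making them invariant to channel gain.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from masgrade.io import FS_LOW
from masgrade.preprocess import StretchSegment, smoothed_derivative

#: Default Savitzky-Golay windows (ms) for the velocity and acceleration
#: estimates used in feature extraction and catch detection.
VELOCITY_SMOOTH_MS = 25.0
ACCEL_SMOOTH_MS = 101.0

KINEMATIC_FEATURES = (
    "rom",
    "catch_angle",
    "catch_angle_over_rom",
    "angle_max_semg",
    "angle_max_semg_over_rom",
    "angle_max_force",
    "angle_max_force_over_rom",
    "max_angular_velocity",
)

KINETIC_FEATURES = (
    "force_catch_over_initial",
    "norm_force_increment_at_catch",
    "norm_avg_force",
    "norm_avg_force_after_catch",
    "slope_force_after_max",
    "slope_force_after_catch",
)

PHYSIOLOGICAL_FEATURES = (
    "norm_semg_at_catch",
    "norm_avg_semg_after_catch",
    "norm_avg_slope_semg_after_catch",
)

#: Canonical order of the 17 unique features.
FEATURE_NAMES: tuple[str, ...] = (
    KINEMATIC_FEATURES + KINETIC_FEATURES + PHYSIOLOGICAL_FEATURES
)

#: Clinical grouping.  The catch-force ratio is shared between the kinetic
#: and physiological groups, which is why the physiological group counts
#: four members while the vector holds 17 unique values.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "kinematic": KINEMATIC_FEATURES,
    "kinetic": KINETIC_FEATURES,
    "physiological": ("force_catch_over_initial",) + PHYSIOLOGICAL_FEATURES,
}

#: Features divided by (or ratios of) the raw channel, hence invariant to a
#: uniform rescaling of the force or sEMG gain.
GAIN_INVARIANT_FEATURES = (
    "force_catch_over_initial",
    "norm_force_increment_at_catch",
    "norm_avg_force",
    "norm_avg_force_after_catch",
    "norm_semg_at_catch",
    "norm_avg_semg_after_catch",
    "norm_avg_slope_semg_after_catch",
)


class DegenerateSegmentError(ValueError):
    """Raised when a segment has no angular excursion (ratios undefined)."""


@dataclasses.dataclass(frozen=True)
class CatchEvent:
    """The detected catch: sample index, elbow excursion and time within the segment."""

    idx: int
    angle_at: float  # deg, excursion from segment start
    time_at: float  # s from segment start


def angular_velocity(
    angle: np.ndarray, fs: float = FS_LOW, smooth_ms: float = 0.0
) -> np.ndarray:
    """Angular velocity (deg/s).

    With ``smooth_ms=0`` (the primitive form): central finite differences
    on the interior, one-sided at the endpoints (``np.gradient``
    convention); exact for linear ramps.  A positive ``smooth_ms`` uses the
    Savitzky-Golay fitted derivative instead, which suppresses the
    fs-amplified sensor noise on measured signals.
    """
    angle = np.asarray(angle, dtype=float)
    if len(angle) < 3:
        raise ValueError(f"need >= 3 samples for a velocity estimate, got {len(angle)}")
    return smoothed_derivative(angle, fs=fs, deriv=1, smooth_ms=smooth_ms)


def detect_catch(
    angle: np.ndarray,
    fs: float = FS_LOW,
    guard_frac: float = 0.05,
    smooth_ms: float = ACCEL_SMOOTH_MS,
) -> CatchEvent:
    """Locate the catch as the instant of maximum deceleration.

    The angular acceleration is estimated by a fitted second derivative
    (cubic Savitzky-Golay over ``smooth_ms``); the catch is the
    acceleration minimum inside the interior window
    ``[guard_frac, 1 - guard_frac]`` of the segment (the guard avoids
    endpoint differentiation artefacts).  Ties break toward the earliest
    index.  An event is always returned: a stretch without a true catch
    (a non-spastic, MAS 0 arm) yields its ordinary peak movement
    deceleration, whose associated force and sEMG readings still help
    separate spastic from non-spastic cases.
    """
    angle = np.asarray(angle, dtype=float)
    n = len(angle)
    if n < int(np.ceil(3 / guard_frac)):
        raise ValueError(
            f"segment of {n} samples too short for catch detection "
            f"(need >= {int(np.ceil(3 / guard_frac))})"
        )
    win_ms = min(smooth_ms, 1000.0 * n / (4 * fs))  # keep the fit window inside the segment
    accel = smoothed_derivative(angle, fs=fs, deriv=2, smooth_ms=win_ms)
    lo = int(np.floor(guard_frac * n))
    hi = int(np.ceil((1 - guard_frac) * n))
    interior = accel[lo:hi]
    amin = float(interior.min())
    tol = 1e-9 * (abs(amin) + 1.0)  # earliest tie within numerical precision
    idx = lo + int(np.argmax(interior <= amin + tol))
    start_angle = float(angle[0])
    return CatchEvent(idx=idx, angle_at=float(angle[idx]) - start_angle, time_at=idx / fs)


def _interior_velocity(angle: np.ndarray, fs: float) -> np.ndarray:
    """Smoothed velocity with the edge half-windows trimmed.

    The fitted derivative extrapolates at the segment edges, where noise is
    strongly amplified; peak-velocity estimates use the interior only.
    """
    vel = angular_velocity(angle, fs, smooth_ms=VELOCITY_SMOOTH_MS)
    half = int(VELOCITY_SMOOTH_MS * fs / 1000.0) // 2
    return vel[half:-half] if len(vel) > 4 * half else vel


def _ols_slope(y: np.ndarray, fs: float) -> float:
    """Ordinary least-squares slope of y against time (per second)."""
    n = len(y)
    if n < 2:
        return 0.0
    t = np.arange(n) / fs
    return float(np.polyfit(t, y, 1)[0])


def extract_features(
    seg: StretchSegment,
    fs: float = FS_LOW,
    guard_frac: float = 0.05,
    init_frac: float = 0.05,
    f_init_floor: float = 1e-6,
) -> dict[str, float]:
    """Compute the 17 features of one stretch segment.

    ``init_frac`` sets the initial-force window (mean force over the first
    5% of the segment).  A non-positive initial force after zero-levelling
    is floored at ``f_init_floor`` with a warning so the catch-force ratio
    stays finite.
    """
    angle = np.asarray(seg.angle, dtype=float)
    force = np.asarray(seg.force, dtype=float)
    semg = np.asarray(seg.semg_env, dtype=float)

    a_min = float(angle.min())
    rom = float(angle.max() - a_min)
    if rom <= 0:
        raise DegenerateSegmentError("segment has zero range of motion")

    catch = detect_catch(angle, fs=fs, guard_frac=guard_frac)
    catch_angle = float(angle[catch.idx]) - a_min

    n_init = max(1, int(round(init_frac * len(angle))))
    f_init = float(force[:n_init].mean())
    if f_init <= 0:
        warnings.warn(
            f"initial force {f_init:.3g} N non-positive after levelling; "
            f"floored at {f_init_floor}",
            stacklevel=2,
        )
        f_init = f_init_floor

    f_max = float(force.max())
    s_max = float(semg.max())
    i_fmax = int(np.argmax(force))
    i_smax = int(np.argmax(semg))

    feats = {
        "rom": rom,
        "catch_angle": catch_angle,
        "catch_angle_over_rom": catch_angle / rom,
        "angle_max_semg": float(angle[i_smax]) - a_min,
        "angle_max_semg_over_rom": (float(angle[i_smax]) - a_min) / rom,
        "angle_max_force": float(angle[i_fmax]) - a_min,
        "angle_max_force_over_rom": (float(angle[i_fmax]) - a_min) / rom,
        "max_angular_velocity": float(np.max(_interior_velocity(angle, fs))),
        "force_catch_over_initial": float(force[catch.idx]) / f_init,
        "norm_force_increment_at_catch": (float(force[catch.idx]) - f_init)
        / f_max if f_max != 0 else 0.0,
        "norm_avg_force": float(force.mean()) / f_max if f_max != 0 else 0.0,
        "norm_avg_force_after_catch": float(force[catch.idx:].mean()) / f_max
        if f_max != 0 else 0.0,
        "slope_force_after_max": _ols_slope(force[i_fmax:], fs),
        "slope_force_after_catch": _ols_slope(force[catch.idx:], fs),
        "norm_semg_at_catch": float(semg[catch.idx]) / s_max if s_max != 0 else 0.0,
        "norm_avg_semg_after_catch": float(semg[catch.idx:].mean()) / s_max
        if s_max != 0 else 0.0,
        "norm_avg_slope_semg_after_catch": _ols_slope(semg[catch.idx:], fs) / s_max
        if s_max != 0 else 0.0,
    }
    return {name: feats[name] for name in FEATURE_NAMES}
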