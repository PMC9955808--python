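"""MAS-conditioned synthetic stretch sessions with planted ground truth.

Each simulated session follows the clinical protocol: three slow passive
stretches followed by three fast ones, separated by rest plateaus.  The
angle of each stretch is a minimum-jerk rise; a spastic catch is planted as
a localised Gaussian deceleration pulse at a grade-dependent fraction of
the excursion (only on fast stretches — the catch is velocity-dependent).
The resisting force holds a grade-dependent tone baseline and steps up by a
multiplicative gain at the catch; the surface EMG is an amplitude-modulated
broadband carrier with a burst at the catch.

Grade profiles respect the ordinal clinical structure: a MAS 1 catch sits
at the end of the range of motion, MAS 1+ in the second half, MAS 2 in the
first half; MAS 3 has elevated tone, suppressed velocity and reduced range;
MAS 4 is near-rigid with a range below 10 degrees; MAS 0 has no catch and
no force step.  The profile numbers themselves are synthetic fixture
parameters, not estimates of any clinical dataset.

Every generated quantity that the pipeline later estimates (stretch
boundaries, range of motion, catch position, force gain) is recorded as
ground truth, computed from the noise-free signals with the same boundary
convention the segmenter uses, so recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, signal
from scipy.optimize import brentq
from scipy.special import erf

from masgrade.io import FS_HIGH, FS_LOW, MAS_LABELS, StretchRecording
from masgrade.preprocess import _refine_window

#: Goniometer mounting split between the two planes (rad): the resultant of
#: the generated (angle_x, angle_y) pair equals the planted elbow angle.
PLANE_ANGLE = 0.35

#: Width of the planted catch deceleration pulse (s).
CATCH_SIGMA = 0.02

#: Transient velocity dip at the catch as a fraction of the local velocity.
#: Below 1 so the rise stays monotone through the catch.
CATCH_DEPTH_FRAC = 0.7

BASELINE_ANGLE = 15.0  # resting elbow angle, deg
FORCE_OFFSET = 1.2  # myometer zero offset, N (removed by levelling)
SEMG_BASE_AMP = 0.03  # resting sEMG amplitude, mV


@dataclasses.dataclass
class MasProfile:
    """Generator parameters for one MAS grade.

    Ranges are sampled per stretch; scalars apply to the whole session.
    ``catch_frac_range`` positions the catch within the normalised range of
    motion (``None`` plants no catch).  ``catch_force_gain`` multiplies the
    tone baseline at the catch; ``tone_level`` is the resisting-force
    plateau in N; velocity ranges are peak angular velocities in deg/s.
    """

    rom_range: tuple[float, float]
    catch_frac_range: Optional[tuple[float, float]]
    catch_force_gain: float
    tone_level: float
    velocity_slow: tuple[float, float]
    velocity_fast: tuple[float, float]
    semg_burst_gain: float
    noise_angle: float = 0.1  # deg, per goniometer plane
    noise_force: float = 0.08  # N
    noise_semg: float = 0.004  # mV

    def validate(self, mas: str) -> None:
        if self.rom_range[0] > self.rom_range[1] or self.rom_range[0] <= 0:
            raise ValueError(f"invalid rom_range {self.rom_range}")
        cfr = self.catch_frac_range
        if mas == "4" and self.rom_range[1] >= 10.0:
            raise ValueError("MAS 4 profile must keep the range of motion below 10 deg")
        if mas == "2" and not (cfr and 0.0 < cfr[0] and cfr[1] < 0.5):
            raise ValueError("MAS 2 catch must lie in the first half of the range")
        if mas == "1" and not (cfr and 0.8 < cfr[0] and cfr[1] < 1.0):
            raise ValueError("MAS 1 catch must lie at the end of the range")
        if mas == "1+" and not (cfr and 0.5 < cfr[0] and cfr[1] < 0.8):
            raise ValueError("MAS 1+ catch must lie in the second half of the range")
        if mas == "0" and (cfr is not None or self.catch_force_gain != 1.0):
            raise ValueError("MAS 0 profile must plant no catch and unit force gain")
        if mas == "3" and not (
            self.tone_level >= 8.0
            and self.velocity_fast[1] <= 100.0
            and self.rom_range[1] <= 80.0
        ):
            raise ValueError(
                "MAS 3 profile requires elevated tone, suppressed velocity "
                "and a reduced range of motion"
            )


DEFAULT_PROFILES: dict[str, MasProfile] = {
    "0": MasProfile((130, 150), None, 1.0, 3.0, (35, 55), (150, 200), 0.0),
    "1": MasProfile((120, 145), (0.82, 0.95), 1.35, 4.0, (35, 55), (140, 190), 0.12),
    "1+": MasProfile((105, 135), (0.55, 0.75), 1.6, 5.5, (35, 55), (130, 180), 0.18),
    "2": MasProfile((90, 125), (0.2, 0.45), 1.9, 7.0, (30, 50), (120, 170), 0.25),
    "3": MasProfile((40, 70), (0.1, 0.3), 2.2, 12.0, (18, 30), (45, 80), 0.3),
    "4": MasProfile((3.0, 7.0), None, 1.0, 16.0, (6, 10), (14, 25), 0.0),
}


@dataclasses.dataclass
class StretchTruth:
    """Planted per-stretch ground truth (indices on the 1000 Hz timebase)."""

    index: int
    speed: str
    start_idx: int  # 2% excursion crossing of the clean angle
    end_idx: int  # one past the 98% crossing
    rise_start: int  # nominal start of the minimum-jerk rise
    rise_end: int
    rom: float  # clean angular span inside [start_idx, end_idx)
    planted_rom: float  # nominal minimum-jerk amplitude
    peak_velocity: float
    catch_idx: Optional[int]  # session sample of maximum deceleration
    catch_frac: Optional[float]  # realised excursion fraction at the catch
    planted_catch_frac: Optional[float]
    force_gain: float
    tone: float


@dataclasses.dataclass
class GroundTruth:
    """Session-level planted truth: label plus one record per stretch."""

    mas_label: str
    fs: float
    stretches: list[StretchTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mas_label": self.mas_label,
            "fs": self.fs,
            "stretches": [dataclasses.asdict(s) for s in self.stretches],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _minjerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _minjerk_vel(u: np.ndarray) -> np.ndarray:
    return 30 * u**2 * (1 - u) ** 2


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0)))


def _build_rise(
    delta: float, duration: float, catch_frac: Optional[float], fs: float
) -> tuple[np.ndarray, Optional[int]]:
    """Minimum-jerk rise of amplitude ``delta`` with an optional catch.

    The catch is planted as a Gaussian deceleration pulse centred exactly
    at the excursion fraction ``catch_frac``, followed by an equal
    re-acceleration pulse 4 sigma later (the examiner pushing through the
    resistance), so the transient velocity dip — ``CATCH_DEPTH_FRAC`` of
    the local velocity — recovers fully and the planted range of motion is
    unchanged.  The symmetric deceleration lobe keeps the acceleration
    minimum at the planted instant under any symmetric smoothing.
    Returns (relative angle array, catch sample or None).
    """
    n = max(8, int(round(duration * fs)))
    t = np.arange(n) / fs
    u = np.clip(t / duration, 0.0, 1.0)
    angle = delta * _minjerk(u)
    if catch_frac is None:
        return angle, None
    u_f = brentq(lambda v: _minjerk(v) - catch_frac, 1e-9, 1 - 1e-9)
    t_catch = u_f * duration
    v_local = delta * _minjerk_vel(np.array(u_f))[()] / duration
    vdip = CATCH_DEPTH_FRAC * v_local  # deg/s
    sig = CATCH_SIGMA
    v_extra = -vdip * (
        _norm_cdf((t - t_catch) / sig) - _norm_cdf((t - t_catch - 4 * sig) / sig)
    )
    dip = integrate.cumulative_trapezoid(v_extra, dx=1.0 / fs, initial=0.0)
    angle = angle + dip
    return angle, int(round(t_catch * fs))


def _force_rise(
    t: np.ndarray,
    duration: float,
    tone: float,
    gain: float,
    catch_sample: Optional[int],
    fs: float,
) -> np.ndarray:
    rest = 0.1 * tone
    ramp = _smoothstep(t / max(0.08 * duration, 0.02))
    level = rest + (tone - rest) * ramp
    if catch_sample is not None and gain != 1.0:
        t_c = catch_sample / fs
        level = level + tone * (gain - 1.0) * _norm_cdf((t - (t_c - 0.03)) / 0.01)
    return level


class _SessionBuilder:
    def __init__(self, fs: float):
        self.fs = fs
        self.angle: list[np.ndarray] = []
        self.force: list[np.ndarray] = []
        self.amp: list[np.ndarray] = []
        self.n = 0

    def append(self, angle: np.ndarray, force: np.ndarray, amp: np.ndarray) -> int:
        start = self.n
        self.angle.append(angle)
        self.force.append(force)
        self.amp.append(amp)
        self.n += len(angle)
        return start

    def plateau(self, duration: float, angle_level: float, force_level: float) -> None:
        n = int(round(duration * self.fs))
        self.append(
            np.full(n, angle_level),
            np.full(n, force_level),
            np.full(n, SEMG_BASE_AMP),
        )


def generate_session(
    mas: str,
    seed,
    profile: Optional[MasProfile] = None,
    noise_scale: float = 1.0,
    n_slow: int = 3,
    n_fast: int = 3,
    subject_id: str = "synthetic",
    trial_id: str = "T1",
    **profile_overrides,
) -> tuple[StretchRecording, GroundTruth]:
    """Generate one synthetic session (slow stretches first, then fast).

    ``seed`` may be an int or a ``numpy`` SeedSequence; the output is
    bit-identical for equal seeds.  ``profile_overrides`` replace fields of
    the grade's default profile and are validated against the grade's
    structural invariants.  ``noise_scale`` multiplies all three channel
    noise levels (0 gives noise-free signals).
    """
    if mas not in MAS_LABELS:
        raise ValueError(f"unknown MAS grade {mas!r}")
    prof = profile or DEFAULT_PROFILES[mas]
    if profile_overrides:
        prof = dataclasses.replace(prof, **profile_overrides)
    prof.validate(mas)
    rng = np.random.default_rng(seed)
    fs = FS_LOW

    builder = _SessionBuilder(fs)
    rest_force = 0.1 * prof.tone_level
    builder.plateau(0.6, BASELINE_ANGLE, rest_force)

    plan: list[dict] = []
    for i in range(n_slow + n_fast):
        speed = "slow" if i < n_slow else "fast"
        delta = rng.uniform(*prof.rom_range)
        v_peak = rng.uniform(
            *(prof.velocity_slow if speed == "slow" else prof.velocity_fast)
        )
        duration = 1.875 * delta / v_peak  # minimum-jerk peak-velocity relation
        catch_frac = None
        if prof.catch_frac_range is not None and speed == "fast":
            catch_frac = rng.uniform(*prof.catch_frac_range)

        rise, catch_sample = _build_rise(delta, duration, catch_frac, fs)
        t = np.arange(len(rise)) / fs
        force = _force_rise(
            t, duration, prof.tone_level, prof.catch_force_gain, catch_sample, fs
        )
        amp = np.full(len(rise), SEMG_BASE_AMP)
        if catch_sample is not None and prof.semg_burst_gain > 0:
            amp = amp + prof.semg_burst_gain * np.exp(
                -((t - catch_sample / fs) ** 2) / (2 * 0.04**2)
            )
        rise_start = builder.append(BASELINE_ANGLE + rise, force, amp)

        top = BASELINE_ANGLE + rise[-1]
        n_hold = int(round(0.4 * fs))
        t_hold = np.arange(n_hold) / fs
        hold_force = force[-1] + (rest_force - force[-1]) * _smoothstep(t_hold / 0.3)
        builder.append(np.full(n_hold, top), hold_force, np.full(n_hold, SEMG_BASE_AMP))

        t_ret = max(0.4, 1.875 * (top - BASELINE_ANGLE) / 110.0)
        n_ret = int(round(t_ret * fs))
        u_ret = np.arange(n_ret) / max(n_ret - 1, 1)
        ret = top - (top - BASELINE_ANGLE) * _minjerk(u_ret)
        builder.append(
            ret, np.full(n_ret, rest_force), np.full(n_ret, SEMG_BASE_AMP)
        )
        builder.plateau(0.8, BASELINE_ANGLE, rest_force)

        plan.append(
            {
                "index": i,
                "speed": speed,
                "rise_start": rise_start,
                "rise_end": rise_start + len(rise),
                "planted_rom": delta,
                "peak_velocity": v_peak,
                "catch_sample": catch_sample,
                "planted_catch_frac": catch_frac,
            }
        )

    clean_angle = np.concatenate(builder.angle)
    clean_force = np.concatenate(builder.force) + FORCE_OFFSET
    amp_lo = np.concatenate(builder.amp)
    n_lo = len(clean_angle)

    truths = []
    for p in plan:
        start, end, _ = _refine_window(clean_angle, p["rise_start"], p["rise_end"])
        window = clean_angle[start:end]
        rom = float(window.max() - window.min())
        catch_idx = catch_frac = None
        if p["catch_sample"] is not None:
            catch_idx = p["rise_start"] + p["catch_sample"]
            catch_frac = float(
                (clean_angle[catch_idx] - window.min()) / rom
            )
        truths.append(
            StretchTruth(
                index=p["index"],
                speed=p["speed"],
                start_idx=start,
                end_idx=end,
                rise_start=p["rise_start"],
                rise_end=p["rise_end"],
                rom=rom,
                planted_rom=p["planted_rom"],
                peak_velocity=p["peak_velocity"],
                catch_idx=catch_idx,
                catch_frac=catch_frac,
                planted_catch_frac=p["planted_catch_frac"],
                force_gain=prof.catch_force_gain if p["catch_sample"] is not None else 1.0,
                tone=prof.tone_level,
            )
        )

    # split the planted angle across the two goniometer planes
    angle_x = clean_angle * np.cos(PLANE_ANGLE)
    angle_y = clean_angle * np.sin(PLANE_ANGLE)
    angle_x = angle_x + noise_scale * prof.noise_angle * rng.standard_normal(n_lo)
    angle_y = angle_y + noise_scale * prof.noise_angle * rng.standard_normal(n_lo)
    force = clean_force + noise_scale * prof.noise_force * rng.standard_normal(n_lo)

    # sEMG: amplitude-modulated broadband carrier at 2000 Hz
    n_hi = 2 * n_lo
    carrier = rng.standard_normal(n_hi)
    sos = signal.butter(2, [20, 450], btype="bandpass", fs=FS_HIGH, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier /= max(carrier.std(), 1e-12)
    amp_hi = np.repeat(amp_lo, 2)
    semg = amp_hi * carrier + noise_scale * prof.noise_semg * rng.standard_normal(n_hi)

    rec = StretchRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        time_lo=np.arange(n_lo) / fs,
        angle_x=angle_x,
        angle_y=angle_y,
        force=force,
        time_hi=np.arange(n_hi) / FS_HIGH,
        semg=semg,
        mas_label=mas,
    )
    return rec, GroundTruth(mas_label=mas, fs=fs, stretches=truths)


def generate_cohort(
    n_per_class: int,
    seed: int,
    labels: Sequence[str] = MAS_LABELS,
    noise_scale: float = 1.0,
) -> tuple[list[StretchRecording], list[str], list[GroundTruth]]:
    """Generate a balanced cohort: ``n_per_class`` sessions per grade.

    Per-session seeds are spawned from the master seed, so cohorts with the
    same master seed are bit-identical and different sessions draw from
    disjoint random streams.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels) * n_per_class)
    recordings, out_labels, truths = [], [], []
    k = 0
    for mas in labels:
        for i in range(n_per_class):
            rec, gt = generate_session(
                mas,
                children[k],
                noise_scale=noise_scale,
                subject_id=f"SYN-{mas}-{i:03d}",
                trial_id="T1",
            )
            recordings.append(rec)
            out_labels.append(mas)
            truths.append(gt)
            k += 1
    return recordings, out_labels, truths
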