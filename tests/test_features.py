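"""Catch detection and feature extraction against planted ground truth."""

import numpy as np
import pytest

from masgrade import features as ft
from masgrade.preprocess import StretchSegment


def _minjerk(u):
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _segment(angle, force=None, semg=None, speed="fast"):
    n = len(angle)
    force = np.full(n, 5.0) if force is None else force
    semg = np.full(n, 0.1) if semg is None else semg
    return StretchSegment(
        start_idx=0,
        end_idx=n,
        speed=speed,
        angle=np.asarray(angle, float),
        force=np.asarray(force, float),
        semg_env=np.asarray(semg, float),
        rom=float(np.max(angle) - np.min(angle)),
    )


def _catch_rise(delta=100.0, duration=2.0, catch_t=1.2, fs=1000.0, depth_frac=0.6):
    """Min-jerk rise with a symmetric deceleration/recovery pulse at catch_t."""
    t = np.arange(int(duration * fs)) / fs
    u = t / duration
    angle = delta * _minjerk(u)
    sig = 0.02
    v_local = delta * 30 * (catch_t / duration) ** 2 * (1 - catch_t / duration) ** 2 / duration
    from scipy.special import erf

    def cdf(z):
        return 0.5 * (1 + erf(z / np.sqrt(2)))

    v_extra = -depth_frac * v_local * (cdf((t - catch_t) / sig) - cdf((t - catch_t - 4 * sig) / sig))
    from scipy.integrate import cumulative_trapezoid

    return angle + cumulative_trapezoid(v_extra, dx=1 / fs, initial=0.0), t


class TestAngularVelocity:
    def test_linear_ramp_exact(self):
        angle = 50.0 * np.arange(1000) / 1000.0
        np.testing.assert_allclose(ft.angular_velocity(angle), 50.0, atol=1e-9)

    def test_constant_angle_zero(self):
        np.testing.assert_allclose(ft.angular_velocity(np.full(100, 12.0)), 0.0)

    def test_sinusoid_peak_closed_form(self):
        fs, f, amp = 1000.0, 1.0, 30.0
        t = np.arange(3000) / fs
        v = ft.angular_velocity(amp * np.sin(2 * np.pi * f * t), fs)
        assert np.max(v) == pytest.approx(2 * np.pi * f * amp, rel=0.005)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ft.angular_velocity(np.zeros(2))


class TestDetectCatch:
    def test_planted_deceleration_within_10ms(self):
        angle, t = _catch_rise(catch_t=1.2)
        catch = ft.detect_catch(angle)
        assert abs(catch.time_at - 1.2) <= 0.010

    def test_constant_deceleration_tie_breaks_earliest(self):
        # quadratic ease-out: acceleration constant everywhere, so every
        # interior sample ties and the earliest interior index wins
        n = 1000
        t = np.arange(n) / 1000.0
        angle = 100.0 * (2 * t - t**2)
        catch = ft.detect_catch(angle, guard_frac=0.05)
        assert catch.idx == int(np.floor(0.05 * n))

    def test_deeper_second_pulse_wins(self):
        angle1, t = _catch_rise(catch_t=0.6, depth_frac=0.3)
        angle2, _ = _catch_rise(catch_t=1.4, depth_frac=0.7)
        # superpose both pulses on one rise
        base = _catch_rise(catch_t=0.6, depth_frac=0.0)[0]
        angle = angle1 + angle2 - base
        catch = ft.detect_catch(angle)
        assert abs(catch.time_at - 1.4) <= 0.015

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ft.detect_catch(np.zeros(30))


class TestFeatureSchema:
    def test_counts_and_grouping(self):
        assert len(ft.FEATURE_NAMES) == 17
        assert len(set(ft.FEATURE_NAMES)) == 17
        assert len(ft.KINEMATIC_FEATURES) == 8
        assert len(ft.KINETIC_FEATURES) == 6
        assert len(ft.PHYSIOLOGICAL_FEATURES) == 3
        # the clinical grouping counts the shared force ratio twice
        assert len(ft.FEATURE_GROUPS["physiological"]) == 4
        assert "force_catch_over_initial" in ft.FEATURE_GROUPS["kinetic"]
        assert "force_catch_over_initial" in ft.FEATURE_GROUPS["physiological"]

    def test_extractor_emits_all_names(self):
        angle, _ = _catch_rise()
        feats = ft.extract_features(_segment(angle))
        assert tuple(feats) == ft.FEATURE_NAMES


class TestExtractFeatures:
    def test_planted_catch_position(self):
        # plant the catch at 40% excursion of a 100-degree rise; the
        # deceleration dip permanently costs depth * local velocity * 4 sigma
        # degrees of excursion, which the closed form accounts for
        from scipy.optimize import brentq

        delta, duration, depth = 100.0, 2.0, 0.6
        u_f = brentq(lambda v: _minjerk(v) - 0.4, 1e-9, 1 - 1e-9)
        angle, t = _catch_rise(
            delta=delta, duration=duration, catch_t=u_f * duration, depth_frac=depth
        )
        v_local = delta * 30 * u_f**2 * (1 - u_f) ** 2 / duration
        dip_loss = depth * v_local * 4 * 0.02
        feats = ft.extract_features(_segment(angle))
        assert feats["rom"] == pytest.approx(delta - dip_loss, abs=0.2)
        assert feats["catch_angle"] == pytest.approx(40.0, abs=1.0)
        assert feats["catch_angle_over_rom"] == pytest.approx(
            40.0 / (delta - dip_loss), abs=0.02
        )

    def test_constant_force_identities(self):
        angle, _ = _catch_rise()
        feats = ft.extract_features(_segment(angle, force=np.full(len(angle), 5.0)))
        assert feats["norm_avg_force"] == pytest.approx(1.0)
        assert feats["norm_force_increment_at_catch"] == pytest.approx(0.0, abs=1e-9)
        assert feats["slope_force_after_max"] == pytest.approx(0.0, abs=1e-9)

    def test_force_step_at_catch_doubles_ratio(self):
        angle, t = _catch_rise(catch_t=1.2)
        catch_idx = ft.detect_catch(angle).idx
        force = np.full(len(angle), 3.0)
        force[catch_idx:] = 6.0  # F -> 2F exactly at the catch
        feats = ft.extract_features(_segment(angle, force=force))
        assert feats["force_catch_over_initial"] == pytest.approx(2.0)

    def test_gain_invariance_of_normalised_features(self):
        angle, _ = _catch_rise()
        rng = np.random.default_rng(4)
        force = 5.0 + np.cumsum(rng.normal(0, 0.01, len(angle)))
        semg = 0.1 + np.abs(np.sin(np.arange(len(angle)) / 100.0)) * 0.2
        base = ft.extract_features(_segment(angle, force=force, semg=semg))
        scaled = ft.extract_features(
            _segment(angle, force=3.7 * force, semg=0.42 * semg)
        )
        for name in ft.GAIN_INVARIANT_FEATURES:
            assert scaled[name] == pytest.approx(base[name], abs=1e-9), name

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ft.DegenerateSegmentError):
            ft.extract_features(_segment(np.full(1000, 30.0)))

    def test_nonpositive_initial_force_floored_with_warning(self):
        angle, _ = _catch_rise()
        force = np.linspace(-1.0, 5.0, len(angle))
        with pytest.warns(UserWarning, match="initial force"):
            feats = ft.extract_features(_segment(angle, force=force))
        assert np.isfinite(feats["force_catch_over_initial"])


class TestNoiseFreeRecovery:
    def test_planted_features_recovered(self, clean_sessions):
        from masgrade.pipeline import extract_session_features

        for mas, (rec, gt) in clean_sessions.items():
            table = extract_session_features(rec)
            fast = table[table.speed == "fast"].reset_index(drop=True)
            truths = [s for s in gt.stretches if s.speed == "fast"]
            for (_, row), truth in zip(fast.iterrows(), truths):
                assert row["rom"] == pytest.approx(truth.rom, abs=1.0)
                if truth.catch_frac is not None:
                    assert row["catch_angle_over_rom"] == pytest.approx(
                        truth.catch_frac, abs=0.05
                    )
                    # closed form for the levelled force ratio: rest = 10% of
                    # tone, so the ratio is (gain - 0.1) / 0.9
                    expected = (truth.force_gain - 0.1) / 0.9
                    assert row["force_catch_over_initial"] == pytest.approx(
                        expected, rel=0.02
                    )
                    assert (
                        abs(row["force_catch_over_initial"] - truth.force_gain)
                        <= 0.1 * truth.force_gain
                    )
                    assert row["norm_semg_at_catch"] > 0.9

    def test_max_velocity_recovered_without_catch(self, clean_sessions):
        from masgrade.pipeline import extract_session_features

        rec, gt = clean_sessions["0"]
        table = extract_session_features(rec)
        for (_, row), truth in zip(table.iterrows(), gt.stretches):
            assert row["max_angular_velocity"] == pytest.approx(
                truth.peak_velocity, rel=0.02
            )


class TestCatchRatioConsistency:
    def test_early_catch_below_half_late_catch_above(self, clean_sessions):
        from masgrade.pipeline import extract_session_features

        early = extract_session_features(clean_sessions["2"][0])
        late = extract_session_features(clean_sessions["1"][0])
        assert (early[early.speed == "fast"]["catch_angle_over_rom"] < 0.5).all()
        assert (late[late.speed == "fast"]["catch_angle_over_rom"] > 0.8).all()
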