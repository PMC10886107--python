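"""Stabilometric metric oracles: hand arithmetic, closed forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copsway.metrics import (
    FEATURE_NAMES,
    CenteredTrajectory,
    CopTrajectory,
    InvalidTrajectoryError,
    center_stabilogram,
    distance_metrics,
    extract_features,
    mean_frequency,
    path_metrics,
    sway_area_rate,
)

from conftest import circle_closed_forms, make_circle, make_random_trajectory


def _features_dict(traj, **kw):
    return extract_features(traj, **kw).as_dict()


class TestCentering:
    def test_mean_subtraction(self):
        traj = CopTrajectory(time=[0, 1, 2], ap=[1, 2, 3], ml=[4, 5, 6])
        c = center_stabilogram(traj)
        np.testing.assert_allclose(c.ap_c, [-1, 0, 1], atol=1e-12)
        np.testing.assert_allclose(c.ml_c, [-1, 0, 1], atol=1e-12)
        assert c.dt == 1.0 and c.duration == 2.0

    def test_constant_path_centers_to_zero(self):
        traj = CopTrajectory(time=[0, 1, 2], ap=[7, 7, 7], ml=[7, 7, 7])
        c = center_stabilogram(traj)
        np.testing.assert_allclose(c.ap_c, 0, atol=1e-12)
        np.testing.assert_allclose(c.ml_c, 0, atol=1e-12)

    def test_circle_already_centered_over_whole_periods(self, circle):
        # sinusoids over integer cycles average to zero analytically
        assert abs(circle.ap.mean()) < 1e-6
        assert abs(circle.ml.mean()) < 1e-6
        c = center_stabilogram(circle)
        np.testing.assert_allclose(c.ap_c, circle.ap, atol=1e-5)

    @pytest.mark.parametrize("bad", [
        dict(time=[0.0], ap=[1.0], ml=[1.0]),                # < 2 samples
        dict(time=[0, 1, 2], ap=[1, np.nan, 3], ml=[0, 0, 0]),  # non-finite
        dict(time=[0, 1, 1.5], ap=[1, 2, 3], ml=[0, 0, 0]),  # non-uniform dt
        dict(time=[0, 2, 1], ap=[1, 2, 3], ml=[0, 0, 0]),    # non-monotone
        dict(time=[0, 1], ap=[1, 2, 3], ml=[0, 0]),          # length mismatch
    ])
    def test_invalid_trajectories_rejected(self, bad):
        with pytest.raises(InvalidTrajectoryError):
            CopTrajectory(**bad)


class TestHandExamples:
    def test_distance_metrics(self):
        c = CenteredTrajectory(
            ap_c=np.array([-1.0, 0.0, 1.0]), ml_c=np.zeros(3),
            dt=1.0, duration=2.0)
        d = distance_metrics(c)
        assert d.MD_AP == pytest.approx(2 / 3)
        assert d.RMS_AP == pytest.approx(np.sqrt(2 / 3))
        assert d.MD_ML == 0.0
        assert d.MD_COP == pytest.approx(2 / 3)
        assert d.RMS_COP == pytest.approx(np.sqrt(2 / 3))

    def test_path_metrics_3_4_5_triangle(self):
        c = CenteredTrajectory(
            ap_c=np.array([0.0, 3.0, 3.0]), ml_c=np.array([0.0, 4.0, 4.0]),
            dt=1.0, duration=2.0)
        p = path_metrics(c)
        assert p.ESC_COP == pytest.approx(5.0)
        assert p.ESC_AP == pytest.approx(3.0)
        assert p.ESC_ML == pytest.approx(4.0)
        assert p.VEL_COP == pytest.approx(2.5)

    def test_sway_area_diamond(self):
        # diamond path: cross-product sum is 3, so SWAY = 3 / (2T)
        c = CenteredTrajectory(
            ap_c=np.array([1.0, 0.0, -1.0, 0.0]),
            ml_c=np.array([0.0, 1.0, 0.0, -1.0]),
            dt=1.0, duration=3.0)
        assert sway_area_rate(c) == pytest.approx(3.0 / (2 * 3.0))

    def test_sway_area_of_line_is_zero(self):
        t = np.arange(100) / 10
        ap = 5 * np.sin(2 * np.pi * 0.5 * t)
        c = center_stabilogram(CopTrajectory(time=t, ap=ap, ml=0 * t))
        assert sway_area_rate(c) == 0.0

    def test_constant_trajectory_zero_metrics_flagged_freqs(self):
        traj = CopTrajectory(time=[0, 1, 2], ap=[7, 7, 7], ml=[7, 7, 7])
        f = extract_features(traj)
        assert f.ESC_COP == 0 and f.VEL_COP == 0 and f.MD_COP == 0
        assert np.isnan(f.FREQ_COP) and np.isnan(f.FREQ_AP)
        assert set(f.undefined_freqs) == {"FREQ_COP", "FREQ_AP", "FREQ_ML"}


class TestMeanFrequency:
    def test_pure_ap_sinusoid_closed_form(self):
        # amplitude a, frequency f: VEL_AP = 4af, MD_AP = 2a/π,
        # so FREQ_AP = πf/2
        a, f, fs, dur = 7.0, 0.5, 200.0, 60.0
        t = np.arange(round(dur * fs) + 1) / fs
        traj = CopTrajectory(time=t, ap=a * np.sin(2 * np.pi * f * t),
                             ml=np.zeros_like(t))
        feats = extract_features(traj)
        assert feats.VEL_AP == pytest.approx(4 * a * f, rel=1e-3)
        assert feats.MD_AP == pytest.approx(2 * a / np.pi, rel=1e-3)
        assert feats.FREQ_AP == pytest.approx(np.pi * f / 2, rel=1e-3)
        assert "FREQ_ML" in feats.undefined_freqs

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mean_frequency((1.0, -1.0, 1.0), (1.0, 1.0, 1.0))

    def test_rotational_component_form(self):
        f = mean_frequency((2.0, 2.0, 2.0), (8.0, 8.0, 8.0),
                           component_form="rotational")
        assert f.FREQ_AP == pytest.approx(8.0 / (2 * np.pi * 2.0))
        p = mean_frequency((2.0, 2.0, 2.0), (8.0, 8.0, 8.0))
        assert p.FREQ_AP == pytest.approx(1.0)  # 8 / (4·2)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            mean_frequency((1, 1, 1), (1, 1, 1), component_form="fourier")


class TestCircleOracle:
    def test_all_16_features_match_closed_forms(self, circle):
        feats = _features_dict(circle)
        closed = circle_closed_forms(duration=circle.duration)
        for name, expected in closed.items():
            assert feats[name] == pytest.approx(expected, rel=5e-3), name

    def test_convergence_with_sampling_rate(self):
        # each feature's error vs its closed form shrinks as fs doubles
        errors = {name: [] for name in FEATURE_NAMES}
        for fs in (25.0, 50.0, 100.0, 200.0):
            traj = make_circle(fs=fs)
            feats = _features_dict(traj)
            closed = circle_closed_forms(duration=traj.duration)
            for name in FEATURE_NAMES:
                errors[name].append(
                    abs(feats[name] - closed[name]) / closed[name])
        # FREQ_AP/FREQ_ML are ratios of two O(h²)-convergent quantities:
        # their errors can cancel at particular rates, so only bounded
        # convergence is guaranteed; everything else shrinks monotonically
        ratio_features = {"FREQ_AP", "FREQ_ML"}
        for name, errs in errors.items():
            if name in ratio_features:
                assert max(errs) < 1.5e-3, (name, errs)
                assert errs[-1] < 2e-4, (name, errs)
            else:
                assert errs[-1] < 1e-3, (name, errs)
                for lo, hi in zip(errs[1:], errs[:-1]):
                    assert lo <= hi + 1e-10, (name, errs)


class TestInvariances:
    def test_translation_invariance_specific(self, circle):
        base = _features_dict(circle)
        shifted = CopTrajectory(time=circle.time, ap=circle.ap + 5.0,
                                ml=circle.ml - 3.0)
        for name, value in _features_dict(shifted).items():
            assert value == pytest.approx(base[name], rel=1e-9), name

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset_ap=st.floats(-50, 50), offset_ml=st.floats(-50, 50),
           seed=st.integers(0, 2**16))
    def test_translation_invariance(self, offset_ap, offset_ml, seed):
        traj = make_random_trajectory(np.random.default_rng(seed), n=200)
        base = _features_dict(traj)
        shifted = CopTrajectory(time=traj.time, ap=traj.ap + offset_ap,
                                ml=traj.ml + offset_ml)
        for name, value in _features_dict(shifted).items():
            assert value == pytest.approx(base[name], rel=1e-9, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_scale_equivariance(self, c, seed):
        # distances/excursions/velocities scale by c, SWAY by c², FREQ by 1
        traj = make_random_trajectory(np.random.default_rng(seed), n=200)
        base = _features_dict(traj)
        scaled = CopTrajectory(time=traj.time, ap=c * traj.ap,
                               ml=c * traj.ml)
        feats = _features_dict(scaled)
        for name in FEATURE_NAMES:
            if name == "SWAY":
                expected = base[name] * c * c
            elif name.startswith("FREQ"):
                expected = base[name]
            else:
                expected = base[name] * c
            assert feats[name] == pytest.approx(expected, rel=1e-9), name

    def test_time_reversal_invariance(self, rng):
        for _ in range(10):
            traj = make_random_trajectory(rng, n=300)
            base = _features_dict(traj)
            rev = CopTrajectory(time=traj.time, ap=traj.ap[::-1],
                                ml=traj.ml[::-1])
            for name, value in _features_dict(rev).items():
                assert value == pytest.approx(base[name], rel=1e-9), name

    def test_structural_inequalities_on_random_paths(self, rng):
        # Jensen ordering, Pythagorean RMS identity, excursion triangle
        # bounds — on 100 random trajectories
        for _ in range(100):
            f = extract_features(make_random_trajectory(rng, n=250))
            assert f.RMS_COP >= f.MD_COP
            assert f.RMS_AP >= f.MD_AP
            assert f.RMS_ML >= f.MD_ML
            assert f.RMS_COP ** 2 == pytest.approx(
                f.RMS_AP ** 2 + f.RMS_ML ** 2, rel=1e-9)
            assert max(f.ESC_AP, f.ESC_ML) <= f.ESC_COP * (1 + 1e-12)
            assert f.ESC_COP <= (f.ESC_AP + f.ESC_ML) * (1 + 1e-12)


def _naive_features(traj: CopTrajectory) -> dict[str, float]:
    """Loop-based reimplementation of every formula (test oracle)."""
    n = len(traj.ap)
    mean_ap = sum(traj.ap) / n
    mean_ml = sum(traj.ml) / n
    ap = [a - mean_ap for a in traj.ap]
    ml = [m - mean_ml for m in traj.ml]
    duration = traj.time[-1] - traj.time[0]

    md_cop = sum((a * a + m * m) ** 0.5 for a, m in zip(ap, ml)) / n
    md_ap = sum(abs(a) for a in ap) / n
    md_ml = sum(abs(m) for m in ml) / n
    rms_cop = (sum(a * a + m * m for a, m in zip(ap, ml)) / n) ** 0.5
    rms_ap = (sum(a * a for a in ap) / n) ** 0.5
    rms_ml = (sum(m * m for m in ml) / n) ** 0.5
    esc_cop = sum(((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2) ** 0.5
                  for i in range(n - 1))
    esc_ap = sum(abs(ap[i + 1] - ap[i]) for i in range(n - 1))
    esc_ml = sum(abs(ml[i + 1] - ml[i]) for i in range(n - 1))
    sway = sum(abs(ap[i + 1] * ml[i] - ap[i] * ml[i + 1])
               for i in range(n - 1)) / (2 * duration)
    vel_cop, vel_ap, vel_ml = (e / duration for e in (esc_cop, esc_ap, esc_ml))
    return {
        "MD_COP": md_cop, "MD_AP": md_ap, "MD_ML": md_ml,
        "RMS_COP": rms_cop, "RMS_AP": rms_ap, "RMS_ML": rms_ml,
        "ESC_COP": esc_cop, "ESC_AP": esc_ap, "ESC_ML": esc_ml,
        "VEL_COP": vel_cop, "VEL_AP": vel_ap, "VEL_ML": vel_ml,
        "SWAY": sway,
        "FREQ_COP": vel_cop / (2 * np.pi * md_cop),
        "FREQ_AP": vel_ap / (4 * md_ap),
        "FREQ_ML": vel_ml / (4 * md_ml),
    }


def test_naive_loop_oracle_equivalence(rng):
    """Production metrics agree with a naive loop implementation to 1e-9."""
    for _ in range(100):
        traj = make_random_trajectory(rng, n=150)
        feats = _features_dict(traj)
        oracle = _naive_features(traj)
        for name, expected in oracle.items():
            assert feats[name] == pytest.approx(expected, rel=1e-9), name


def test_lowpass_hook_reduces_path_length(rng):
    """The optional low-pass stage removes high-frequency path length but
    barely affects the slow positional spread."""
    traj = make_random_trajectory(rng, n=2000, fs=100.0)
    raw = extract_features(traj)
    filtered = extract_features(traj, lowpass_hz=5.0)
    assert filtered.ESC_COP < raw.ESC_COP
    assert filtered.RMS_COP == pytest.approx(raw.RMS_COP, rel=0.1)
    with pytest.raises(ValueError):
        extract_features(traj, lowpass_hz=60.0)  # above Nyquist
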