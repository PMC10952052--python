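import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exobench import exo as xo
from exobench.kinematics import (Phase, PhaseSegmentation, first_lift_cycle,
                                 segment_phases, trunk_inclination)
from exobench.markers import MarkerFrameSeries

from conftest import make_series


def _band_model(k_load=2.0, k_unload=1.0, bilateral=False, arm=0.10):
    pairs = [("LBAND_T", "LBAND_M")] + ([("RBAND_T", "RBAND_M")]
                                        if bilateral else [])
    return xo.SoftExoModel(name="test_band",
                           loading_coeffs=[0.0, k_load],
                           unloading_coeffs=[0.0, k_unload],
                           elongation_range=(0.0, 50.0),
                           band_marker_labels=pairs, moment_arm=arm)


def _triangular_band_series(peak_mm=10.0, n=200, rate=128.0):
    """Band markers separating by a triangular elongation profile."""
    half = n // 2
    elong = np.concatenate([np.linspace(0, peak_mm, half),
                            np.linspace(peak_mm, 0, half)]) / 1000.0
    t_marker = np.column_stack([0.1 + elong, np.zeros(n), np.ones(n)])
    m_marker = np.tile([0.0, 0.0, 1.0], (n, 1))
    series = make_series({"LBAND_T": t_marker, "LBAND_M": m_marker},
                         rate=rate)
    seg = PhaseSegmentation(segments=[(Phase.FLEXION, 0, half),
                                      (Phase.EXTENSION, half, n)], rate=rate)
    return series, seg


class TestBandElongation:
    def test_first_frame_is_zero(self):
        series, _ = _triangular_band_series()
        elong = xo.band_elongation(series, _band_model())
        assert elong[0] == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_separation(self):
        series, _ = _triangular_band_series(peak_mm=20.8)
        elong = xo.band_elongation(series, _band_model())
        assert elong.max() == pytest.approx(20.8, abs=1e-9)

    def test_matches_generator_truth(self, anthro, darwing_model):
        from exobench.synthetic import Task, TaskSpec, generate_lift_kinematics

        series, gt = generate_lift_kinematics(
            anthro, TaskSpec(task=Task.STOOP), exo=darwing_model,
            marker_noise_std=0.0)
        elong = xo.band_elongation(series, darwing_model)
        assert np.abs(elong - gt.true_elongation).max() < 1e-6


class TestSoftMoment:
    def test_bilinear_triangular_profile(self):
        series, seg = _triangular_band_series(peak_mm=10.0)
        moment = xo.soft_assistive_moment(series, seg, _band_model())
        half = series.n_frames // 2
        assert moment[:half].max() == pytest.approx(2.0, rel=1e-9)
        assert moment[half:].max() == pytest.approx(1.0, rel=1e-6)

    def test_constant_force_times_arm(self):
        series, seg = _triangular_band_series()
        model = xo.SoftExoModel(name="const", loading_coeffs=[47.0],
                                unloading_coeffs=[47.0],
                                elongation_range=(0.0, 50.0),
                                band_marker_labels=[("LBAND_T", "LBAND_M")],
                                moment_arm=0.10)
        moment = xo.soft_assistive_moment(series, seg, model)
        np.testing.assert_allclose(moment, 4.7, rtol=1e-12)

    def test_moment_arm_linearity(self):
        series, seg = _triangular_band_series()
        m1 = xo.soft_assistive_moment(series, seg, _band_model(arm=0.10))
        m2 = xo.soft_assistive_moment(series, seg, _band_model(arm=0.20))
        np.testing.assert_allclose(m2, 2.0 * m1, rtol=1e-12)

    def test_bilateral_bands_sum(self):
        n = 200
        series_uni, seg = _triangular_band_series(n=n)
        both = {lab: series_uni.get(lab).copy()
                for lab in ("LBAND_T", "LBAND_M")}
        both["RBAND_T"] = both["LBAND_T"] + [0.0, -0.1, 0.0]
        both["RBAND_M"] = both["LBAND_M"] + [0.0, -0.1, 0.0]
        series_bi = make_series(both, rate=series_uni.rate)
        m_uni = xo.soft_assistive_moment(series_uni, seg, _band_model())
        m_bi = xo.soft_assistive_moment(series_bi, seg,
                                        _band_model(bilateral=True))
        np.testing.assert_allclose(m_bi, 2.0 * m_uni, rtol=1e-9)

    def test_invariant_to_rigid_body_motion(self):
        from scipy.spatial.transform import Rotation

        series, seg = _triangular_band_series()
        m_ref = xo.soft_assistive_moment(series, seg, _band_model())
        rot = Rotation.from_euler("zyx", [30.0, 20.0, 10.0], degrees=True)
        moved = MarkerFrameSeries(
            labels=series.labels,
            positions=rot.apply(series.positions.reshape(-1, 3)).reshape(
                series.positions.shape) + np.array([0.5, 0.5, 0.5]),
            rate=series.rate, time=series.time)
        np.testing.assert_allclose(
            xo.soft_assistive_moment(moved, seg, _band_model()), m_ref,
            atol=1e-9)

    def test_out_of_range_elongation_clips_with_warning(self):
        series, seg = _triangular_band_series(peak_mm=80.0)
        with pytest.warns(UserWarning, match="outside fit range"):
            moment = xo.soft_assistive_moment(series, seg, _band_model())
        assert moment.max() == pytest.approx(2.0 * 50.0 * 0.10, rel=1e-9)


def _naive_rigid_moment(series, model, tau):
    """Loop-based reference: force resolution + determinant cross product."""
    clav_l, hip_l, thigh_l = model.attachment_labels
    out = np.empty(series.n_frames)
    for i in range(series.n_frames):
        clav = series.get(clav_l)[i]
        hip = series.get(hip_l)[i]
        thigh = series.get(thigh_l)[i]
        sac = 0.5 * (series.get("LPSI")[i] + series.get("RPSI")[i])
        b1 = hip - clav
        b2 = thigh - hip
        n = [b1[1] * b2[2] - b1[2] * b2[1],
             b1[2] * b2[0] - b1[0] * b2[2],
             b1[0] * b2[1] - b1[1] * b2[0]]
        d = [n[1] * b1[2] - n[2] * b1[1],
             n[2] * b1[0] - n[0] * b1[2],
             n[0] * b1[1] - n[1] * b1[0]]
        dn = np.sqrt(d[0]**2 + d[1]**2 + d[2]**2)
        f = [tau[i] / np.linalg.norm(b1) * c / dn for c in d]
        r = clav - sac
        my = r[2] * f[0] - r[0] * f[2]
        out[i] = abs(my)
    return out


class TestRigidMoment:
    def test_cross_product_against_brute_force(self):
        rng = np.random.default_rng(123)
        n = 100
        pos = {
            "CLAV": rng.normal([0.3, 0.0, 1.4], 0.2, (n, 3)),
            "EXO_HIP": rng.normal([0.05, 0.0, 0.95], 0.05, (n, 3)),
            "EXO_THIGH": rng.normal([0.05, 0.0, 0.6], 0.05, (n, 3)),
            "LPSI": rng.normal([0.0, 0.06, 1.0], 0.02, (n, 3)),
            "RPSI": rng.normal([0.0, -0.06, 1.0], 0.02, (n, 3)),
        }
        series = make_series(pos, rate=128.0)
        model = xo.RigidExoModel(name="probe", loading_coeffs=[5.0, 0.3],
                                 unloading_coeffs=[5.0, 0.3],
                                 alpha_range=(0.0, 180.0))
        seg = PhaseSegmentation(
            segments=[(Phase.FLEXION, 0, n)], rate=128.0)
        moment, _ = xo.rigid_assistive_moment(series, seg, model)
        from exobench.kinematics import exo_angle

        tau = model.torque(exo_angle(series).angle, "loading")
        expected = _naive_rigid_moment(series, model, tau)
        assert np.abs(moment - expected).max() < 1e-9

    def test_planar_pose_torque_scaling(self):
        """Perpendicular r and F: sagittal moment = |r| * |F|."""
        n = 4
        pos = {
            "CLAV": np.tile([0.374, 0.0, 1.0], (n, 1)),
            "EXO_HIP": np.tile([0.0, 0.0, 1.0], (n, 1)),
            "EXO_THIGH": np.tile([0.0, 0.0, 0.6], (n, 1)),
            "LPSI": np.tile([0.0, 0.06, 1.0], (n, 1)),
            "RPSI": np.tile([0.0, -0.06, 1.0], (n, 1)),
        }
        series = make_series(pos, rate=128.0)
        tau_const = 98.66 * 0.374  # torque giving |F| = 98.66 N at |B1|=0.374
        model = xo.RigidExoModel(name="probe", loading_coeffs=[tau_const],
                                 unloading_coeffs=[tau_const],
                                 alpha_range=(0.0, 180.0))
        seg = PhaseSegmentation(segments=[(Phase.FLEXION, 0, n)], rate=128.0)
        moment, arm = xo.rigid_assistive_moment(series, seg, model)
        np.testing.assert_allclose(moment, 0.374 * 98.66, rtol=1e-9)
        np.testing.assert_allclose(arm, 0.374, rtol=1e-9)

    def test_zero_torque_gives_zero_moment(self):
        series = _rigid_demo_series()
        model = xo.RigidExoModel(name="zero", loading_coeffs=[0.0],
                                 unloading_coeffs=[0.0])
        seg = PhaseSegmentation(segments=[(Phase.FLEXION, 0,
                                           series.n_frames)], rate=series.rate)
        moment, _ = xo.rigid_assistive_moment(series, seg, model)
        np.testing.assert_allclose(moment, 0.0, atol=1e-12)


def _rigid_demo_series(n=8):
    return make_series({
        "CLAV": np.tile([0.3, 0.0, 1.4], (n, 1)),
        "EXO_HIP": np.tile([0.05, 0.0, 0.95], (n, 1)),
        "EXO_THIGH": np.tile([0.05, 0.0, 0.6], (n, 1)),
        "LPSI": np.tile([0.0, 0.06, 1.0], (n, 1)),
        "RPSI": np.tile([0.0, -0.06, 1.0], (n, 1)),
    })


def _linear_curve(k_load, k_unload, theta_max_rad=1.0, n=257):
    theta = np.degrees(np.linspace(0, theta_max_rad, n))
    return xo.MomentAngleCurve(
        flexion_theta=theta, flexion_moment=k_load * np.radians(theta),
        extension_theta=theta[::-1],
        extension_moment=k_unload * np.radians(theta[::-1]))


class TestHysteresis:
    def test_identical_branches_lose_nothing(self):
        h = xo.hysteresis(_linear_curve(40.0, 40.0))
        assert h.loss == pytest.approx(0.0, abs=1e-12)
        assert h.loss_percent == pytest.approx(0.0, abs=1e-9)

    def test_linear_triangle_closed_form(self):
        h = xo.hysteresis(_linear_curve(40.0, 24.0))
        assert h.loading_area == pytest.approx(20.0, rel=1e-4)
        assert h.unloading_area == pytest.approx(12.0, rel=1e-4)
        assert h.loss == pytest.approx(8.0, rel=1e-3)
        assert h.loss_percent == pytest.approx(40.0, rel=1e-3)

    def test_cubic_branches_against_antiderivative(self):
        coeffs_load = [0.0, 30.0, -8.0, 1.5]   # M(θ), θ in rad
        coeffs_unload = [0.0, 18.0, -5.0, 0.9]
        n = 2049
        theta_rad = np.linspace(0.0, 1.2, n)
        poly = np.polynomial.polynomial
        curve = xo.MomentAngleCurve(
            flexion_theta=np.degrees(theta_rad),
            flexion_moment=poly.polyval(theta_rad, coeffs_load),
            extension_theta=np.degrees(theta_rad[::-1]),
            extension_moment=poly.polyval(theta_rad[::-1], coeffs_unload))
        h = xo.hysteresis(curve)
        exact_load = poly.polyval(1.2, poly.polyint(coeffs_load))
        exact_unload = poly.polyval(1.2, poly.polyint(coeffs_unload))
        assert h.loading_area == pytest.approx(exact_load, rel=1e-3)
        assert h.unloading_area == pytest.approx(exact_unload, rel=1e-3)

    def test_nonpositive_loading_area_flagged(self):
        curve = _linear_curve(0.0, 0.0)
        h = xo.hysteresis(curve)
        assert np.isnan(h.loss_percent)

    @settings(max_examples=30, deadline=None)
    @given(k_load=st.floats(5.0, 80.0),
           ratio=st.floats(0.0, 1.0))
    def test_loss_percent_bounded_for_nested_branches(self, k_load, ratio):
        h = xo.hysteresis(_linear_curve(k_load, ratio * k_load))
        assert -1e-6 <= h.loss_percent <= 100.0 + 1e-6


class TestMomentAngleCurve:
    def test_flexion_branch_monotone_on_synthetic_trial(self, rigid_stoop_trial,
                                                        laevo_model):
        series, _ = rigid_stoop_trial
        theta = trunk_inclination(series)
        seg = segment_phases(theta)
        moment, _ = xo.rigid_assistive_moment(series, seg, laevo_model)
        curve = xo.build_moment_angle_curve(moment, theta,
                                            first_lift_cycle(seg))
        # theta rises monotonically up to the branch peak; dead-band frames
        # attached at the tail may dip marginally below the peak
        k = int(np.argmax(curve.flexion_theta))
        assert np.all(np.diff(curve.flexion_theta[:k + 1]) > -1e-9)
        assert curve.flexion_theta.max() - curve.flexion_theta[-1] < 0.5
        lo = max(curve.flexion_theta.min(), curve.extension_theta.min())
        hi = min(curve.flexion_theta.max(), curve.extension_theta.max())
        step = np.max(np.abs(np.diff(curve.flexion_theta)))
        assert curve.flexion_theta.max() - hi <= 2 * step
        assert lo - curve.flexion_theta.min() <= 2 * step

    def test_constant_hold_has_no_cycle(self):
        import numpy as np
        from exobench.kinematics import AngleSeries

        n = 512
        angles = AngleSeries(angle=np.full(n, 40.0), velocity=np.zeros(n),
                             rate=128.0, time=np.arange(n) / 128.0)
        with pytest.warns(UserWarning):
            seg = segment_phases(angles)
        with pytest.raises(ValueError):
            first_lift_cycle(seg)


class TestSummaries:
    def test_single_curve_summary_equals_curve_metrics(self):
        curve = _linear_curve(40.0, 24.0)
        curve.task, curve.exo = "Stoop", "demo"
        out = xo.summarize_assistance([{"exo": "demo", "task": "Stoop",
                                        "curve": curve,
                                        "moment_arm_max": 0.374}])
        row = out["peaks"].iloc[0]
        peak, at = curve.peak()
        assert row["peak_moment_Nm"] == pytest.approx(peak)
        assert row["moment_arm_max_cm"] == pytest.approx(37.4)
        h = xo.hysteresis(curve)
        cell = out["hysteresis"].iloc[0]
        assert cell["loss_Nmrad"] == pytest.approx(h.loss)

    def test_mean_of_identical_curves_is_unchanged(self):
        curve = _linear_curve(40.0, 24.0)
        curve.task, curve.exo = "Stoop", "demo"
        rec = {"exo": "demo", "task": "Stoop", "curve": curve,
               "moment_arm_max": 0.3}
        one = xo.summarize_assistance([rec])
        two = xo.summarize_assistance([rec, dict(rec)])
        assert one["hysteresis"]["loss_Nmrad"].iloc[0] == pytest.approx(
            two["hysteresis"]["loss_Nmrad"].iloc[0])


class TestModelFiles:
    def test_yaml_round_trip(self, tmp_path, laevo_model):
        import yaml

        data = {"name": "probe", "type": "rigid",
                "loading": {"coeffs": [0.0, 1.0]},
                "unloading": {"coeffs": [0.0, 0.5]},
                "alpha_range_deg": [0.0, 90.0]}
        path = tmp_path / "probe.yaml"
        path.write_text(yaml.safe_dump(data))
        model = xo.load_exo_model(path)
        assert isinstance(model, xo.RigidExoModel)
        assert model.alpha_range == (0.0, 90.0)

    def test_crossing_branches_rejected(self):
        with pytest.raises(ValueError, match="unloading"):
            xo.SoftExoModel(name="bad", loading_coeffs=[0.0, 1.0],
                            unloading_coeffs=[0.0, 2.0],
                            elongation_range=(0.0, 10.0))

    def test_builtin_devices_load(self):
        names = xo.builtin_device_names()
        assert set(names) >= {"laevo_like", "paexo_like", "auxivo_like",
                              "darwing_like"}
        kinds = {n: xo.builtin_device(n).kind for n in names}
        assert kinds["laevo_like"] == "rigid"
        assert kinds["darwing_like"] == "soft"
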