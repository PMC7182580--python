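import numpy as np
import pytest

from octaflow import (
    DopplerVolume,
    PhantomSpec,
    PhaseWrapError,
    ScanMeta,
    VeinSpec,
    make_doppler_phantom,
    phase_to_velocity,
    plane_flow,
    total_retinal_blood_flow,
    vein_flow,
    velocity_to_phase,
)


class TestPhaseVelocity:
    def test_zero_phase_is_zero_velocity(self):
        assert phase_to_velocity(0.0, ScanMeta()) == 0.0

    def test_pi_phase_at_defaults(self):
        # lambda * f / (4 n) = 840e-6 mm * 70 kHz / (4 * 1.38)
        v = phase_to_velocity(np.pi, ScanMeta())
        assert v == pytest.approx(840e-6 * 70000 / (4 * 1.38), rel=1e-12)
        assert v == pytest.approx(10.652, abs=1e-3)

    def test_odd_symmetry(self):
        meta = ScanMeta()
        phases = np.linspace(-np.pi, np.pi, 11)
        assert np.allclose(
            phase_to_velocity(phases, meta), -phase_to_velocity(-phases, meta)
        )

    def test_wrapped_phase_rejected_both_ways(self):
        with pytest.raises(PhaseWrapError):
            phase_to_velocity(3.5, ScanMeta())
        with pytest.raises(PhaseWrapError):
            velocity_to_phase(20.0, ScanMeta())  # above the 10.65 mm/s limit

    def test_roundtrip(self):
        meta = ScanMeta()
        assert velocity_to_phase(phase_to_velocity(1.0, meta), meta) == (
            pytest.approx(1.0)
        )


class TestPlaneFlow:
    def test_uniform_velocity_unit_conversion(self):
        # v = 10 mm/s over 0.01 mm^2 -> 0.1 uL/s -> 6 uL/min
        meta = ScanMeta(field_mm=1.0, n_bscans=10, n_ascans=10)  # 0.01 mm^2/px
        v = np.full((10, 10), 10.0)
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        assert plane_flow(v, mask, meta) == pytest.approx(6.0)

    def test_zero_velocity_zero_flow(self):
        meta = ScanMeta(n_bscans=20, n_ascans=20)
        assert plane_flow(np.zeros((20, 20)), np.ones((20, 20), bool), meta) == 0.0

    def test_empty_mask_warns_and_returns_zero(self):
        meta = ScanMeta(n_bscans=20, n_ascans=20)
        with pytest.warns(UserWarning):
            q = plane_flow(np.ones((20, 20)), np.zeros((20, 20), bool), meta)
        assert q == 0.0

    def test_parabolic_profile_matches_poiseuille_integral(self):
        # fine grid: Q -> v_peak * pi R^2 / 2 = 4.71 uL/min for 20 mm/s, 50 um
        meta = ScanMeta(field_mm=0.4, n_bscans=400, n_ascans=400)
        dy = dx = 0.4 / 400
        y = (np.arange(400) + 0.5) * dy - 0.2
        r2 = y[:, None] ** 2 + y[None, :] ** 2
        radius, v_peak = 0.05, 20.0
        velocity = v_peak * np.clip(1 - r2 / radius**2, 0, None)
        mask = r2 <= radius**2
        expected = v_peak * np.pi * radius**2 / 2 * 60
        assert expected == pytest.approx(4.712, abs=0.01)
        assert plane_flow(velocity, mask, meta) == pytest.approx(expected, rel=0.03)


def _volume_with_plane_flows(flows_by_plane, meta):
    """Uniform-phase volume whose per-plane flow follows the given list."""
    phase = np.zeros((meta.n_bscans, meta.n_ascans, len(flows_by_plane)))
    for z, val in enumerate(flows_by_plane):
        phase[:, :, z] = val
    return DopplerVolume(phase=phase, meta=meta)


class TestVeinFlow:
    def test_max_over_planes(self):
        meta = ScanMeta(n_bscans=20, n_ascans=20)
        vol = _volume_with_plane_flows([0.3, 0.7, 0.5], meta)
        mask = np.ones((20, 20), bool)
        vm = vein_flow(vol, mask)
        assert np.argmax(np.abs(vm.plane_flows)) == 1
        assert vm.max_flow == pytest.approx(np.abs(vm.plane_flows).max())

    def test_equal_planes_equal_max(self):
        meta = ScanMeta(n_bscans=20, n_ascans=20)
        vol = _volume_with_plane_flows([0.4, 0.4, 0.4], meta)
        vm = vein_flow(vol, np.ones((20, 20), bool))
        assert vm.max_flow == pytest.approx(abs(vm.plane_flows[0]))

    def test_phantom_max_at_mid_vessel_plane(self):
        spec = PhantomSpec(n_volumes=1, n_depth=15)
        volumes, masks, _ = make_doppler_phantom(spec)
        vm = vein_flow(volumes[0], masks[0])
        assert np.argmax(np.abs(vm.plane_flows)) == 7


class TestTotalFlow:
    def test_summation_over_veins(self):
        meta = ScanMeta(field_mm=1.0, n_bscans=10, n_ascans=10)
        phase_for_unit_v = velocity_to_phase(1.0, meta)
        phase = np.full((10, 10, 3), phase_for_unit_v)
        vol = DopplerVolume(phase=phase, meta=meta)
        m1 = np.zeros((10, 10), bool)
        m1[0, :5] = True  # 5 px * 0.01 mm^2 * 1 mm/s * 60 = 3 uL/min
        m2 = np.zeros((10, 10), bool)
        m2[1, :] = True  # 10 px -> 6 uL/min
        with pytest.warns(UserWarning):  # fewer than 3 volumes
            eye = total_retinal_blood_flow([vol], [m1, m2])
        assert eye.trbf == pytest.approx(9.0)

    def test_identical_volumes_average_to_single_value(self):
        volumes, masks, _ = make_doppler_phantom(PhantomSpec(n_volumes=3))
        eye = total_retinal_blood_flow(volumes, masks)
        assert eye.trbf == pytest.approx(eye.per_volume_trbf[0])
        assert eye.n_volumes == 3

    def test_no_veins_is_an_error(self):
        volumes, _, _ = make_doppler_phantom(PhantomSpec(n_volumes=3))
        with pytest.raises(ValueError, match="vein"):
            total_retinal_blood_flow(volumes, [])

    def test_flow_linear_in_phase_scaling(self):
        spec = PhantomSpec(n_volumes=1)
        volumes, masks, _ = make_doppler_phantom(spec)
        base = total_retinal_blood_flow(volumes, masks).trbf
        scaled = [
            DopplerVolume(phase=0.5 * v.phase, meta=v.meta) for v in volumes
        ]
        assert total_retinal_blood_flow(scaled, masks).trbf == pytest.approx(
            0.5 * base, rel=1e-12
        )

    def test_invariant_to_splitting_a_vein_mask(self):
        spec = PhantomSpec(
            veins=(VeinSpec(center_mm=(1.0, 1.0), radius_mm=0.1,
                            peak_velocity_mm_s=8.0),),
            n_volumes=1,
        )
        volumes, masks, _ = make_doppler_phantom(spec)
        whole = total_retinal_blood_flow(volumes, masks).trbf
        left = masks[0].copy()
        left[:, 250:] = False
        right = masks[0] & ~left
        split = total_retinal_blood_flow(volumes, [left, right]).trbf
        assert split == pytest.approx(whole, rel=0.01)

    def test_noise_free_phantom_recovery_within_5_percent(self):
        volumes, masks, truth = make_doppler_phantom(PhantomSpec(n_volumes=1))
        eye = total_retinal_blood_flow(volumes, masks)
        assert eye.trbf == pytest.approx(truth, rel=0.05)
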