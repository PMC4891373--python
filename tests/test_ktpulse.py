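"""kT-points trajectories, STA system assembly, MLS design, waveforms."""

import numpy as np
import pytest

from ptxh import bloch, ktpulse
from ptxh.constants import GAMMA_BAR_HZ_PER_T
from ptxh.core import FlipAngleMap, Mask


def _toy_system(gains):
    """STA system with one channel, one kT-point and given real gains (deg/V)."""
    gains = np.asarray(gains, float)
    n = len(gains)
    mask = Mask(np.ones((n, 1, 1), bool), np.eye(4))
    return ktpulse.STASystem(
        A=gains.reshape(-1, 1).astype(complex),
        positions_mm=np.zeros((n, 3)),
        df_hz=np.zeros(n),
        t_centres=np.array([105e-6]),
        T=280e-6,
        mask=mask,
        n_channels=1,
        n_points=1,
        affine=np.eye(4),
        sens_abs=gains.reshape(-1, 1) / 3.22,
    )


class TestTrajectory:
    def test_default_eight_points_totalling_2p24_ms(self, trajectory):
        assert trajectory.n_points == 8
        assert trajectory.duration * 1e3 == pytest.approx(2.24, abs=1e-12)
        assert np.allclose(trajectory.k_points[0], 0.0)
        assert np.allclose(trajectory.k_points[-1], 0.0)
        radii = np.linalg.norm(trajectory.k_points[1:7], axis=1)
        assert np.allclose(radii, 6.33)

    def test_trajectory_closure(self, trajectory):
        assert np.allclose(trajectory.total_blip_area(), 0.0, atol=1e-20)

    def test_single_centre_point_when_no_axis_points(self):
        traj = ktpulse.make_ktpoints_trajectory(n_axis_points=0)
        assert traj.n_points == 1
        assert traj.duration == pytest.approx(280e-6)
        assert np.allclose(traj.total_blip_area(), 0.0)

    def test_blip_area_closed_form(self, trajectory):
        # transition from centre to +kx: |dk| = 6.33 1/m in 70 us
        area = trajectory.blips[0].area
        expected = 6.33 / GAMMA_BAR_HZ_PER_T
        assert area[0] == pytest.approx(expected, rel=1e-9)
        assert abs(expected - 1.487e-7) < 1e-10
        # mean gradient ~2.12 mT/m, well within hardware limits
        assert abs(area[0]) / 70e-6 == pytest.approx(2.124e-3, rel=1e-2)
        assert np.abs(trajectory.blips[0].amplitude).max() < trajectory.g_max

    def test_infeasible_blip_rejected_with_transition_name(self):
        with pytest.raises(ValueError, match="blip"):
            ktpulse.make_ktpoints_trajectory(k_radius=500.0, blip_dur=10e-6)

    def test_blip_samples_integrate_to_analytic_area(self, trajectory):
        for blip in trajectory.blips:
            samples = blip.sample(5e-6)
            assert np.allclose(samples.sum(axis=1) * 5e-6, blip.area, atol=1e-18)


class TestSTASystem:
    def test_uniform_single_channel_closed_form(self, small_mask, small_spec):
        from ptxh import phantom

        spec = small_spec
        b1 = phantom.make_b1_maps(
            phantom.PhantomSpec(
                grid_shape=spec.grid_shape,
                voxel_size_mm=spec.voxel_size_mm,
                n_channels=1,
            ),
            small_mask,
            uniform=True,
        )
        traj = ktpulse.make_ktpoints_trajectory(n_axis_points=0)
        system = ktpulse.build_sta_system(b1, None, traj, small_mask)
        # 1 uT/V for 210 us: 360 * gamma_bar * 1e-6 * 210e-6 = 3.2189 deg/V
        assert np.allclose(np.abs(system.A), 3.2189, atol=2e-4)

    def test_zero_sensitivity_gives_zero_row(self, small_mask):
        from ptxh.core import B1MapSet

        maps = np.ones((1,) + small_mask.data.shape, dtype=complex)
        first_voxel = tuple(np.argwhere(small_mask.data)[0])
        maps[(0,) + first_voxel] = 0.0
        b1 = B1MapSet(maps, small_mask.affine, small_mask)
        traj = ktpulse.make_ktpoints_trajectory(n_axis_points=0)
        system = ktpulse.build_sta_system(b1, None, traj, small_mask)
        assert np.all(system.A[0] == 0.0)
        assert np.any(system.A[1] != 0.0)

    def test_constant_offresonance_changes_only_phase(self, small_mask, small_spec):
        from ptxh import phantom
        from ptxh.core import FieldMap

        b1 = phantom.make_b1_maps(small_spec, small_mask)
        traj = ktpulse.make_ktpoints_trajectory(n_axis_points=0)
        s0 = ktpulse.build_sta_system(b1, None, traj, small_mask)
        df = FieldMap(np.full(small_mask.data.shape, 120.0), small_mask.affine, small_mask)
        s1 = ktpulse.build_sta_system(b1, df, traj, small_mask)
        assert np.allclose(np.abs(s0.A), np.abs(s1.A))
        assert not np.allclose(s0.A, s1.A)


class TestSolveMLS:
    def test_two_voxel_closed_form(self):
        system = _toy_system([1.0, 2.0])
        w = ktpulse.solve_mls(system, 10.0, lambda_global=0.0, seed=0)
        # least squares: b = theta (a1 + a2) / (a1^2 + a2^2) = 6 V
        assert abs(w.weights[0, 0]) == pytest.approx(6.0, rel=1e-6)
        flips = system.flip(w.flat)
        assert np.allclose(flips, [6.0, 12.0], rtol=1e-6)
        assert w.metadata["achieved_nrmse_percent"] == pytest.approx(31.62, abs=0.05)

    def test_global_regularisation_shrinks_solution(self):
        system = _toy_system([1.0, 2.0])
        norms = []
        for lam in [0.0, 1e2, 1e6]:
            w = ktpulse.solve_mls(system, 10.0, lambda_global=lam, seed=0)
            norms.append(np.linalg.norm(w.weights))
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_objective_nonincreasing_on_phantom(self, sta_system):
        w = ktpulse.solve_mls(sta_system, 15.0, seed=0)
        assert w.metadata["achieved_nrmse_percent"] < 12.0

    def test_nan_inputs_rejected(self):
        system = _toy_system([1.0, 2.0])
        system.A[0, 0] = np.nan
        with pytest.raises(ValueError):
            ktpulse.solve_mls(system, 10.0)

    def test_local_sar_regularisation_reduces_max_vop_sar(self, sta_system):
        from ptxh import sarmon

        mats = sarmon.random_psd_matrices(20, sta_system.n_channels, seed=4, scale=1e-5)
        vops = sarmon.VOPSet(mats)
        sars = []
        init = None
        # continuation sweep: each solve warm-starts from the previous lambda
        for lam in [0.0, 1e4, 1e6]:
            w = ktpulse.solve_mls(
                sta_system, 15.0, lambda_local=lam, vops=vops, seed=0,
                max_outer=30, init=init,
            )
            init = w.flat
            rep = sarmon.pulse_sar(w, vops, tr=61e-3, subpulse_dur=210e-6)
            sars.append(rep.max_sar_per_tr)
        assert sars[0] >= sars[1] >= sars[2]

    def test_deterministic_for_fixed_seed(self, sta_system):
        w1 = ktpulse.solve_mls(sta_system, 15.0, seed=3, max_outer=5)
        w2 = ktpulse.solve_mls(sta_system, 15.0, seed=3, max_outer=5)
        assert np.array_equal(w1.weights, w2.weights)


class TestRegionGrowing:
    def test_no_dropout_on_default_phantom(self, sta_system, design_weights):
        flips = sta_system.flip(design_weights.flat)
        assert flips.min() >= 0.5 * 15.0
        assert design_weights.metadata["min_flip_fraction"] >= 0.5

    def test_degenerate_growth_equals_plain_solve(self):
        system = _toy_system([1.0, 2.0])
        plain = ktpulse.solve_mls(system, 10.0, lambda_global=0.0, seed=0)
        grown = ktpulse.region_growing_solve(
            system, 10.0, seed_fraction=1.0, lambda_global=0.0, seed=0
        )
        assert np.allclose(np.abs(plain.weights), np.abs(grown.weights), rtol=1e-6)

    def test_deterministic(self, sta_system, design_weights):
        again = ktpulse.region_growing_solve(sta_system, 15.0, seed=0)
        assert np.array_equal(again.weights, design_weights.weights)


class TestPredictionAndNRMSE:
    def test_zero_weights_zero_map(self, sta_system):
        w = ktpulse.RFWeights(np.zeros((sta_system.n_channels, sta_system.n_points)))
        fa = ktpulse.predict_flip_angle(sta_system, w)
        assert np.all(fa.values == 0.0)

    def test_linearity_in_weights(self, sta_system, design_weights):
        fa1 = ktpulse.predict_flip_angle(sta_system, design_weights)
        fa2 = ktpulse.predict_flip_angle(
            sta_system, ktpulse.RFWeights(2.0 * design_weights.weights)
        )
        sel = sta_system.mask.data
        assert np.allclose(fa2.values[sel], 2.0 * fa1.values[sel], rtol=1e-12)

    @pytest.mark.parametrize(
        "scale, expected",
        [(1.0, 0.0), (1.1, 10.0)],
    )
    def test_nrmse_trivial_cases(self, scale, expected, head_mask):
        vals = np.where(head_mask.data, scale * 15.0, 0.0)
        fa = FlipAngleMap(vals, head_mask.affine, mask=head_mask)
        assert ktpulse.nrmse(fa, 15.0, head_mask) == pytest.approx(expected, abs=1e-9)

    def test_nrmse_two_voxel_case(self):
        system = _toy_system([1.0, 2.0])
        w = ktpulse.solve_mls(system, 10.0, lambda_global=0.0, seed=0)
        fa = ktpulse.predict_flip_angle(system, w)
        assert ktpulse.nrmse(fa, 10.0, system.mask) == pytest.approx(31.62, abs=0.05)


class TestAssembleWaveforms:
    def test_default_duration_at_any_raster(self, trajectory, design_weights):
        for dt in (5e-6, 10e-6):
            wave = ktpulse.assemble_waveforms(design_weights, trajectory, dt)
            assert wave.duration * 1e3 == pytest.approx(2.24, abs=1e-12)

    def test_zero_weights_zero_rf_but_gradients_play(self, trajectory):
        w = ktpulse.RFWeights(np.zeros((4, trajectory.n_points)))
        wave = ktpulse.assemble_waveforms(w, trajectory)
        assert np.all(wave.rf == 0.0)
        assert np.abs(wave.gradients).max() > 0.0

    def test_rf_zero_during_blips_gradients_zero_during_subpulses(
        self, trajectory, design_weights
    ):
        wave = ktpulse.assemble_waveforms(design_weights, trajectory, 5e-6)
        ns, nb = 42, 14
        for j in range(trajectory.n_points):
            s = j * (ns + nb)
            assert np.all(wave.gradients[:, s : s + ns] == 0.0)
            assert np.all(wave.rf[:, s + ns : s + ns + nb] == 0.0)

    def test_peak_voltage_violation_names_channel_and_subpulse(self, trajectory):
        w = ktpulse.RFWeights(np.zeros((4, trajectory.n_points)))
        w.weights[2, 5] = 500.0
        with pytest.raises(ValueError, match="channel 2, sub-pulse 5"):
            ktpulse.assemble_waveforms(w, trajectory)

    def test_incommensurate_raster_rejected(self, trajectory, design_weights):
        with pytest.raises(ValueError, match="raster"):
            ktpulse.assemble_waveforms(design_weights, trajectory, 4e-6)

    def test_bloch_oracle_at_small_tip(self, sta_system, design_weights, trajectory, b1_true, b0_true):
        """Assembled waveform reproduces A b in the small-tip regime."""
        small = ktpulse.RFWeights(design_weights.weights / 15.0)  # ~1 degree
        wave = ktpulse.assemble_waveforms(small, trajectory, 5e-6)
        mag = bloch.bloch_simulate(wave, b1_true, b0_true, sta_system.mask)
        sta = sta_system.flip(small.flat)
        rel = np.abs(mag.flip_deg - sta) / np.maximum(sta, 1e-12)
        assert rel.max() <= 0.01


def test_export_pulse_writes_all_artifacts(tmp_path, trajectory, design_weights):
    ktpulse.export_pulse(design_weights, trajectory, tmp_path)
    assert (tmp_path / "pulse.h5").exists()
    assert (tmp_path / "pulse.txt").exists()
    assert (tmp_path / "design.json").exists()
    wave = bloch.Waveform.load_hdf5(tmp_path / "pulse.h5")
    assert wave.duration * 1e3 == pytest.approx(2.24, abs=1e-12)
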