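"""Alignment, adaptive force scaling, dynamics, and minimization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from densfit import (
    FitConfig,
    adaptive_force_update,
    build_topology,
    energy_minimize,
    model_to_map,
    cross_correlation,
    rigid_body_align,
    run_fit,
    stereo_score,
)
from densfit.fitting_engine import restraint_energy_forces, write_trajectory_pdb
from conftest import random_model


class TestAdaptiveForceUpdate:
    def test_flat_similarity_grows_by_e(self):
        cfg = FitConfig(seed=0, tau=4.0, feedback_interval=4.0)
        assert adaptive_force_update(10.0, 0.5, 0.5, cfg) == pytest.approx(
            10.0 * np.e, rel=1e-12)

    def test_improvement_shrinks_monotonically(self):
        cfg = FitConfig(seed=0)
        k = 10.0
        prev = 0.1
        for i in range(200):
            now = prev + 0.01
            k_new = adaptive_force_update(k, now, prev, cfg)
            assert 0 < k_new < k
            k, prev = k_new, now

    @pytest.mark.parametrize("n", [1, 5, 23])
    def test_stalled_updates_match_closed_form(self, n):
        cfg = FitConfig(seed=0, tau=4.0, feedback_interval=2.0, k_cap=1e12)
        k = cfg.k_start
        for _ in range(n):
            k = adaptive_force_update(k, 0.4, 0.4, cfg)
        assert k == pytest.approx(
            cfg.k_start * np.exp(n * cfg.feedback_interval / cfg.tau),
            rel=1e-12)

    def test_cap_clamps(self):
        cfg = FitConfig(seed=0, k_cap=20.0)
        assert adaptive_force_update(15.0, 0.3, 0.3, cfg) == 20.0


class TestRestraintForces:
    def test_forces_are_minus_gradient(self, barrel_model, barrel_topo):
        rng = np.random.default_rng(0)
        x = barrel_model.coords + 0.15 * rng.standard_normal(
            barrel_model.coords.shape)
        _, f = restraint_energy_forces(x, barrel_topo,
                                       is_heavy=barrel_model.is_heavy)
        h = 1e-6
        for i, a in [(0, 0), (7, 1), (20, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[i, a] += h
            xm[i, a] -= h
            ep, _ = restraint_energy_forces(xp, barrel_topo,
                                            is_heavy=barrel_model.is_heavy)
            em, _ = restraint_energy_forces(xm, barrel_topo,
                                            is_heavy=barrel_model.is_heavy)
            assert f[i, a] == pytest.approx(-(ep - em) / (2 * h), rel=1e-4,
                                            abs=1e-6)

    def test_zero_at_reference_geometry(self, barrel_model, barrel_topo):
        e, f = restraint_energy_forces(barrel_model.coords, barrel_topo,
                                       is_heavy=barrel_model.is_heavy)
        assert e == pytest.approx(0.0, abs=1e-9)
        assert np.abs(f).max() < 1e-6


class TestRigidBodyAlign:
    def test_already_optimal_is_fixed_point(self, barrel_model, barrel_target,
                                             spread_params):
        cc_in = cross_correlation(
            model_to_map(barrel_model, barrel_target, spread_params),
            barrel_target)
        R, t, aligned = rigid_body_align(barrel_model, barrel_target,
                                         spread_params, coarse=False)
        angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        assert angle < 0.5
        assert np.linalg.norm(t) < 0.1
        cc_out = cross_correlation(
            model_to_map(aligned, barrel_target, spread_params), barrel_target)
        assert cc_out >= cc_in - 1e-6

    def test_translation_recovery(self, barrel_model, barrel_target,
                                  spread_params):
        shift = np.array([3.0, -2.0, 1.0])
        moved = barrel_model.with_coords(barrel_model.coords + shift)
        _, _, aligned = rigid_body_align(moved, barrel_target, spread_params,
                                         coarse=False)
        residual = np.abs(aligned.coords - barrel_model.coords).max(axis=0)
        assert np.all(residual < 0.5 * barrel_target.voxel_size)

    def test_rotation_recovery(self):
        # an asymmetric fixture: the barrel's near 6-fold symmetry would make
        # symmetry-equivalent alignments equally correct
        from densfit import FixtureSpec, make_target_maps, make_toy_coil, normalize_map
        from densfit.forward_model import SpreadParams
        spec = FixtureSpec(kind="coil", n_strands=4, strand_length=6,
                           radius=4.5, box=32, pixel_size=0.84, noise_sd=0.0,
                           seed=6)
        coil, _ = make_toy_coil(spec)
        target = normalize_map(make_target_maps(coil, spec)[0])
        params = SpreadParams.for_pixel_size(spec.pixel_size)
        rot = Rotation.from_euler("z", 30, degrees=True)
        com = coil.center_of_mass()
        moved = coil.with_coords(
            (coil.coords - com) @ rot.as_matrix().T + com)
        R, _, aligned = rigid_body_align(moved, target, params,
                                         n_orientations=200, seed=4)
        # net rotation after alignment should undo the 30 degrees
        residual = Rotation.from_matrix(R) * rot
        assert np.degrees(residual.magnitude()) < 2.0


class TestRunFit:
    def test_self_target_stays_put(self, barrel, barrel_target, spread_params):
        model, topo = barrel
        cfg = FitConfig(seed=5, max_time=8.0, timestep=0.004,
                        temperature=0.0, k_cap=1e4)
        traj = run_fit(model, topo, barrel_target, cfg, params=spread_params)
        assert traj.frames[0].similarity > 0.999
        assert traj.frames[-1].similarity >= traj.frames[0].similarity - 1e-9
        drift = np.sqrt(np.mean(np.sum(
            (traj.frames[-1].coords - model.coords) ** 2, axis=1)))
        assert drift < 0.5

    def test_seeded_determinism(self, barrel, barrel_target, spread_params):
        model, topo = barrel
        cfg = FitConfig(seed=9, max_time=4.0, timestep=0.004)
        t1 = run_fit(model, topo, barrel_target, cfg, params=spread_params)
        t2 = run_fit(model, topo, barrel_target, cfg, params=spread_params)
        assert t1.n_frames == t2.n_frames
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.coords, f2.coords)
            assert f1.k == f2.k

    def test_k_series_piecewise_exponential(self, barrel, barrel_target,
                                            spread_params):
        model, topo = barrel
        cfg = FitConfig(seed=3, max_time=8.0, timestep=0.004,
                        feedback_interval=2.0, eval_stride=2.0, tau=4.0)
        traj = run_fit(model, topo, barrel_target, cfg, params=spread_params)
        ks = np.array([f.k for f in traj.frames])
        # log k changes by multiples of dt_fb / tau between recorded frames
        steps = np.diff(np.log(ks)) / (cfg.feedback_interval / cfg.tau)
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_frozen_k_zero_is_pure_relaxation(self, barrel, barrel_target,
                                              spread_params):
        model, topo = barrel
        start = model.with_coords(
            model.coords + 0.3 * np.random.default_rng(1).standard_normal(
                model.coords.shape))
        cfg = FitConfig(seed=2, max_time=20.0, timestep=0.004, temperature=0.0)
        traj = run_fit(start, topo, barrel_target, cfg, params=spread_params,
                       k_frozen=0.0)
        q0 = stereo_score(model, topo, coords=start.coords).total
        q1 = stereo_score(model, topo, coords=traj.frames[-1].coords).total
        assert q1 < 0.1 * q0  # relaxed toward the reference geometry

    def test_trajectory_export(self, tmp_path, barrel, barrel_target,
                               spread_params):
        model, topo = barrel
        cfg = FitConfig(seed=1, max_time=4.0, timestep=0.004)
        traj = run_fit(model, topo, barrel_target, cfg, params=spread_params)
        tsv = tmp_path / "traj.tsv"
        traj.to_tsv(tsv)
        table = np.loadtxt(tsv, skiprows=1)
        assert table.shape == (traj.n_frames, 5)
        pdb = tmp_path / "traj.pdb"
        write_trajectory_pdb(traj, model, pdb)
        assert pdb.read_text().count("MODEL") >= traj.n_frames


class TestEnergyMinimize:
    def test_single_bond_converges_to_b0(self):
        model = random_model(2, 0).with_coords(
            np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        topo = build_topology(model, bond_cutoff=1.8)
        stretched = model.with_coords(np.array([[0.0, 0, 0], [1.6, 0, 0]]))
        out = energy_minimize(stretched, topo, force_tol=1e-6)
        d = np.linalg.norm(out.coords[1] - out.coords[0])
        assert d == pytest.approx(1.5, abs=1e-4)

    def test_restrained_displacement_energy_bound(self, barrel, barrel_spec):
        model, topo = barrel
        rng = np.random.default_rng(8)
        start = model.with_coords(model.coords + 0.2 * rng.standard_normal(
            model.coords.shape))
        e_strain, _ = restraint_energy_forces(start.coords, topo,
                                              is_heavy=model.is_heavy)
        k_pos = 1000.0
        out = energy_minimize(start, topo, restrain_heavy=True, k_pos=k_pos)
        max_disp = np.linalg.norm(out.coords - start.coords, axis=1).max()
        assert max_disp <= np.sqrt(2 * e_strain / k_pos) + 1e-9

    def test_quality_never_worse_on_clash_free_fixture(self, barrel):
        model, topo = barrel
        rng = np.random.default_rng(15)
        start = model.with_coords(model.coords + 0.15 * rng.standard_normal(
            model.coords.shape))
        q0 = stereo_score(model, topo, coords=start.coords).total
        out = energy_minimize(start, topo)
        q1 = stereo_score(model, topo, coords=out.coords).total
        assert q1 <= q0 + 1e-9
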