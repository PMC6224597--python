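"""Vertex-model tests: mesh construction, energy, forces, equilibria."""

import dataclasses

import numpy as np
import pytest

from corset.exceptions import ParameterError, TopologyError
from corset.vertex import (
    EnergyParams,
    ModulationSpec,
    build_tube,
    calibrate_alpha_wt,
    relax,
    relax_modulated,
    tissue_energy,
)
from corset.vertex.energy import energy_and_grad

from oracles import brute_force_energy


class TestMeshConstruction:
    def test_unit_volumes_at_construction(self, wt_mesh):
        v = wt_mesh.cell_volumes()
        assert np.all(np.abs(v - 1.0) < 1e-9)

    def test_cell_count_12x16(self):
        mesh = build_tube(n_circ=12, n_axial=16)
        assert mesh.n_cells == 192
        assert np.all(np.abs(mesh.cell_volumes() - 1.0) < 1e-9)

    def test_every_apical_vertex_shared_by_three_cells(self, wt_mesh):
        assert np.all(wt_mesh.apical_vertex_count() == 3)

    def test_odd_n_circ_rejected(self):
        with pytest.raises(TopologyError):
            build_tube(n_circ=9)

    def test_extreme_target_ratio_rejected(self):
        with pytest.raises(ParameterError):
            build_tube(target_ratio=0.97)

    def test_apical_starts_at_target_radius(self):
        mesh = build_tube(target_ratio=0.41)
        ap = mesh.verts[mesh.free]
        assert np.allclose(np.hypot(ap[:, 0], ap[:, 1]), 0.41, atol=1e-12)


class TestEnergy:
    def test_alpha_zero_at_construction_is_pure_lateral_area(self, wt_mesh):
        p = EnergyParams(alpha=0.0, psi=0.38)
        w, _, info = energy_and_grad(wt_mesh.verts, wt_mesh, p, want_grad=False)
        assert w == pytest.approx(info["lateral_area"], abs=1e-10)

    def test_matches_brute_force_oracle(self, wt_mesh):
        # both at construction and at a deformed configuration
        p = EnergyParams(alpha=0.242, psi=0.38)
        assert tissue_energy(wt_mesh, p) == pytest.approx(
            brute_force_energy(wt_mesh, 0.242, 0.38), abs=1e-12 * 100)
        rng = np.random.default_rng(3)
        verts = wt_mesh.verts.copy()
        verts[wt_mesh.free] += rng.uniform(-0.02, 0.02, (wt_mesh.free.sum(), 3))
        deformed = wt_mesh.with_verts(verts)
        assert tissue_energy(deformed, p) == pytest.approx(
            brute_force_energy(deformed, 0.242, 0.38), rel=1e-12)

    def test_doubling_alpha_doubles_apical_term(self, wt_mesh):
        w0 = tissue_energy(wt_mesh, EnergyParams(alpha=0.0, psi=0.38))
        w1 = tissue_energy(wt_mesh, EnergyParams(alpha=0.1, psi=0.38))
        w2 = tissue_energy(wt_mesh, EnergyParams(alpha=0.2, psi=0.38))
        assert (w2 - w0) == pytest.approx(2.0 * (w1 - w0), rel=1e-12)

    def test_volume_term_vanishes_iff_unit_volumes(self, wt_mesh):
        # at construction all v = 1, so energies at different psi coincide
        w_a = tissue_energy(wt_mesh, EnergyParams(alpha=0.1, psi=0.38))
        w_b = tissue_energy(wt_mesh, EnergyParams(alpha=0.1, psi=5.0))
        assert w_a == pytest.approx(w_b, abs=1e-12)
        # squeeze the apical surface -> v != 1 -> psi matters
        verts = wt_mesh.verts.copy()
        verts[wt_mesh.free, :2] *= 0.9
        squeezed = wt_mesh.with_verts(verts)
        assert abs(tissue_energy(squeezed, EnergyParams(alpha=0.1, psi=5.0))
                   - tissue_energy(squeezed, EnergyParams(alpha=0.1, psi=0.38))) > 1e-6

    def test_rigid_symmetries(self, wt_mesh):
        p = EnergyParams(alpha=0.242, psi=0.38)
        w0 = tissue_energy(wt_mesh, p)
        pitch = wt_mesh.period / wt_mesh.n_axial
        assert abs(tissue_energy(wt_mesh.translated(pitch), p) - w0) < 1e-10
        assert abs(tissue_energy(
            wt_mesh.rotated(2 * np.pi / wt_mesh.n_circ), p) - w0) < 1e-10

    def test_analytic_gradient_matches_finite_differences(self, wt_mesh):
        p = EnergyParams(alpha=0.242, psi=0.38)
        # check at a non-symmetric configuration so no terms vanish
        rng = np.random.default_rng(7)
        verts = wt_mesh.verts.copy()
        verts[wt_mesh.free] += rng.uniform(-0.01, 0.01, (wt_mesh.free.sum(), 3))
        _, g, _ = energy_and_grad(verts, wt_mesh, p)
        idx = rng.choice(np.nonzero(wt_mesh.free)[0], 20, replace=False)
        h = 1e-6
        for vi in idx:
            for d in range(3):
                vv = verts.copy()
                vv[vi, d] += h
                wp, _, _ = energy_and_grad(vv, wt_mesh, p, want_grad=False)
                vv[vi, d] -= 2 * h
                wm, _, _ = energy_and_grad(vv, wt_mesh, p, want_grad=False)
                fd = (wp - wm) / (2 * h)
                assert g[vi, d] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestRelaxation:
    def test_wild_type_equilibrium_ratio(self, wt_mesh, alpha_wt):
        res = relax(wt_mesh, EnergyParams(alpha=alpha_wt, psi=0.38))
        assert res.converged
        assert res.max_force < 1e-6
        assert res.morphology.ratio == pytest.approx(0.56, abs=0.01)
        # height consistency: h ~ (d_g - d_r)/2 within discretization error
        m = res.morphology
        assert m.mean_height == pytest.approx((m.d_g - m.d_r) / 2, rel=0.08)

    def test_energy_trace_non_increasing(self, small_mesh):
        res = relax(small_mesh, EnergyParams(alpha=0.23, psi=0.38))
        assert res.converged
        assert np.all(np.diff(res.energy_trace) <= 1e-10)

    def test_equilibrium_robust_to_initial_jitter(self, alpha_wt):
        p = EnergyParams(alpha=alpha_wt, psi=0.38)
        ratios = []
        for seed in (1, 2):
            mesh = build_tube(n_circ=10, n_axial=6, seed=seed, jitter=0.01)
            res = relax(mesh, p)
            assert res.converged
            ratios.append(res.morphology.ratio)
        assert abs(ratios[0] - ratios[1]) < 1e-3

    def test_overcontraction_hits_guard_and_is_flagged(self, small_mesh):
        res = relax(small_mesh, EnergyParams(alpha=2.0, psi=0.38))
        assert not res.converged
        assert res.flags

    def test_free_basal_destroys_tubular_equilibrium(self, small_mesh):
        free_all = dataclasses.replace(
            small_mesh, free=np.ones(small_mesh.n_verts, dtype=bool))
        res = relax(free_all, EnergyParams(alpha=0.23, psi=0.38),
                    max_iters=3000)
        basal = res.mesh.verts[:small_mesh.n_verts // 2]
        r_basal = np.hypot(basal[:, 0], basal[:, 1])
        tubular = (res.converged
                   and np.all(np.abs(r_basal - 1.0) < 0.05)
                   and 0.1 < res.morphology.ratio < 0.95)
        assert not tubular


class TestCalibration:
    def test_round_trip_recovers_known_alpha(self, small_mesh):
        res = relax(small_mesh, EnergyParams(alpha=0.22, psi=0.38))
        assert res.converged
        target = res.morphology.ratio
        back = calibrate_alpha_wt(psi=0.38, target_ratio=target,
                                  mesh=small_mesh, bracket=(0.05, 0.5))
        assert back == pytest.approx(0.22, abs=1e-3)

    def test_ratio_monotone_decreasing_in_alpha(self, wt_mesh, alpha_wt):
        ratios = []
        mesh = wt_mesh
        for f in np.linspace(0.5, 1.1, 8):
            res = relax(mesh, EnergyParams(alpha=f * alpha_wt, psi=0.38))
            assert res.converged
            mesh = res.mesh
            ratios.append(res.morphology.ratio)
        assert np.all(np.diff(ratios) < 0)

    def test_unbracketable_target_raises(self, small_mesh):
        from corset.exceptions import CalibrationError
        with pytest.raises(CalibrationError):
            calibrate_alpha_wt(psi=0.38, target_ratio=0.95,
                               mesh=small_mesh, bracket=(0.2, 0.4))


class TestModulation:
    def test_zero_amplitude_gives_uniform_tube(self, small_mesh, alpha_wt):
        mod = ModulationSpec(base=alpha_wt, amplitude=0.0,
                             wavelength=small_mesh.period)
        res, amp = relax_modulated(small_mesh,
                                   EnergyParams(alpha=alpha_wt, psi=0.38), mod)
        assert res.converged
        assert amp < 0.01

    def test_modulation_produces_pearling(self, wt_mesh, alpha_wt):
        p = EnergyParams(alpha=alpha_wt, psi=0.38)
        uniform = relax(wt_mesh, p).morphology.pearling_amplitude
        mod = ModulationSpec(base=alpha_wt, amplitude=0.25 * alpha_wt,
                             wavelength=wt_mesh.period)
        res, amp = relax_modulated(wt_mesh, p, mod)
        assert res.converged
        assert amp >= 5 * max(uniform, 1e-3)

    def test_phase_shift_moves_constriction_by_half_period(self, wt_mesh, alpha_wt):
        p = EnergyParams(alpha=alpha_wt, psi=0.38)
        pitch = wt_mesh.period / wt_mesh.n_axial
        zmins = []
        for phase in (0.0, np.pi):
            mod = ModulationSpec(base=alpha_wt, amplitude=0.25 * alpha_wt,
                                 wavelength=wt_mesh.period, phase=phase)
            res, _ = relax_modulated(wt_mesh, p, mod)
            m = res.morphology
            zmins.append(m.z_profile[np.argmin(m.r_profile)])
        shift = abs(zmins[1] - zmins[0]) % wt_mesh.period
        expected = wt_mesh.period / 2
        assert min(shift, wt_mesh.period - shift) == pytest.approx(
            expected, abs=1.5 * pitch)

    def test_amplitude_exceeding_base_rejected(self):
        with pytest.raises(ParameterError):
            ModulationSpec(base=0.1, amplitude=0.2, wavelength=1.0)
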