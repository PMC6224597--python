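"""Generator tests: determinism, closed-form checks, noise scaling."""

import numpy as np
import pytest

from corset.exceptions import ParameterError
from corset.synth import (
    gen_correlated_profiles,
    gen_frap_series,
    gen_recoil_trace,
    gen_speckle_movie,
    gen_tube_stack,
)

from oracles import frap_recovery, single_exponential


class TestDeterminism:
    @pytest.mark.parametrize("make", [
        lambda s: gen_frap_series(P=0.7, k=0.02, noise_sd=0.03, seed=s)[0].i_frap,
        lambda s: gen_recoil_trace(v0=1.0, noise_sd=0.05, seed=s)[0].L,
        lambda s: gen_speckle_movie(n_frames=4, seed=s)[0].frames,
        lambda s: gen_correlated_profiles(0.5, 100, seed=s)[0],
        lambda s: gen_tube_stack(n_axial=2, noise_sd=0.02, seed=s)[0].data,
    ], ids=["frap", "recoil", "speckle", "profiles", "tube"])
    def test_same_seed_bit_identical(self, make):
        assert np.array_equal(make(42), make(42))
        assert not np.array_equal(make(42), make(43))


class TestFrapGenerator:
    def test_ideal_half_recovery_time(self):
        # P=1, k=ln2: the clean normalized curve reaches 0.5 at t = 1 s
        rec, _ = gen_frap_series(P=1.0, k=np.log(2.0), bleach_depth=1.0,
                                 acq_decay=0.0, background=0.0, noise_sd=0.0,
                                 n_pre=3, n_post=12, dt=1.0)
        post = rec.i_frap[rec.n_pre:]
        assert post[1] == pytest.approx(0.5, abs=1e-12)  # t = 1 s after bleach
        t = np.arange(post.size) * 1.0
        assert np.allclose(post, frap_recovery(t, 1.0, np.log(2.0)), atol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            gen_frap_series(P=0.5, k=-1.0)
        with pytest.raises(ParameterError):
            gen_frap_series(P=0.5, k=0.1, dt=0.0)
        with pytest.raises(ParameterError):
            gen_frap_series(P=1.5, k=0.1)


class TestRecoilGenerator:
    def test_zero_velocity_is_flat(self):
        trace, _ = gen_recoil_trace(v0=0.0, pre_slope=0.0, noise_sd=0.0)
        assert np.allclose(trace.L, trace.L[0], atol=1e-12)

    def test_analytic_derivative_at_cut(self):
        trace, truth = gen_recoil_trace(v0=1.12, tau1=1.0, tau2=8.0,
                                        frac1=0.7, noise_sd=0.0, dt=1e-4,
                                        duration=6.0, t_cut=5.0)
        i = np.searchsorted(trace.t, 5.0)
        v_num = (trace.L[i + 1] - trace.L[i]) / 1e-4
        assert v_num == pytest.approx(1.12, rel=1e-3)

    def test_frac1_one_is_single_exponential(self):
        trace, truth = gen_recoil_trace(v0=0.8, tau1=2.0, tau2=9.0,
                                        frac1=1.0, noise_sd=0.0)
        post = trace.t > 5.0
        expected = single_exponential(trace.t[post], truth.params["Linf"],
                                      truth.params["A1"], 2.0, 5.0)
        assert np.allclose(trace.L[post], expected, atol=1e-12)

    def test_continuity_at_cut(self):
        trace, _ = gen_recoil_trace(v0=1.5, pre_slope=0.02, noise_sd=0.0,
                                    dt=1e-3, duration=6.0)
        i = np.searchsorted(trace.t, 5.0)
        assert abs(trace.L[i + 1] - trace.L[i]) < 0.01

    def test_tau_order_enforced(self):
        with pytest.raises(ParameterError):
            gen_recoil_trace(v0=1.0, tau1=5.0, tau2=1.0)


class TestSpeckleGenerator:
    def test_static_movie_frames_identical_up_to_noise(self):
        seq, _ = gen_speckle_movie(flow=(0, 0), drift=(0, 0), n_frames=3,
                                   noise_sd=0.0, seed=0)
        assert np.allclose(seq.frames[0], seq.frames[1], atol=1e-12)

    def test_particle_displacement_matches_flow_plus_drift(self):
        # track one isolated bright particle's centroid across two frames
        seq, truth = gen_speckle_movie(nx=96, ny=96, n_frames=2, density=0.0005,
                                       flow=(4.71, 0.0), drift=(1.0, 0.0),
                                       noise_sd=0.0, psf_sigma=1.5, seed=5)
        expected_dx = truth.params["flow_px_per_frame"][0]
        roi = seq.roi
        sub0 = seq.frames[0][roi]
        sub1 = seq.frames[1][roi]
        iy, ix = np.unravel_index(np.argmax(sub0), sub0.shape)
        xs = np.arange(-6, 7)

        def centroid(img):
            w = img[iy - 6:iy + 7, ix - 6:ix + 7]
            return float((w * xs[None, :]).sum() / w.sum())

        dx = centroid(sub1) - centroid(sub0)
        assert dx == pytest.approx(expected_dx, abs=0.15)

    def test_underseeding_recorded(self):
        _, truth = gen_speckle_movie(density=0.001, n_frames=2, seed=1)
        assert truth.warnings


class TestTubeGenerator:
    def test_midplane_corset_radius(self):
        stack, truth, _ = gen_tube_stack(noise_sd=0.0, psf_sigma=0.0,
                                         n_axial=4, seed=0)
        sl = stack.channel("corset")[truth.mid_slice]
        ny = sl.shape[0]
        cy = (ny - 1) / 2
        col = sl[:, 2]  # a column away from any bridge center
        bright = np.nonzero(col > 0.2)[0]
        r_px = np.abs(bright - cy)
        expected = (truth.d_r / 2) / truth.voxel
        assert np.all(np.abs(r_px - expected) <= 1.0 + 1.5)

    def test_hole_count_on_unrolled_surface(self):
        from scipy.ndimage import label

        from corset.synth.tube import corset_surface_mask
        _, truth, _ = gen_tube_stack(noise_sd=0.0, psf_sigma=0.0,
                                     n_axial=6, seed=0)
        mask = corset_surface_mask(truth)
        lab, n = label(~mask)
        # the circumference is periodic: merge components split by the seam
        parent = list(range(n + 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in zip(lab[0], lab[-1]):
            if a and b:
                parent[find(a)] = find(b)
        n_holes = len({find(i) for i in range(1, n + 1)})
        assert n_holes == truth.n_circ * truth.n_axial

    def test_top_projection_shows_en_face_bridges(self):
        from scipy.ndimage import binary_fill_holes, label
        stack, truth, _ = gen_tube_stack(noise_sd=0.0, psf_sigma=0.0,
                                         n_axial=6, seed=0)
        proj = stack.channel("corset")[truth.top_slices].max(axis=0)
        mask = proj > 0.2
        interior = binary_fill_holes(mask) & ~mask
        _, n = label(interior)
        # offset rings: every second axial column has a cell centered at the
        # top of the tube, whose opening projects en face
        assert n == truth.n_axial // 2

    def test_geometric_impossibility_rejected(self):
        with pytest.raises(ParameterError):
            gen_tube_stack(bridge_radii=5.0)
        with pytest.raises(ParameterError):
            gen_tube_stack(heights=13.0, d_g=25.0)

    def test_truth_ratio_definition(self):
        _, truth, _ = gen_tube_stack(heights=5.5, d_g=25.0, n_axial=2)
        assert truth.d_r == pytest.approx(25.0 - 11.0)


class TestProfilesGenerator:
    def test_rho_one_gives_exact_unit_correlation(self):
        p1, p2, _ = gen_correlated_profiles(1.0, 500, seed=0)
        assert np.corrcoef(p1, p2)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_large_sample(self):
        p1, p2, _ = gen_correlated_profiles(0.0, 100_000, seed=1)
        assert abs(np.corrcoef(p1, p2)[0, 1]) < 0.01

    def test_rho_059(self):
        p1, p2, _ = gen_correlated_profiles(0.59, 10_000, seed=2)
        assert np.corrcoef(p1, p2)[0, 1] == pytest.approx(0.59, abs=0.02)

    def test_invalid_rho(self):
        with pytest.raises(ParameterError):
            gen_correlated_profiles(1.2, 100)


class TestNoiseScaling:
    def test_doubling_noise_doubles_residual_sd(self):
        base = dict(n_axial=4, psf_sigma=0.0, seed=None)
        ideal, _, _ = gen_tube_stack(noise_sd=0.0, **base)
        sds = []
        for ns in (0.02, 0.04):
            resid = []
            for seed in (10, 11):
                s, _, _ = gen_tube_stack(noise_sd=ns, n_axial=4,
                                         psf_sigma=0.0, seed=seed)
                resid.append((s.data - ideal.data).ravel())
            sds.append(np.concatenate(resid).std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.05)
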