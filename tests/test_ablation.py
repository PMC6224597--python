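"""Ablation tests: recoil fitting, displacement, segmentation, tracking."""

import numpy as np
import pytest
from scipy.ndimage import rotate, shift

from corset.ablation import (
    DisplacementTrace,
    fit_recoil,
    mask_circularity,
    segment_bridges,
    total_displacement,
    track_circularity,
)
from corset.exceptions import DataError
from corset.synth import gen_recoil_trace

from oracles import ramanujan_perimeter


class TestRecoilFit:
    def test_noiseless_control_velocity(self):
        trace, _ = gen_recoil_trace(v0=1.12, tau1=1.0, tau2=8.0, frac1=0.7,
                                    noise_sd=0.0, dt=1.0)
        fit = fit_recoil(trace, model="double")
        assert fit.v_recoil == pytest.approx(1.12, abs=0.01)
        assert fit.t0 == pytest.approx(5.0, abs=1e-6)

    def test_zero_velocity_selects_single(self):
        trace, _ = gen_recoil_trace(v0=0.0, noise_sd=0.0)
        fit = fit_recoil(trace, model="auto")
        assert fit.model == "single"
        assert abs(fit.v_recoil) < 0.01

    def test_effective_cut_time_with_noise(self):
        errs = []
        for seed in range(20):
            trace, _ = gen_recoil_trace(v0=1.12, noise_sd=0.05, dt=1.0,
                                        seed=seed)
            fit = fit_recoil(trace, model="double")
            errs.append(abs(fit.t0 - 5.0))
        assert np.median(errs) <= 1.0  # within one frame interval

    def test_noiseless_sweep_within_one_percent(self, rng):
        for _ in range(100):
            v0 = rng.uniform(0.2, 2.0)
            tau1 = rng.uniform(0.5, 3.0)
            tau2 = tau1 * rng.uniform(1.5, 6.0)
            trace, _ = gen_recoil_trace(v0=v0, tau1=tau1, tau2=tau2,
                                        frac1=rng.uniform(0.3, 0.9),
                                        noise_sd=0.0)
            fit = fit_recoil(trace, model="double")
            assert abs(fit.v_recoil - v0) / v0 < 0.01

    def test_noisy_median_error_below_10pct(self):
        errs = []
        for seed in range(60):
            trace, _ = gen_recoil_trace(v0=1.12, noise_sd=0.05, seed=seed)
            fit = fit_recoil(trace, model="double")
            errs.append(abs(fit.v_recoil - 1.12) / 1.12)
        assert np.median(errs) < 0.10

    def test_control_to_depleted_ratio(self):
        fc = fit_recoil(gen_recoil_trace(v0=1.12, noise_sd=0.0)[0], "double")
        fn = fit_recoil(gen_recoil_trace(v0=0.47, noise_sd=0.0)[0], "double")
        assert fc.v_recoil / fn.v_recoil == pytest.approx(2.3, abs=0.15)


class TestTotalDisplacement:
    def test_flat_trace_zero(self):
        trace, _ = gen_recoil_trace(v0=0.0, noise_sd=0.0, duration=60.0)
        assert total_displacement(trace) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generated_plateau_rise(self):
        trace, truth = gen_recoil_trace(v0=1.0, tau1=1.0, tau2=5.0,
                                        frac1=0.7, noise_sd=0.0, duration=80.0)
        assert total_displacement(trace, horizon=50.0) == pytest.approx(
            truth.params["total_rise"], abs=0.01)

    def test_horizon_beyond_trace_raises(self):
        trace, _ = gen_recoil_trace(v0=1.0, duration=30.0)
        with pytest.raises(DataError, match="horizon"):
            total_displacement(trace, horizon=50.0)


def _ring_frame(centers_radii, shape=(220, 220), width=3, value=1.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx, r in centers_radii:
        d = np.hypot(yy - cy, xx - cx)
        img[(d >= r) & (d < r + width)] = value
    return img


class TestSegmentation:
    def test_known_rings_recovered(self):
        rings = [(50, 50, 10), (50, 160, 14), (160, 50, 12),
                 (160, 160, 9), (110, 110, 11), (30, 110, 13)]
        img = _ring_frame(rings)
        seg = segment_bridges([img], min_area=50)
        lab = seg.labels[0]
        assert lab.max() == 6
        areas = np.sort(np.bincount(lab.ravel())[1:])
        expected = np.sort([np.pi * r**2 for _, _, r in rings])
        assert np.all(np.abs(areas / expected - 1.0) < 0.10)

    def test_uniform_frame_has_no_labels(self):
        seg = segment_bridges([np.full((100, 100), 3.0)])
        assert seg.labels[0].max() == 0

    def test_multiplicative_brightness_invariance(self):
        img = _ring_frame([(60, 60, 12), (140, 140, 10)])
        img += 0.5  # nonzero baseline
        seg1 = segment_bridges([img], min_area=50)
        seg2 = segment_bridges([img * 7.0], min_area=50)
        assert np.array_equal(seg1.labels[0] > 0, seg2.labels[0] > 0)


class TestCircularity:
    @staticmethod
    def _disk(r, shape=(120, 120), center=None):
        cy, cx = center or (shape[0] / 2, shape[1] / 2)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return np.hypot(yy - cy, xx - cx) <= r

    @staticmethod
    def _ellipse(a, b, shape=(160, 160), angle=0.0):
        cy, cx = shape[0] / 2, shape[1] / 2
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def test_disk_is_circular(self):
        assert mask_circularity(self._disk(40)) >= 0.98

    def test_ellipse_matches_ramanujan(self):
        a, b = 40.0, 20.0
        mask = self._ellipse(a, b)
        expected = 4 * np.pi * (np.pi * a * b) / ramanujan_perimeter(a, b) ** 2
        assert mask_circularity(mask) == pytest.approx(expected, rel=0.03)

    def test_invariant_under_rotation_and_translation(self):
        mask = self._ellipse(35, 18)
        c0 = mask_circularity(mask)
        rot = rotate(mask.astype(float), 37, reshape=True, order=1) > 0.5
        tra = shift(mask.astype(float), (6.3, -4.7), order=1) > 0.5
        assert mask_circularity(rot) == pytest.approx(c0, rel=0.02)
        assert mask_circularity(tra) == pytest.approx(c0, rel=0.02)


class TestTracking:
    def _deforming_sequence(self, n=10):
        labels = []
        for i in range(n):
            a = 30.0 + 2.5 * i  # progressively more elongated, same area
            b = 30.0**2 / a
            mask = TestCircularity._ellipse(a, b, shape=(160, 160))
            labels.append(mask.astype(int))
        return labels

    def test_deforming_disk_single_track_decreasing_circularity(self):
        track = track_circularity(self._deforming_sequence())
        assert track.n_tracks == 1
        circ = track.table.sort_values("frame")["circularity"].to_numpy()
        assert np.all(np.diff(circ) < 1e-6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(4):
            lab = np.zeros((120, 120), dtype=int)
            lab[TestCircularity._disk(15, center=(40 + i, 40))] = 1
            lab[TestCircularity._disk(12, center=(85, 80 - i))] = 2
            frames.append(lab)
        permuted = []
        for lab in frames:
            new = np.zeros_like(lab)
            new[lab == 1] = 2
            new[lab == 2] = 1
            permuted.append(new)
        t1 = track_circularity(frames)
        t2 = track_circularity(permuted)
        key = ["frame", "area", "perimeter"]
        a = t1.table.sort_values(key).reset_index(drop=True)
        b = t2.table.sort_values(key).reset_index(drop=True)
        assert np.allclose(a["circularity"], b["circularity"])
        assert t1.n_tracks == t2.n_tracks == 2

    def test_lost_object_terminates_track(self):
        lab1 = np.zeros((120, 120), dtype=int)
        lab1[TestCircularity._disk(10, center=(30, 30))] = 1
        lab2 = np.zeros((120, 120), dtype=int)  # object disappears
        track = track_circularity([lab1, lab2, lab2])
        assert track.terminated
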