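"""Gridding reconstruction: density compensation, adjoint correctness,
coil combination and HSR/HTR cine behaviour."""

import numpy as np
import pytest

from utecine.forward_sim import RawDataset, acquire, simulate_coil_maps
from utecine.gridding import GriddingConfig, kb_interpolate, kb_spread, nufft_forward
from utecine.phantom import DynamicPhantom, Ellipsoid, mouse_thorax_phantom
from utecine.recon import (coil_combine_sos, density_compensation,
                           finalize_image, grid_adjoint, reconstruct_cine)
from utecine.schedule import GatingParams, build_schedule
from utecine.trajectory import make_spoke_set

SIM = dict(field_strength=7.0, dose_umol_per_kg=200.0, tr=0.0035,
           te=0.031e-3, flip_deg=15.0)


class TestDensityCompensation:
    def test_shell_volume_ratio(self):
        w = density_compensation([0.0, 1.0])
        # shells [0, 0.5] and [0.5, 1.5]: volume ratio (1.5^3 - 0.5^3)/0.5^3
        assert w[1] / w[0] == pytest.approx((1.5 ** 3 - 0.5 ** 3) / 0.5 ** 3)

    def test_monotone_in_radius(self):
        w = density_compensation(np.linspace(0, 32, 64))
        assert np.all(np.diff(w) > 0)

    def test_degenerate_all_zero_radii(self):
        np.testing.assert_array_equal(density_compensation([0.0, 0.0, 0.0]),
                                      np.ones(3))

    def test_negative_radii_rejected(self):
        with pytest.raises(ValueError):
            density_compensation([-1.0, 0.0])


class TestAdjointCorrectness:
    def test_inner_product_identity(self, rng):
        """<A x, y> == <x, A^H y> for interpolation/gridding on 16^3."""
        cfg = GriddingConfig()
        M = 16
        for _ in range(3):
            grid = rng.standard_normal((M, M, M)) + 1j * rng.standard_normal((M, M, M))
            u = rng.uniform(-M / 2, M / 2, size=(50, 3)) * 0.95
            y = rng.standard_normal(50) + 1j * rng.standard_normal(50)
            ip1 = np.vdot(y, kb_interpolate(grid, u, cfg))
            ip2 = np.vdot(kb_spread(y, u, M, cfg), grid)
            assert abs(ip1 - ip2) / abs(ip1) < 1e-10

    def test_forward_matches_direct_dft_on_smooth_object(self, direct_dft, rng):
        """Deapodized oversampled-FFT interpolation reproduces the exact
        transform of a smooth test function to better than 1%."""
        N = 16
        ax = np.arange(N) - N // 2
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        img = np.exp(-(xx ** 2 + yy ** 2 + zz ** 2) / (2 * 3.0 ** 2))
        k = rng.uniform(-N / 2, N / 2, size=(150, 3)) * 0.98
        got = nufft_forward(img + 0j, k)
        oracle = direct_dft(img + 0j, k)
        assert np.max(np.abs(got - oracle)) / np.max(np.abs(oracle)) < 0.01


class TestFinalizeImage:
    def test_constant_kspace_gives_centered_sharp_peak(self):
        cfg = GriddingConfig()
        N, M = 16, 32
        grid = np.ones((M, M, M), dtype=complex)
        img = finalize_image(grid, cfg, N)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (N // 2, N // 2, N // 2)
        sidelobe = np.partition(img.ravel(), -2)[-2]
        assert img.max() > 10 * sidelobe

    def test_zero_grid_gives_zero_image(self):
        img = finalize_image(np.zeros((32, 32, 32), dtype=complex),
                             GriddingConfig(), 16)
        assert not img.any()

    def test_single_dc_sample_mass_concentrates_at_grid_center(self):
        cfg = GriddingConfig()
        grid = grid_adjoint(np.array([1.0 + 0j]), np.zeros((1, 3)), cfg, 16)
        assert grid.shape == (32, 32, 32)
        peak = np.unravel_index(np.argmax(np.abs(grid)), grid.shape)
        assert peak == (16, 16, 16)
        # all mass within the kernel footprint
        total = grid.sum()
        assert abs(grid[12:21, 12:21, 12:21].sum() - total) < 1e-9 * abs(total)

    def test_sample_outside_grid_rejected(self):
        cfg = GriddingConfig()
        with pytest.raises(ValueError):
            grid_adjoint(np.array([1.0 + 0j]), np.array([[40.0, 0, 0]]), cfg, 16)


class TestSumOfSquares:
    def test_single_coil_identity(self):
        v = np.abs(np.random.default_rng(0).standard_normal((1, 4, 4, 4)))
        np.testing.assert_allclose(coil_combine_sos(v), v[0])

    def test_pythagorean_pair(self):
        a = np.full((2, 2, 2), 3.0)
        b = np.full((2, 2, 2), 4.0)
        np.testing.assert_allclose(coil_combine_sos([a, b]), 5.0)

    def test_adding_a_coil_never_decreases(self):
        rng = np.random.default_rng(1)
        v = np.abs(rng.standard_normal((3, 5, 5, 5)))
        assert np.all(coil_combine_sos(v) >= coil_combine_sos(v[:2]) - 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coil_combine_sos(np.zeros((4, 4, 4)))


def _static_raw(matrix=32, n_spokes=600, n_coils=1, noise=0.0, seed=0,
                phantom=None):
    ph = phantom or DynamicPhantom(
        fov_mm=20.0, matrix=matrix, rr_interval=0.15,
        primitives=(Ellipsoid("blood", (0, 0, 0), (4.0, 4.0, 4.0)),))
    spokes = make_spoke_set(n_spokes, matrix)
    coils = simulate_coil_maps(n_coils, matrix)
    return ph, acquire(ph, None, spokes, coils, noise, seed, **SIM)


class TestPipeline:
    def test_uniform_sphere_contrast(self):
        ph, raw = _static_raw(matrix=48, n_spokes=2000)
        img = reconstruct_cine(raw, "hsr").data[0]
        ax = np.arange(48) - 24
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        r2 = xx ** 2 + yy ** 2 + zz ** 2
        voxel = 20.0 / 48
        inside = r2 <= (3.0 / voxel) ** 2
        outside = r2 >= (7.0 / voxel) ** 2
        assert img[inside].mean() / img[outside].mean() >= 20

    def test_sos_combination_flattens_array_coil_shading(self):
        ph, raw1 = _static_raw(matrix=32, n_spokes=800, n_coils=4)
        cine = reconstruct_cine(raw1, "hsr")
        # per-coil recon for comparison
        from utecine.recon import density_compensation as dcf_fn
        from utecine.gridding import nufft_adjoint
        spokes = raw1.spokes
        coords = spokes.sample_coordinates().reshape(-1, 3)
        dcf = dcf_fn(spokes.sample_radii)
        w = np.broadcast_to(dcf, (spokes.n_spokes, spokes.n_readout)).ravel()
        w = w / (spokes.n_spokes * 32 ** 3)
        ax = np.arange(32) - 16
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = (xx ** 2 + yy ** 2 + zz ** 2) <= (3.0 / (20 / 32)) ** 2
        cv_combined = np.std(cine.data[0][inside]) / np.mean(cine.data[0][inside])
        for c in range(4):
            per = np.abs(nufft_adjoint(raw1.samples[0, :, :, c].ravel() * w,
                                       coords, 32))
            cv_single = np.std(per[inside]) / np.mean(per[inside])
            assert cv_combined < cv_single

    def test_hsr_frame_equals_union_of_htr_children(self):
        ph = mouse_thorax_phantom(matrix=32)
        spokes = make_spoke_set(512, 32)
        sched = build_schedule(512, GatingParams())
        raw = acquire(ph, sched, spokes, simulate_coil_maps(1, 32), 0.0, 0, **SIM)
        hsr = reconstruct_cine(raw, "hsr")
        # Rebuild HSR frame 0 from the concatenated data of its 4 HTR children.
        from utecine.gridding import nufft_adjoint
        from utecine.recon import density_compensation as dcf_fn
        dcf = dcf_fn(spokes.sample_radii)
        parts_coords, parts_vals = [], []
        for slot in range(4):
            proj = np.arange(slot, 512, 4)
            parts_coords.append(spokes.sample_coordinates(proj).reshape(-1, 3))
            parts_vals.append((raw.samples[0, proj, :, 0]
                               * dcf[None, :]).ravel())
        coords = np.concatenate(parts_coords)
        vals = np.concatenate(parts_vals) / (512 * 32 ** 3)
        rebuilt = np.abs(nufft_adjoint(vals, coords, 32))
        np.testing.assert_allclose(rebuilt, hsr.data[0], rtol=1e-9, atol=1e-12)

    def test_htr_has_four_times_more_frames(self):
        ph = mouse_thorax_phantom(matrix=32)
        spokes = make_spoke_set(256, 32)
        sched = build_schedule(256, GatingParams())
        raw = acquire(ph, sched, spokes, simulate_coil_maps(1, 32), 0.0, 0, **SIM)
        assert reconstruct_cine(raw, "hsr").n_frames == 10
        assert reconstruct_cine(raw, "htr").n_frames == 40

    def test_htr_mean_tracks_hsr_on_static_object(self):
        ph, raw = _static_raw(matrix=32, n_spokes=2048)
        # wrap as a one-frame gated acquisition of a static object
        sched = build_schedule(2048, GatingParams(rr_interval=4.5 * 0.0035))
        raw = RawDataset(samples=raw.samples, spokes=raw.spokes, schedule=sched,
                         noise_sigma=0.0, seed=0, meta=raw.meta)
        hsr = reconstruct_cine(raw, "hsr").data[0]
        htr = reconstruct_cine(raw, "htr").data.mean(axis=0)
        corr = np.corrcoef(hsr.ravel(), htr.ravel())[0, 1]
        assert corr > 0.95

    def test_undersampled_htr_has_more_background_streak_energy(self):
        ph, raw = _static_raw(matrix=32, n_spokes=512)
        sched = build_schedule(512, GatingParams(rr_interval=4.5 * 0.0035))
        raw = RawDataset(samples=raw.samples, spokes=raw.spokes, schedule=sched,
                         noise_sigma=0.0, seed=0, meta=raw.meta)
        hsr = reconstruct_cine(raw, "hsr").data[0]
        htr = reconstruct_cine(raw, "htr").data[0]
        ax = np.arange(32) - 16
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        bg = (xx ** 2 + yy ** 2 + zz ** 2) >= (7.0 / (20 / 32)) ** 2
        assert np.sum(htr[bg] ** 2) > np.sum(hsr[bg] ** 2)

    def test_beating_ventricle_cavity_signal_tracks_cycle(self):
        """Bright-blood volume is maximal at end-diastole (frame 0) and
        minimal near the configured end-systole (phase 0.35 -> frame 3)."""
        ph = mouse_thorax_phantom(matrix=32)
        spokes = make_spoke_set(1024, 32)
        sched = build_schedule(1024, GatingParams())
        raw = acquire(ph, sched, spokes, simulate_coil_maps(1, 32), 0.0, 0, **SIM)
        cine = reconstruct_cine(raw, "hsr")
        # integrate reconstructed intensity over the LV bounding region
        voxel = 20.0 / 32
        cx = int(round(-1.9 / voxel + 16))
        box = (slice(cx - 4, cx + 4), slice(16 - 4, 16 + 4), slice(None))
        sums = [cine.data[f][box].sum() for f in range(cine.n_frames)]
        assert int(np.argmax(sums)) == 0
        assert int(np.argmin(sums)) in (3, 4)

    def test_htr_requires_gating(self):
        ph, raw = _static_raw(matrix=16, n_spokes=64)
        with pytest.raises(ValueError):
            reconstruct_cine(raw, "htr")
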