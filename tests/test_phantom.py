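"""Digital phantom rasterization and multi-coil forward simulation."""

import numpy as np

from capria.kinetics import KineticParams, make_schedule, perfusion_signal
from capria.nufft import Nufft3
from capria.phantom import (
    RawContainer,
    default_phantom,
    make_coil_model,
    region_maps,
    simulate_kspace,
    split_halves,
    truth_difference_series,
    truth_frame_series,
)
from capria.trajectory import bin_frames, build_schedule, desk_protocol


class TestRegionMaps:
    def test_coverage_and_overlap_resolution(self):
        spec = default_phantom(grid=32, edge_smooth_vox=0.0)
        static, regions, head = region_maps(spec)
        assert static.max() > 0
        assert len(regions) == 5  # 3 vessels + 2 tissue regions
        stack = np.stack([m for m, _, _ in regions])
        assert stack.max() <= 1.0
        # vessel-first claim: no voxel belongs to two regions
        assert (stack > 0.5).sum(axis=0).max() <= 1

    def test_seed_determinism_of_coils(self):
        a = make_coil_model(16, 183.0, 4, seed=5).sens
        b = make_coil_model(16, 183.0, 4, seed=5).sens
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, make_coil_model(16, 183.0, 4, seed=6).sens)

    def test_rss_positive_over_support(self):
        spec = default_phantom(grid=24)
        coils = make_coil_model(24, spec.fov, 8, seed=0)
        _, _, head = region_maps(spec)
        assert coils.rss()[head].min() > 0


class TestTruthSeries:
    def test_zero_flip_angles_give_zero_series(self):
        spec = default_phantom(grid=16)
        # alphas must be positive, so emulate the limit with tiny angles
        fa = make_schedule("constant", 1e-6, 1e-6, 8)
        t = 1.4 + np.arange(8) * 0.009
        out = truth_difference_series(spec, t, fa, 1.4)
        assert np.abs(out).max() < 1e-7

    def test_late_vessel_is_silent(self):
        from capria.phantom import VesselSegment

        spec = default_phantom(grid=16)
        late = VesselSegment((0, 0, -20), (0, 0, 20), 5.0, delta_t=9.0, v=1.0)
        spec = type(spec)(
            grid=16, fov=spec.fov, vessel_segments=(late,), tissue_regions=(),
            noise_sigma=0, phase_drift=0, edge_smooth_vox=0,
        )
        fa = make_schedule("constant", 6, 6, 8)
        t = 1.4 + np.arange(8) * 0.009
        out = truth_difference_series(spec, t, fa, 1.4)
        assert np.abs(out).max() == 0.0

    def test_tissue_voxel_matches_kinetics_pointwise(self):
        spec = default_phantom(grid=24, edge_smooth_vox=0.0)
        _, regions, _ = region_maps(spec)
        fa = make_schedule("quadratic-variable", 2, 9, 216)
        cfg = desk_protocol(matrix=24)
        t = cfg.spoke_times()
        series = truth_difference_series(spec, t, fa, cfg.tau)
        mask, kind, reg = next(r for r in regions if r[1] == "tissue")
        vox = np.argwhere(mask > 0.99)[0]
        got = series[:, vox[0], vox[1], vox[2]]
        p = KineticParams(Delta_t=reg.Delta_t, f=reg.f, T1t=reg.T1t)
        np.testing.assert_allclose(got, perfusion_signal(p, fa, t, cfg.tau), rtol=1e-10)


class TestSimulation:
    def test_difference_recovers_truth_structure(self, small_clean_container):
        """Adjoint of the subtracted noiseless data reproduces the dominant
        structure of the ground-truth difference (forward/adjoint oracle)."""
        container, spec, fa = small_clean_container
        cfg = container.config
        diff = container.control.astype(complex) - container.label.astype(complex)
        binning = bin_frames(cfg, cfg.t_max)
        truth = truth_frame_series(spec, cfg, fa, binning)
        W = binning.spokes_per_frame
        frame_of = (container.schedule.within - 1) // W
        rows = frame_of == 0
        coords = container.coords[rows].reshape(-1, 3)
        plan = Nufft3(coords, cfg.matrix, cfg.fov)
        sens = container.sens_truth
        dcf = np.sum(coords**2, axis=1)  # radial density compensation ~ k^2
        data = diff[rows].reshape(-1, sens.shape[0]) * dcf[:, None]
        imgs = plan.adjoint_batch(np.ascontiguousarray(data.T))
        back = np.sum(np.conj(sens) * imgs, axis=0)
        t = truth[0]
        corr = np.corrcoef(np.abs(back).ravel(), t.ravel())[0, 1]
        assert corr > 0.7  # adjoint (not inverse): structure, not values

    def test_linearity_in_blood_volume(self):
        cfg = desk_protocol(matrix=16, n_pairs=2)
        base = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0)
        seg = base.vessel_segments[0]
        v1, v2 = (
            type(base)(
                grid=16, fov=base.fov,
                vessel_segments=(type(seg)(seg.start, seg.end, seg.radius, seg.delta_t, v),),
                tissue_regions=(), noise_sigma=0, phase_drift=0,
            )
            for v in (0.4, 0.8)
        )
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        coils = make_coil_model(16, cfg.fov, 2, 0)
        sched = build_schedule(cfg)
        d1 = simulate_kspace(v1, coils, sched, cfg, fa)
        d2 = simulate_kspace(v2, coils, sched, cfg, fa)
        diff1 = d1.control.astype(complex) - d1.label.astype(complex)
        diff2 = d2.control.astype(complex) - d2.label.astype(complex)
        # doubling v doubles the difference (up to complex64 storage rounding
        # against the much larger static signal)
        np.testing.assert_allclose(diff2, 2 * diff1, rtol=1e-4, atol=1e-4)

    def test_seeded_determinism(self):
        cfg = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg.fov, seed=9)
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        coils = make_coil_model(16, cfg.fov, 2, 0)
        sched = build_schedule(cfg)
        a = simulate_kspace(spec, coils, sched, cfg, fa)
        b = simulate_kspace(spec, coils, sched, cfg, fa)
        np.testing.assert_array_equal(a.label, b.label)
        np.testing.assert_array_equal(a.control, b.control)

    def test_container_hdf5_roundtrip(self, small_clean_container, tmp_path):
        container, _, _ = small_clean_container
        path = tmp_path / "raw.h5"
        container.save(path)
        back = RawContainer.load(path)
        np.testing.assert_array_equal(back.label, container.label)
        np.testing.assert_array_equal(back.control, container.control)
        np.testing.assert_array_equal(back.coords, container.coords)
        assert back.config == container.config
        assert back.fa_schedule.alphaN == container.fa_schedule.alphaN


class TestSplitHalves:
    def test_even_split_counts(self, small_clean_container):
        container, _, _ = small_clean_container
        h1, h2 = split_halves(container)
        assert h1.config.n_pairs == h2.config.n_pairs == container.config.n_pairs // 2

    def test_two_pairs_split_one_one(self):
        cfg = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg.fov)
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        coils = make_coil_model(16, cfg.fov, 2, 0)
        c = simulate_kspace(spec, coils, build_schedule(cfg), cfg, fa)
        h1, h2 = split_halves(c)
        assert h1.config.n_pairs == h2.config.n_pairs == 1

    def test_concatenation_reproduces_original(self, small_clean_container):
        container, _, _ = small_clean_container
        h1, h2 = split_halves(container)
        np.testing.assert_array_equal(
            np.concatenate([h1.label, h2.label]), container.label
        )
        np.testing.assert_array_equal(
            np.concatenate([h1.coords, h2.coords]), container.coords
        )

    def test_first_half_identical_to_short_scan(self):
        """Golden ordering makes the first half bit-identical to a
        prospectively half-length acquisition with the same seed."""
        fa = make_schedule("quadratic-variable", 2, 9, 216)
        cfg_full = desk_protocol(matrix=16, n_pairs=4)
        cfg_half = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg_full.fov, seed=4)
        coils = make_coil_model(16, cfg_full.fov, 2, 4)
        full = simulate_kspace(spec, coils, build_schedule(cfg_full), cfg_full, fa)
        short = simulate_kspace(spec, coils, build_schedule(cfg_half), cfg_half, fa)
        h1, _ = split_halves(full)
        np.testing.assert_array_equal(h1.label, short.label)
        np.testing.assert_array_equal(h1.control, short.control)
        np.testing.assert_array_equal(h1.coords, short.coords)
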